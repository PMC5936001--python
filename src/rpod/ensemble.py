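"""Ensemble orchestration: multi-model and resampling outlier detection.

Three ways to build the k rankings that feed the Rank Product test:

* ``run_model_ensemble`` — fit heterogeneous members (elastic-net
  logistic, SPLS-DA, SGPLS) on the full data; one ranking per member.
* ``run_random_patients`` — refit one elastic-net logistic model on 80%
  patient subsamples (without replacement), scoring Cook's distance for
  *all* patients each run (held-out leverage from the training
  curvature); one ranking per run, default 100 runs.
* ``run_random_variables`` — refit on random gene subsets (feature
  bagging), all patients each run.

Alongside outliers, the ensemble reports consensus genes: the
intersection of member selections and the genes selected in more than a
frequency threshold (default 75%) of members/runs.

Per-run randomness derives from the master seed through
``numpy.random.SeedSequence(seed).spawn``, so any individual run is
reproducible in isolation and the whole ensemble is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .influence import cooks_distance_for_model
from .models import Hyperparameters, ModelFit, cv_select, fit_logit_en, fit_method
from .rankproduct import RPTable, fdr_bh, outlierness_ranks, rp_test

__all__ = [
    "EnsembleSpec",
    "ConsensusGenes",
    "EnsembleResult",
    "default_members",
    "run_model_ensemble",
    "run_random_patients",
    "run_random_variables",
    "outlier_report",
    "relabel_and_refit",
]


def default_members() -> list[Hyperparameters]:
    """The three-member ensemble with its reference hyperparameters
    (elastic-net alpha 0.9; SPLS-DA alpha 0.8, L=4; SGPLS alpha 0.7, L=4).
    Cross-validation (``EnsembleSpec.cv_members``) is preferred for new data.
    """
    return [
        Hyperparameters("logit_en", alpha=0.9, lambda_=1.0),
        Hyperparameters("splsda", alpha=0.8, n_latent=4),
        Hyperparameters("sgpls", alpha=0.7, n_latent=4),
    ]


@dataclass
class EnsembleSpec:
    members: list = field(default_factory=default_members)
    resampling: str = "none"          # none | random_patients | random_variables
    fraction: float = 0.8             # patient subsample fraction
    n_features_drawn: int = 1000      # feature-bagging draw size
    runs: int = 100
    seed: int = 0
    q_threshold: float = 0.05
    selection_freq_threshold: float = 0.75
    pvalue_mode: str = "auto"
    cv_members: bool = False
    cv_folds: int = 10
    cv_alpha_grid: tuple = (0.5, 0.7, 0.9)
    cv_L_grid: tuple = (1, 2, 3, 4, 5)

    def __post_init__(self):
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if not (0 < self.fraction <= 1):
            raise ValueError("fraction must lie in (0, 1]")


@dataclass
class ConsensusGenes:
    """Per-gene selection frequencies and the derived consensus sets."""

    frequency: np.ndarray          # selection frequency per gene
    denominators: np.ndarray       # members/runs in which the gene was eligible
    common: set                    # selected by every member/run it appeared in
    frequent: set                  # frequency > threshold
    threshold: float

    @classmethod
    def from_selection(cls, selected_sets, p, threshold, eligible_sets=None):
        counts = np.zeros(p)
        denom = np.zeros(p)
        for i, sel in enumerate(selected_sets):
            elig = eligible_sets[i] if eligible_sets is not None else np.arange(p)
            denom[elig] += 1
            counts[np.asarray(list(sel), dtype=int)] += 1 if len(sel) else 0
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(denom > 0, counts / np.maximum(denom, 1), 0.0)
        common = set(np.flatnonzero((counts == denom) & (denom > 0)).tolist())
        frequent = set(np.flatnonzero(freq > threshold).tolist())
        return cls(frequency=freq, denominators=denom, common=common,
                   frequent=frequent, threshold=threshold)


@dataclass
class EnsembleResult:
    rp_table: RPTable
    fits: list
    consensus: ConsensusGenes
    D: np.ndarray
    misclass_fraction: np.ndarray   # per sample (original order), across members/runs
    spec: EnsembleSpec
    sample_ids: list = field(default_factory=list)  # original D-matrix order


def _spawn_rngs(seed: int, count: int) -> list[np.random.Generator]:
    """Stable master-seed -> per-run generator derivation."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(count)]


def _resolve_member(X, y, hp: Hyperparameters, spec: EnsembleSpec, model_id: str) -> ModelFit:
    if spec.cv_members:
        if hp.method == "logit_en":
            cv = cv_select(X, y, "logit_en", alpha_grid=spec.cv_alpha_grid,
                           folds=spec.cv_folds, seed=spec.seed)
        else:
            cv = cv_select(X, y, hp.method, alpha_grid=spec.cv_alpha_grid,
                           L_grid=spec.cv_L_grid, folds=spec.cv_folds, seed=spec.seed)
        hp = cv.best
    return fit_method(X, y, hp, model_id=model_id)


def run_model_ensemble(X, y, spec: EnsembleSpec | None = None, sample_ids=None) -> EnsembleResult:
    """Fit every member on the full data and run the RP consensus test.

    A failing member aborts the ensemble (k is part of the null
    distribution; members are never silently dropped).
    """
    spec = spec or EnsembleSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if len(spec.members) < 2:
        raise ValueError("ensemble needs at least 2 members")
    if sample_ids is None:
        sample_ids = list(range(n))

    fits, D_cols, ids = [], [], []
    for j, hp in enumerate(spec.members):
        mid = f"{hp.method}_{j}"
        try:
            fit = _resolve_member(X, y, hp, spec, mid)
            infl = cooks_distance_for_model(fit, X, y, sample_ids=sample_ids)
        except Exception as exc:
            raise RuntimeError(f"ensemble member {mid!r} failed: {exc}") from exc
        fits.append(fit)
        D_cols.append(infl.D)
        ids.append(mid)
    D = np.column_stack(D_cols)
    table = rp_test(D, sample_ids=sample_ids, model_ids=ids,
                    q_threshold=spec.q_threshold, pvalue_mode=spec.pvalue_mode)
    consensus = ConsensusGenes.from_selection(
        [set(f.selected.tolist()) for f in fits], p, spec.selection_freq_threshold
    )
    mis = np.mean(
        [(f.predict_proba(X) > 0.5).astype(int) != y.astype(int) for f in fits], axis=0
    )
    return EnsembleResult(rp_table=table, fits=fits, consensus=consensus, D=D,
                          misclass_fraction=mis, spec=spec, sample_ids=list(sample_ids))


def _resampling_rp_table(D: np.ndarray, sample_ids, spec: EnsembleSpec) -> RPTable:
    """RP table for a resampling ensemble; a single run degenerates to the
    plain single-model ranking (RP = rank, exact p = rank/n)."""
    if D.shape[1] >= 2:
        return rp_test(D, sample_ids=sample_ids,
                       model_ids=[f"run_{r}" for r in range(D.shape[1])],
                       q_threshold=spec.q_threshold, pvalue_mode=spec.pvalue_mode)
    rm = outlierness_ranks(D)
    n = rm.n
    ranks = rm.R[:, 0]
    p = ranks / n
    q = fdr_bh(p)
    df = pd.DataFrame({
        "sample_id": list(sample_ids), "rank_run_0": ranks, "RP": ranks,
        "p_value": p, "q_value": q, "outlier": q < spec.q_threshold,
    }).sort_values("RP", kind="stable").reset_index(drop=True)
    return RPTable(table=df, n=n, k=1, pvalue_mode="exact",
                   q_threshold=spec.q_threshold, rank_matrix=rm)


def _logit_en_member(spec: EnsembleSpec) -> Hyperparameters:
    for hp in spec.members:
        if hp.method == "logit_en":
            return hp
    raise ValueError("resampling ensembles require a logit_en member spec")


def run_random_patients(X, y, spec: EnsembleSpec | None = None, sample_ids=None,
                        max_redraws: int = 50) -> EnsembleResult:
    """Patient-resampling ensemble (default 100 runs of 80% subsamples).

    Each run fits elastic-net logistic regression on the drawn patients
    and scores Cook's distance for *all* patients: held-out observations
    get leverage from the training curvature evaluated at their own
    covariates and predicted-probability weights.
    """
    spec = spec or EnsembleSpec(members=[Hyperparameters("logit_en", alpha=0.7, lambda_=1.0)])
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if sample_ids is None:
        sample_ids = list(range(n))
    hp = _logit_en_member(spec)
    m = int(np.floor(spec.fraction * n))
    rngs = _spawn_rngs(spec.seed, spec.runs)

    D = np.empty((n, spec.runs))
    sel_sets, mis = [], np.zeros(n)
    for run, rng in enumerate(rngs):
        for _ in range(max_redraws):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise ValueError("could not draw a patient subsample with both classes")
        # resampled refits feed rankings only; a looser solver tolerance is
        # plenty for ordering Cook's distances and much cheaper over 100 runs
        fit = fit_logit_en(X[idx], y[idx], alpha=hp.alpha, lambda_=hp.lambda_,
                           tol=1e-4, max_iter=500, model_id=f"patients_run_{run}")
        # training rows positions within the full matrix
        infl = cooks_distance_for_model(fit, X, y, sample_ids=sample_ids, train_idx=idx)
        D[:, run] = infl.D
        sel_sets.append(set(fit.selected.tolist()))
        mis += (fit.predict_proba(X) > 0.5).astype(int) != y.astype(int)
    table = _resampling_rp_table(D, sample_ids, spec)
    consensus = ConsensusGenes.from_selection(sel_sets, p, spec.selection_freq_threshold)
    return EnsembleResult(rp_table=table, fits=[], consensus=consensus, D=D,
                          misclass_fraction=mis / spec.runs, spec=spec,
                          sample_ids=list(sample_ids))


def run_random_variables(X, y, spec: EnsembleSpec | None = None, sample_ids=None,
                         max_redraws: int = 50) -> EnsembleResult:
    """Feature-bagging ensemble: random gene subsets, all patients per run.

    Per-gene selection frequencies are relative to the runs in which the
    gene was actually drawn.
    """
    spec = spec or EnsembleSpec(members=[Hyperparameters("logit_en", alpha=0.7, lambda_=1.0)])
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if spec.n_features_drawn > p:
        raise ValueError("n_features_drawn exceeds number of genes")
    if sample_ids is None:
        sample_ids = list(range(n))
    hp = _logit_en_member(spec)
    rngs = _spawn_rngs(spec.seed, spec.runs)

    D = np.empty((n, spec.runs))
    sel_sets, elig_sets, mis = [], [], np.zeros(n)
    for run, rng in enumerate(rngs):
        for _ in range(max_redraws):
            feats = np.sort(rng.choice(p, size=spec.n_features_drawn, replace=False))
            if np.any(X[:, feats].std(axis=0) > 0):
                break
            warnings.warn("all-constant feature draw; re-drawing", RuntimeWarning)
        else:
            raise ValueError("could not draw a non-degenerate feature subset")
        Xs = X[:, feats]
        fit = fit_logit_en(Xs, y, alpha=hp.alpha, lambda_=hp.lambda_,
                           tol=1e-4, max_iter=500, model_id=f"variables_run_{run}")
        infl = cooks_distance_for_model(fit, Xs, y, sample_ids=sample_ids)
        D[:, run] = infl.D
        sel_sets.append(set(feats[fit.selected].tolist()))
        elig_sets.append(feats)
        mis += (fit.predict_proba(Xs) > 0.5).astype(int) != y.astype(int)
    table = _resampling_rp_table(D, sample_ids, spec)
    consensus = ConsensusGenes.from_selection(sel_sets, p, spec.selection_freq_threshold,
                                              eligible_sets=elig_sets)
    return EnsembleResult(rp_table=table, fits=[], consensus=consensus, D=D,
                          misclass_fraction=mis / spec.runs, spec=spec,
                          sample_ids=list(sample_ids))


def outlier_report(
    result: EnsembleResult,
    labels: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    receptor_genes: dict | None = None,
) -> pd.DataFrame:
    """One row per flagged outlier: ranks, RP, p, q, labels and context.

    ``labels`` is a TNBC label frame (sample_id, y, her2_source, suspect);
    ``expression`` a samples x genes frame and ``receptor_genes`` a
    mapping like {"ER": gene_id, ...} to surface receptor expression.
    Samples without a clinical row get blank fields and a note.
    """
    tab = result.rp_table.table
    rep = tab.loc[tab["outlier"]].copy().reset_index(drop=True)
    mis_map = dict(zip(result.sample_ids, result.misclass_fraction))
    rep["misclass_fraction"] = [mis_map.get(s, np.nan) for s in rep["sample_id"]]
    rep["note"] = ""
    if expression is not None and receptor_genes:
        for label, gene in receptor_genes.items():
            vals = []
            for s in rep["sample_id"]:
                vals.append(expression.at[s, gene]
                            if s in expression.index and gene in expression.columns
                            else np.nan)
            rep[f"{label}_expr"] = vals
    if labels is not None:
        lab = labels.set_index("sample_id")
        for col in ("y", "her2_source", "suspect"):
            if col in lab.columns:
                rep[col] = [lab.at[s, col] if s in lab.index else ""
                            for s in rep["sample_id"]]
        missing = [s not in lab.index for s in rep["sample_id"]]
        rep.loc[missing, "note"] = "no clinical row"
    return rep


def relabel_and_refit(X, y, flip_ids, spec: EnsembleSpec | None = None,
                      sample_ids=None) -> tuple[EnsembleResult, float]:
    """Flip the given labels, re-run the model ensemble, and report the
    Jaccard overlap of consensus (common) gene sets with the original run.
    """
    spec = spec or EnsembleSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if sample_ids is None:
        sample_ids = list(range(n))
    id_to_pos = {s: i for i, s in enumerate(sample_ids)}
    for f in flip_ids:
        if f not in id_to_pos:
            raise KeyError(f"unknown sample id {f!r}")
    base = run_model_ensemble(X, y, spec, sample_ids=sample_ids)
    y2 = y.copy()
    for f in flip_ids:
        y2[id_to_pos[f]] = 1 - y2[id_to_pos[f]]
    refit = run_model_ensemble(X, y2, spec, sample_ids=sample_ids)
    a, b = base.consensus.common, refit.consensus.common
    union = a | b
    overlap = len(a & b) / len(union) if union else 1.0
    return refit, overlap


def jaccard(a, b) -> float:
    """Jaccard overlap of two sets (1.0 when both are empty)."""
    a, b = set(a), set(b)
    u = a | b
    return len(a & b) / len(u) if u else 1.0
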