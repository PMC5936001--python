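"""Data model, file IO, receptor-status labels and confounder screening.

The expression container is a samples x genes matrix of non-negative
FPKM-like values (optionally log2-transformed).  The clinical side builds
the triple-negative (TNBC) binary response from ER, PR and HER2 receptor
calls.  HER2 has three clinical sources that frequently disagree — IHC
level (0/1+/2+/3+), IHC status and FISH — so the label builder applies the
precedence FISH (when determinate) > IHC status, and samples whose assays
contradict one another are flagged as *suspect*: their TNBC label may be
wrong, which makes them prime outlier candidates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionDataset",
    "ClinicalTable",
    "TNBCLabels",
    "load_expression",
    "log_transform",
    "load_clinical",
    "build_tnbc_labels",
    "flag_suspect_individuals",
    "fisher_exact_pvalue",
    "screen_confounders",
]

POS, NEG, EQUIV, INDET, MISSING = "positive", "negative", "equivocal", "indeterminate", "missing"
_STATUS_CODES = {POS, NEG, EQUIV, INDET, MISSING}
_LEVEL_CODES = {"0", "1+", "2+", "3+", MISSING}

# IHC level -> receptor sign (2+ is indeterminate by clinical convention)
LEVEL_SIGN = {"0": NEG, "1+": NEG, "2+": INDET, "3+": POS, MISSING: MISSING}


# --------------------------------------------------------------------------
# Expression data
# --------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Samples x genes expression values with IDs and transform state."""

    sample_ids: list
    gene_ids: list
    values: np.ndarray
    transform: str = "raw_fpkm"  # raw_fpkm | log

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.gene_ids):
            raise ValueError("value matrix shape does not match ID lists")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.gene_ids)) != p:
            raise ValueError("duplicate gene IDs")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        if self.transform == "raw_fpkm" and (self.values < 0).any():
            raise ValueError("raw FPKM values must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


def _read_table(path) -> pd.DataFrame:
    # pandas mangles duplicate header names, so check the raw header first
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    delim = "\t" if "\t" in header else ","
    names = header.split(delim)[1:]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample or gene IDs in file header")
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def load_expression(path, orientation: str = "samples_by_genes",
                    transform: str = "raw_fpkm") -> ExpressionDataset:
    """Read a delimited expression table (TSV/CSV, one header row, ID column).

    The result is always samples x genes; ``orientation`` states how the
    file is laid out.  Non-numeric or missing cells and duplicate IDs are
    errors (fail fast; no imputation).  ``transform="log"`` marks the file
    as already model-ready (log scale or arbitrary real values), skipping
    the non-negativity check applied to raw FPKM.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    if orientation == "genes_by_samples":
        df = df.T
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & ~df[col].isna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        if vals.isna().any():
            row = df.index[vals.isna().argmax()]
            raise ValueError(f"missing value at row {row!r}, column {col!r}")
        df[col] = vals
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError("duplicate sample or gene IDs in file")
    return ExpressionDataset(
        sample_ids=[str(s) for s in df.index],
        gene_ids=[str(g) for g in df.columns],
        values=df.to_numpy(dtype=float),
        transform=transform,
    )


def log_transform(ds: ExpressionDataset, offset: float = 1.0) -> ExpressionDataset:
    """log2(x + offset) transform; offset 1 keeps zero FPKM at zero."""
    if ds.transform != "raw_fpkm":
        raise ValueError("dataset is already log-transformed")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        gene_ids=list(ds.gene_ids),
        values=np.log2(ds.values + offset),
        transform="log",
    )


# --------------------------------------------------------------------------
# Clinical data and TNBC labels
# --------------------------------------------------------------------------

DEFAULT_COLUMN_MAP = {
    "sample_id": "sample_id",
    "er_status": "er_status",
    "pr_status": "pr_status",
    "her2_ihc_level": "her2_ihc_level",
    "her2_ihc_status": "her2_ihc_status",
    "her2_fish": "her2_fish",
}

_VALUE_ALIASES = {
    "positive": POS, "pos": POS, "+": POS,
    "negative": NEG, "neg": NEG, "-": NEG,
    "equivocal": EQUIV, "indeterminate": INDET,
    "": MISSING, "na": MISSING, "nan": MISSING, "[not available]": MISSING,
    "[not evaluated]": MISSING, "missing": MISSING,
}


def _norm_status(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return MISSING
    s = str(v).strip().lower()
    out = _VALUE_ALIASES.get(s, s)
    if out not in _STATUS_CODES:
        raise ValueError(f"unrecognized receptor status code {v!r}")
    return out


def _norm_level(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return MISSING
    s = str(v).strip().lower()
    if s in ("", "na", "nan", "missing", "[not available]", "[not evaluated]"):
        return MISSING
    if s in _LEVEL_CODES:
        return s
    raise ValueError(f"unrecognized HER2 IHC level {v!r}")


@dataclass
class ClinicalTable:
    """Per-sample receptor calls plus covariates (race, age, ...)."""

    table: pd.DataFrame                 # normalized receptor columns
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        req = ["sample_id", "er_status", "pr_status",
               "her2_ihc_level", "her2_ihc_status", "her2_fish"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise ValueError(f"clinical table lacks columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in clinical table")
        for c in ("er_status", "pr_status", "her2_ihc_status", "her2_fish"):
            self.table[c] = self.table[c].map(_norm_status)
        self.table["her2_ihc_level"] = self.table["her2_ihc_level"].map(_norm_level)
        bad = ~self.table["er_status"].isin({POS, NEG, MISSING})
        if bad.any():
            raise ValueError("ER status must be positive/negative/missing")
        bad = ~self.table["pr_status"].isin({POS, NEG, MISSING})
        if bad.any():
            raise ValueError("PR status must be positive/negative/missing")

    @classmethod
    def from_records(cls, records, covariates: pd.DataFrame | None = None):
        return cls(table=pd.DataFrame.from_records(records),
                   covariates=covariates if covariates is not None else pd.DataFrame())


def load_clinical(path, column_map: dict | None = None) -> ClinicalTable:
    """Read a clinical TSV/CSV using a column-name mapping.

    ``column_map`` maps the canonical keys (sample_id, er_status,
    pr_status, her2_ihc_level, her2_ihc_status, her2_fish) to the file's
    column names; remaining keys are treated as covariate columns.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    cov_cols = {}
    if column_map:
        for key, col in column_map.items():
            if key in cmap:
                cmap[key] = col
            else:
                cov_cols[key] = col
    raw = pd.read_csv(path, sep=None, engine="python")
    table = pd.DataFrame({key: raw[col] for key, col in cmap.items()})
    cov = pd.DataFrame({key: raw[col] for key, col in cov_cols.items()})
    cov.insert(0, "sample_id", raw[cmap["sample_id"]])
    return ClinicalTable(table=table, covariates=cov)


def _her2_call(row) -> tuple[str, str]:
    """Resolve the HER2 receptor call and its source for one sample.

    FISH overrides IHC status, but only when FISH is determinate
    (positive/negative); otherwise fall back to a determinate IHC status.
    """
    if row["her2_fish"] in (POS, NEG):
        return row["her2_fish"], "fish"
    if row["her2_ihc_status"] in (POS, NEG):
        return row["her2_ihc_status"], "ihc_status"
    return MISSING, "none"


@dataclass
class TNBCLabels:
    """Binary TNBC outcome per sample plus the excluded-sample list."""

    labels: pd.DataFrame     # sample_id, y, her2_source, suspect
    excluded: pd.DataFrame   # sample_id, reason

    def y_for(self, sample_ids) -> np.ndarray:
        s = self.labels.set_index("sample_id")["y"]
        return s.loc[list(sample_ids)].to_numpy()

    def to_tsv(self, path) -> None:
        lab = self.labels.copy()
        lab["exclusion_reason"] = ""
        exc = self.excluded.copy()
        exc["y"] = ""
        exc["her2_source"] = ""
        exc["suspect"] = ""
        exc = exc.rename(columns={"reason": "exclusion_reason"})
        cols = ["sample_id", "y", "her2_source", "suspect", "exclusion_reason"]
        pd.concat([lab, exc])[cols].to_csv(path, sep="\t", index=False)


def build_tnbc_labels(clin: ClinicalTable) -> TNBCLabels:
    """TNBC response: y=1 iff ER, PR and the resolved HER2 call are all
    negative; y=0 whenever any of the three is positive.  Samples whose
    receptor calls cannot be resolved either way are excluded and listed.
    """
    suspects = {s for s, _ in flag_suspect_individuals(clin)}
    rows, excluded = [], []
    for _, row in clin.table.iterrows():
        sid = row["sample_id"]
        her2, source = _her2_call(row)
        calls = (row["er_status"], row["pr_status"], her2)
        if any(c == POS for c in calls):
            y = 0
        elif all(c == NEG for c in calls):
            y = 1
        else:
            missing_of = [name for name, c in zip(("ER", "PR", "HER2"), calls) if c != NEG]
            excluded.append({"sample_id": sid,
                             "reason": f"unresolved receptor call: {', '.join(missing_of)}"})
            continue
        rows.append({"sample_id": sid, "y": y, "her2_source": source,
                     "suspect": sid in suspects})
    labels = pd.DataFrame(rows, columns=["sample_id", "y", "her2_source", "suspect"])
    exc = pd.DataFrame(excluded, columns=["sample_id", "reason"])
    return TNBCLabels(labels=labels, excluded=exc)


def flag_suspect_individuals(clin: ClinicalTable) -> list[tuple[str, str]]:
    """Samples with internally contradictory HER2 assays.

    Two discordance kinds: the IHC level maps to the opposite sign of the
    IHC status (0/1+ negative, 3+ positive; 2+ is indeterminate and never
    contradicts), or a determinate IHC status contradicts a determinate
    FISH call.
    """
    out = []
    for _, row in clin.table.iterrows():
        sid = row["sample_id"]
        lvl_sign = LEVEL_SIGN[row["her2_ihc_level"]]
        status = row["her2_ihc_status"]
        fish = row["her2_fish"]
        if lvl_sign in (POS, NEG) and status in (POS, NEG) and lvl_sign != status:
            out.append((sid, "ihc_level_vs_ihc_status"))
        if status in (POS, NEG) and fish in (POS, NEG) and status != fish:
            out.append((sid, "ihc_status_vs_fish"))
    return out


# --------------------------------------------------------------------------
# Confounder screening
# --------------------------------------------------------------------------

def fisher_exact_pvalue(table: np.ndarray, max_tables: int = 500_000,
                        seed: int = 0, n_mc: int = 100_000) -> float:
    """Two-sided Fisher's exact p by point-probability summation.

    2x2 tables use scipy; larger tables are enumerated exactly over all
    tables with the observed margins when the enumeration is affordable,
    otherwise a seeded Monte Carlo over random tables (permutation null)
    approximates the same two-sided p with a warning.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a non-negative 2-D count matrix")
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])

    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n_total = int(table.sum())
    lgam = math.lgamma

    def log_point_prob(t) -> float:
        # multivariate hypergeometric point probability of a table
        lp = sum(lgam(r + 1) for r in rows) + sum(lgam(c + 1) for c in cols)
        lp -= lgam(n_total + 1)
        lp -= sum(lgam(int(x) + 1) for x in np.ravel(t))
        return lp

    lp_obs = log_point_prob(table)
    tol = 1e-7

    # enumerate tables with fixed margins, bounded by max_tables
    r, c = table.shape
    count = [0]

    def enumerate_tables(row_idx, remaining_cols, acc):
        if count[0] > max_tables:
            raise MemoryError
        if row_idx == r - 1:
            acc.append(list(remaining_cols))
            yield acc
            acc.pop()
            return
        # fill one row; remaining_cols are the unused column sums
        target = rows[row_idx]

        def fill(cell, left, rowvals):
            if cell == c - 1:
                if 0 <= left <= remaining_cols[cell]:
                    rowvals.append(left)
                    yield rowvals
                    rowvals.pop()
                return
            top = min(left, remaining_cols[cell])
            for vcell in range(top + 1):
                rowvals.append(vcell)
                yield from fill(cell + 1, left - vcell, rowvals)
                rowvals.pop()

        for rowvals in fill(0, int(target), []):
            count[0] += 1
            new_rem = [remaining_cols[j] - rowvals[j] for j in range(c)]
            acc.append(list(rowvals))
            yield from enumerate_tables(row_idx + 1, new_rem, acc)
            acc.pop()

    try:
        total = 0.0
        for t in enumerate_tables(0, list(int(x) for x in cols), []):
            lp = log_point_prob(np.array(t))
            if lp <= lp_obs + tol:
                total += math.exp(lp)
        return float(min(total, 1.0))
    except MemoryError:
        warnings.warn(
            "contingency table too large for exact enumeration; "
            "using seeded Monte Carlo Fisher p", RuntimeWarning,
        )
        rng = np.random.default_rng(seed)
        row_labels = np.repeat(np.arange(r), rows)
        col_labels = np.repeat(np.arange(c), cols)
        hits = 0
        for _ in range(n_mc):
            perm = rng.permutation(col_labels)
            t = np.zeros((r, c), dtype=np.int64)
            np.add.at(t, (row_labels, perm), 1)
            if log_point_prob(t) <= lp_obs + tol:
                hits += 1
        return (hits + 1) / (n_mc + 1)


def screen_confounders(covariates: pd.DataFrame, y: np.ndarray,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Univariate screening of clinical covariates against the outcome.

    Continuous covariates get a univariate logistic Wald p; categorical
    ones get a two-sided Fisher's exact p on the y-by-level contingency
    table.  Rows with a missing covariate value are dropped per covariate;
    constant covariates report p = 1 with a warning.  Returns a table of
    (covariate, test, p_value, significant at ``alpha``).
    """
    import statsmodels.api as sm

    y = np.asarray(y)
    results = []
    for name in covariates.columns:
        if name == "sample_id":
            continue
        col = covariates[name]
        mask = col.notna().to_numpy()
        cv, yv = col[mask], y[mask]
        if cv.nunique() <= 1:
            warnings.warn(f"covariate {name!r} is constant; p reported as 1",
                          RuntimeWarning)
            results.append((name, "constant", 1.0, False))
            continue
        if pd.api.types.is_numeric_dtype(cv) and cv.nunique() > 5:
            design = sm.add_constant(cv.to_numpy(dtype=float))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.Logit(yv.astype(float), design).fit(disp=0, maxiter=200)
                pval = float(res.pvalues[1])
                if not np.isfinite(pval):
                    raise ValueError("non-finite Wald p")
                test = "logistic_wald"
            except Exception:
                warnings.warn(
                    f"possible separation fitting covariate {name!r}; "
                    "flagging as significant", RuntimeWarning,
                )
                pval, test = 0.0, "logistic_wald(separation)"
        else:
            tab = pd.crosstab(pd.Series(yv, name="y"), cv).to_numpy()
            pval = fisher_exact_pvalue(tab)
            test = "fisher_exact"
        results.append((name, test, pval, pval < alpha))
    return pd.DataFrame(results, columns=["covariate", "test", "p_value", "significant"])
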