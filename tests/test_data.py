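"""Expression IO, TNBC label construction, suspects, confounder screening."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rpod.data import (
    ClinicalTable,
    ExpressionDataset,
    build_tnbc_labels,
    fisher_exact_pvalue,
    flag_suspect_individuals,
    load_expression,
    log_transform,
    screen_confounders,
)

POS, NEG, MISS = "positive", "negative", "missing"


def clin_row(sid, er=NEG, pr=NEG, level=MISS, status=MISS, fish=MISS):
    return {"sample_id": sid, "er_status": er, "pr_status": pr,
            "her2_ihc_level": level, "her2_ihc_status": status, "her2_fish": fish}


@pytest.fixture
def tiny_expression(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text("sample_id\tG1\tG2\nS1\t0.0\t1.0\nS2\t7.0\t2.5\nS3\t3.0\t0.1\n")
    return path


class TestExpressionIO:
    def test_samples_by_genes_identity(self, tiny_expression):
        ds = load_expression(tiny_expression, "samples_by_genes")
        assert ds.sample_ids == ["S1", "S2", "S3"]
        assert ds.gene_ids == ["G1", "G2"]
        assert ds.values.shape == (3, 2)
        assert ds.values[1, 0] == 7.0

    def test_transposed_file_round_trips(self, tiny_expression, tmp_path):
        ds = load_expression(tiny_expression, "samples_by_genes")
        tpath = tmp_path / "expr_t.tsv"
        ds.to_frame().T.to_csv(tpath, sep="\t", index_label="gene_id")
        ds2 = load_expression(tpath, "genes_by_samples")
        assert ds2.sample_ids == ds.sample_ids
        assert ds2.gene_ids == ds.gene_ids
        assert np.array_equal(ds2.values, ds.values)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("sample_id\tG1\tG1\nS1\t1.0\t2.0\n")
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            load_expression(path)

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\tG1\nS1\t1.0\nS2\toops\n")
        with pytest.raises(ValueError, match="S2.*G1"):
            load_expression(path)

    def test_missing_cell_rejected(self, tmp_path):
        path = tmp_path / "miss.csv"
        path.write_text("sample_id,G1,G2\nS1,1.0,\nS2,2.0,3.0\n")
        with pytest.raises(ValueError, match="missing"):
            load_expression(path)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionDataset(["S1"], ["G1"], np.array([[-1.0]]))


class TestLogTransform:
    def test_values_and_state(self, tiny_expression):
        ds = log_transform(load_expression(tiny_expression))
        assert ds.transform == "log"
        assert ds.values[0, 0] == 0.0        # log2(0+1)
        assert ds.values[0, 1] == 1.0        # log2(1+1)
        assert ds.values[1, 0] == 3.0        # log2(7+1)

    def test_double_application_rejected(self, tiny_expression):
        ds = log_transform(load_expression(tiny_expression))
        with pytest.raises(ValueError, match="already"):
            log_transform(ds)

    def test_monotone_per_entry(self, tiny_expression):
        raw = load_expression(tiny_expression)
        logd = log_transform(raw)
        order_raw = np.argsort(raw.values, axis=0)
        order_log = np.argsort(logd.values, axis=0)
        assert np.array_equal(order_raw, order_log)


class TestTNBCLabels:
    def test_fish_overrides_ihc_status(self):
        # ER+, PR-, HER2 IHC negative but FISH positive -> non-TNBC via FISH
        clin = ClinicalTable.from_records(
            [clin_row("PT-0101", er=POS, pr=NEG, level="1+", status=NEG, fish=POS)]
        )
        lab = build_tnbc_labels(clin).labels.iloc[0]
        assert lab["y"] == 0 and lab["her2_source"] == "fish"

    def test_fish_negative_makes_tnbc_despite_positive_ihc(self):
        clin = ClinicalTable.from_records(
            [clin_row("PT-0102", er=NEG, pr=NEG, level="3+", status=POS, fish=NEG)]
        )
        lab = build_tnbc_labels(clin).labels.iloc[0]
        assert lab["y"] == 1 and lab["her2_source"] == "fish"

    def test_all_negative_without_fish_uses_ihc(self):
        clin = ClinicalTable.from_records(
            [clin_row("S1", er=NEG, pr=NEG, status=NEG)]
        )
        lab = build_tnbc_labels(clin).labels.iloc[0]
        assert lab["y"] == 1 and lab["her2_source"] == "ihc_status"

    def test_unresolvable_sample_excluded_with_reason(self):
        clin = ClinicalTable.from_records(
            [clin_row("S1", er=NEG, pr=MISS, status=NEG)]
        )
        res = build_tnbc_labels(clin)
        assert res.labels.empty
        assert res.excluded.iloc[0]["sample_id"] == "S1"
        assert "PR" in res.excluded.iloc[0]["reason"]

    def test_deterministic_and_idempotent(self):
        clin = ClinicalTable.from_records(
            [clin_row(f"S{i}", er=e, pr=p, status=s)
             for i, (e, p, s) in enumerate(
                 itertools.product([POS, NEG], repeat=3))]
        )
        a = build_tnbc_labels(clin).labels
        b = build_tnbc_labels(clin).labels
        pd.testing.assert_frame_equal(a, b)

    def test_exhaustive_code_combinations(self):
        """y=1 iff (ER, PR, resolved HER2) are all negative, for every
        combination of receptor codes; otherwise y=0 when any is positive,
        else the sample is excluded."""
        statuses = [POS, NEG, "equivocal", "indeterminate", MISS]
        records, expected = [], {}
        i = 0
        for er, pr in itertools.product([POS, NEG, MISS], repeat=2):
            for ihc, fish in itertools.product(statuses, repeat=2):
                sid = f"S{i}"
                i += 1
                records.append(clin_row(sid, er=er, pr=pr, status=ihc, fish=fish))
                her2 = fish if fish in (POS, NEG) else (ihc if ihc in (POS, NEG) else MISS)
                calls = (er, pr, her2)
                if any(c == POS for c in calls):
                    expected[sid] = 0
                elif all(c == NEG for c in calls):
                    expected[sid] = 1
                else:
                    expected[sid] = None  # excluded
        res = build_tnbc_labels(ClinicalTable.from_records(records))
        got = dict(zip(res.labels["sample_id"], res.labels["y"]))
        excluded = set(res.excluded["sample_id"])
        for sid, want in expected.items():
            if want is None:
                assert sid in excluded
            else:
                assert got[sid] == want, sid

    def test_labels_tsv_round_trip(self, tmp_path):
        clin = ClinicalTable.from_records([
            clin_row("S1", er=NEG, pr=NEG, status=NEG),
            clin_row("S2", er=POS, pr=NEG, status=NEG),
            clin_row("S3", er=NEG, pr=MISS, status=NEG),
        ])
        res = build_tnbc_labels(clin)
        out = tmp_path / "labels.tsv"
        res.to_tsv(out)
        back = pd.read_csv(out, sep="\t")
        assert set(back.columns) == {"sample_id", "y", "her2_source",
                                     "suspect", "exclusion_reason"}
        assert len(back) == 3


class TestSuspects:
    def test_level_contradicts_status(self):
        clin = ClinicalTable.from_records(
            [clin_row("PT-0201", er=NEG, pr=NEG, level="3+", status=NEG)]
        )
        flags = flag_suspect_individuals(clin)
        assert flags == [("PT-0201", "ihc_level_vs_ihc_status")]

    def test_ihc_status_contradicts_fish(self):
        clin = ClinicalTable.from_records(
            [clin_row("PT-0202", er=NEG, pr=NEG, level="2+", status=POS, fish=NEG)]
        )
        flags = flag_suspect_individuals(clin)
        assert flags == [("PT-0202", "ihc_status_vs_fish")]

    def test_concordant_sample_not_flagged(self):
        clin = ClinicalTable.from_records(
            [clin_row("S1", level="1+", status=NEG)]
        )
        assert flag_suspect_individuals(clin) == []

    def test_equivocal_level_never_contradicts(self):
        clin = ClinicalTable.from_records(
            [clin_row("S1", level="2+", status=POS), clin_row("S2", level="2+", status=NEG)]
        )
        assert flag_suspect_individuals(clin) == []

    def test_suspect_flag_propagates_to_labels(self):
        clin = ClinicalTable.from_records(
            [clin_row("S1", er=NEG, pr=NEG, level="3+", status=NEG)]
        )
        lab = build_tnbc_labels(clin).labels.iloc[0]
        assert bool(lab["suspect"]) is True


class TestFisherExact:
    def test_perfectly_associated_2x2(self):
        # [[10,0],[0,10]]: two-sided p = 2/C(20,10)
        p = fisher_exact_pvalue([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_balanced_table_p_is_one(self):
        assert fisher_exact_pvalue([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_rxc_enumeration_matches_hypergeometric_sum_for_2x2(self):
        """The r x c enumeration path, forced on a 2x2-equivalent 2x3 table
        with an empty column, must agree with scipy's 2x2 Fisher."""
        table23 = np.array([[7, 3, 0], [2, 8, 0]])
        p_rxc = fisher_exact_pvalue(table23)
        p_22 = stats.fisher_exact(table23[:, :2])[1]
        assert p_rxc == pytest.approx(p_22, rel=1e-9)

    def test_2x3_point_probability_definition(self):
        """Oracle: enumerate all tables with the observed margins and sum the
        multivariate hypergeometric probabilities <= the observed one."""
        obs = np.array([[4, 1, 1], [1, 3, 2]])
        rows, cols = obs.sum(1), obs.sum(0)
        Ntot = int(obs.sum())

        def prob(t):
            num = (math.prod(math.factorial(r) for r in rows)
                   * math.prod(math.factorial(c) for c in cols))
            den = math.factorial(Ntot) * math.prod(
                math.factorial(int(x)) for x in np.ravel(t))
            return Fraction(num, den)

        p_obs = prob(obs)
        total = Fraction(0)
        for a in range(min(rows[0], cols[0]) + 1):
            for b in range(min(rows[0] - a, cols[1]) + 1):
                c = rows[0] - a - b
                if c < 0 or c > cols[2]:
                    continue
                t = np.array([[a, b, c], [cols[0] - a, cols[1] - b, cols[2] - c]])
                if (t >= 0).all() and prob(t) <= p_obs:
                    total += prob(t)
        assert fisher_exact_pvalue(obs) == pytest.approx(float(total), rel=1e-9)


class TestConfounderScreening:
    def test_categorical_association_flagged(self):
        y = np.repeat([0, 1], 10)
        cov = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10})
        res = screen_confounders(cov, y)
        row = res.iloc[0]
        assert row["test"] == "fisher_exact"
        assert row["p_value"] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert bool(row["significant"])

    def test_independent_categorical_not_flagged(self):
        y = np.tile([0, 1], 10)
        cov = pd.DataFrame({"group": ["a", "a", "b", "b"] * 5})
        res = screen_confounders(cov, y)
        assert not res.iloc[0]["significant"]

    def test_constant_covariate_reports_one_with_warning(self):
        y = np.repeat([0, 1], 5)
        cov = pd.DataFrame({"c": np.ones(10)})
        with pytest.warns(RuntimeWarning, match="constant"):
            res = screen_confounders(cov, y)
        assert res.iloc[0]["p_value"] == 1.0

    def test_continuous_wald_matches_newton_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.2 + 0.8 * x)))).astype(int)
        res = screen_confounders(pd.DataFrame({"age": x}), y)

        # independent Newton IRLS oracle for the Wald z of the slope
        X = np.column_stack([np.ones(200), x])
        beta = np.zeros(2)
        for _ in range(50):
            p = 1 / (1 + np.exp(-X @ beta))
            W = p * (1 - p)
            grad = X.T @ (y - p)
            hess = X.T @ (X * W[:, None])
            step = np.linalg.solve(hess, grad)
            beta += step
            if np.abs(step).max() < 1e-12:
                break
        se = np.sqrt(np.linalg.inv(hess)[1, 1])
        p_wald = 2 * stats.norm.sf(abs(beta[1] / se))
        assert res.iloc[0]["p_value"] == pytest.approx(p_wald, rel=1e-4)

    def test_separable_continuous_covariate_flagged(self):
        y = np.repeat([0, 1], 20)
        cov = pd.DataFrame({"score": np.concatenate([
            np.linspace(0, 1, 20), np.linspace(2, 3, 20)])})
        with pytest.warns(RuntimeWarning, match="separation"):
            res = screen_confounders(cov, y)
        assert bool(res.iloc[0]["significant"])

    def test_missing_rows_dropped_per_covariate(self):
        y = np.repeat([0, 1], 10)
        vals = np.asarray(y, dtype=float) + np.linspace(0, 0.5, 20)
        vals[0] = np.nan
        cov = pd.DataFrame({"biased": vals, "group": ["a", "b"] * 10})
        res = screen_confounders(cov, y)
        assert len(res) == 2
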