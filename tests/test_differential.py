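"""Permutation-FDR differential abundance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from nmdar_stoich import differential, synthetic
from nmdar_stoich.containers import IntensityMatrix


def make_matrix(values, groups=("A", "A", "A", "B", "B", "B"), ids=None):
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    ids = ids or [f"P{i}" for i in range(n_prot)]
    samples = [f"s{i}" for i in range(n_samp)]
    proteins = pd.DataFrame(
        {"gene": ids, "mw_da": [1e5] * n_prot, "is_histone": [False] * n_prot},
        index=pd.Index(ids, name="protein_id"),
    )
    return IntensityMatrix(
        proteins,
        pd.DataFrame(values, index=proteins.index, columns=samples),
        pd.Series(list(groups), index=samples),
    )


class TestPreprocess:
    def test_log2_transform_and_keep_all(self):
        m = make_matrix([[8.0] * 6, [4.0] * 6])
        log2, _ = differential.preprocess(m)
        assert (log2.loc["P0"] == 3.0).all()
        assert len(log2) == 2

    def test_insufficient_valid_values_excluded(self):
        row = [np.nan, np.nan, 8.0, 8.0, 8.0, 8.0]  # 1 valid in A, 3 in B
        m = make_matrix([row, [8.0] * 6])
        log2, _ = differential.preprocess(m, min_valid=3)
        assert list(log2.index) == ["P1"]
        log2_any, _ = differential.preprocess(m, min_valid=3, min_valid_mode="any")
        assert len(log2_any) == 2

    def test_contaminants_removed(self):
        m = make_matrix([[8.0] * 6, [8.0] * 6], ids=["CON_trypsin", "P1"])
        log2, _ = differential.preprocess(m)
        assert list(log2.index) == ["P1"]


def brute_force_pvalues(values: np.ndarray, n1: int) -> np.ndarray:
    """Independent oracle: full enumeration of group-label assignments
    (identity included), plain pooled-variance t with s0 = 0."""
    n = values.shape[1]
    t_for = {}
    for combo in combinations(range(n), n1):
        idx1 = np.array(combo)
        idx2 = np.setdiff1d(np.arange(n), idx1)
        g1, g2 = values[:, idx1], values[:, idx2]
        v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
        pooled = ((n1 - 1) * v1 + (len(idx2) - 1) * v2) / (n - 2)
        se = np.sqrt(pooled * (1 / n1 + 1 / len(idx2)))
        t_for[combo] = (g2.mean(axis=1) - g1.mean(axis=1)) / se
    obs = np.abs(t_for[tuple(range(n1))])
    counts = np.zeros_like(obs)
    for t in t_for.values():
        counts += (np.abs(t) >= obs).astype(float)
    return counts / len(t_for)


class TestPermutationTest:
    def test_identical_groups_nothing_significant(self):
        m = make_matrix(np.full((5, 6), 64.0))
        log2, groups = differential.preprocess(m)
        res = differential.permutation_fdr_ttest(log2, groups, s0=0.1, seed=0)
        assert (res["t_stat"] == 0).all()
        assert not res["significant"].any()

    def test_pvalues_match_brute_force_enumeration(self):
        """With s0=0 and full enumeration, per-protein permutation
        p-values equal the exhaustive 3-vs-3 oracle exactly."""
        rng = np.random.default_rng(17)
        values = rng.lognormal(10, 1, size=(40, 6))
        values[:5, 3:] *= 8.0  # a few real effects
        m = make_matrix(values)
        log2, groups = differential.preprocess(m)
        res = differential.permutation_fdr_ttest(
            log2, groups, s0=0.0, n_permutations=10**6, seed=0
        )
        expected = brute_force_pvalues(log2.to_numpy(), n1=3)
        np.testing.assert_allclose(res["p_value"].to_numpy(), expected, atol=1e-12)

    def test_invariant_to_constant_shift_and_relabeling(self):
        rng = np.random.default_rng(3)
        values = rng.normal(20, 1, size=(30, 10))
        groups = ["A"] * 5 + ["B"] * 5
        m = make_matrix(2.0**values, groups=groups)
        log2, gr = differential.preprocess(m)
        base = differential.permutation_fdr_ttest(log2, gr, seed=1)
        shifted = differential.permutation_fdr_ttest(log2 + 7.5, gr, seed=1)
        np.testing.assert_allclose(base["q_value"], shifted["q_value"], atol=1e-12)
        # swap two samples within group A: same q-values
        perm_cols = ["s1", "s0", "s2", "s3", "s4", "s5", "s6", "s7", "s8", "s9"]
        relabeled = differential.permutation_fdr_ttest(log2[perm_cols], gr, seed=1)
        np.testing.assert_allclose(
            base["q_value"], relabeled["q_value"], atol=1e-12
        )

    def test_qvalues_monotone_in_abs_t(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(10, 0.5, size=(100, 10))
        m = make_matrix(values, groups=["A"] * 5 + ["B"] * 5)
        log2, gr = differential.preprocess(m)
        res = differential.permutation_fdr_ttest(log2, gr, seed=2)
        ordered = res.reindex(res["t_stat"].abs().sort_values(ascending=False).index)
        assert (np.diff(ordered["q_value"]) >= -1e-12).all()
        assert res["q_value"].between(0, 1).all()

    def test_planted_effects_recovered(self):
        cfg = synthetic.ProteomeSimConfig(
            n_background_proteins=300,
            de_proteins=[(f"BG{i:04d}", 4.0) for i in range(10)]
            + [(f"BG{i:04d}", 0.25) for i in range(10, 20)],
            noise_cv=0.1,
            missing_rate=0.0,
            subunit_copies={"Grin1": (1e6, 1e6), "Grin2a": (8e5, 8e5), "Grin2b": (1e6, 1e6)},
            seed=21,
        )
        matrix, _, truth = synthetic.generate_proteome(cfg)
        log2, gr = differential.preprocess(matrix)
        res = differential.permutation_fdr_ttest(log2, gr, seed=0)
        n_up, n_down, table = differential.classify_hits(res)
        hits = set(table.index[table["hit_class"] != "none"])
        planted = set(truth.de_folds)
        assert len(hits & planted) / len(planted) >= 0.9
        assert n_up >= 9 and n_down >= 9

    def test_bh_alternative(self):
        rng = np.random.default_rng(8)
        values = rng.lognormal(10, 0.5, size=(50, 6))
        m = make_matrix(values)
        log2, gr = differential.preprocess(m)
        res = differential.permutation_fdr_ttest(log2, gr, seed=0, method="bh")
        assert res["q_value"].between(0, 1).all()


class TestClassifyHits:
    def test_empty_significance(self):
        res = pd.DataFrame(
            {"log2_fc": [3.0], "t_stat": [5.0], "q_value": [0.9]},
            index=pd.Index(["P0"], name="protein_id"),
        )
        n_up, n_down, _ = differential.classify_hits(res)
        assert (n_up, n_down) == (0, 0)

    def test_fold_change_threshold_applied(self):
        res = pd.DataFrame(
            {"log2_fc": [1.5, -1.2, 0.5], "t_stat": [9, -9, 9], "q_value": [0.01] * 3},
            index=pd.Index(["P0", "P1", "P2"], name="protein_id"),
        )
        n_up, n_down, table = differential.classify_hits(res, fc_threshold=2)
        assert (n_up, n_down) == (1, 1)
        assert table.loc["P2", "hit_class"] == "none"

    def test_hit_rows_satisfy_both_thresholds(self):
        rng = np.random.default_rng(11)
        res = pd.DataFrame(
            {
                "log2_fc": rng.normal(0, 2, 200),
                "t_stat": rng.normal(0, 3, 200),
                "q_value": rng.uniform(0, 1, 200),
            },
            index=pd.Index([f"P{i}" for i in range(200)], name="protein_id"),
        )
        _, _, table = differential.classify_hits(res, fc_threshold=2, fdr=0.05)
        flagged = table[table["hit_class"] != "none"]
        assert (flagged["q_value"] <= 0.05).all()
        assert (flagged["log2_fc"].abs() >= 1.0).all()

    def test_bad_threshold_rejected(self):
        res = pd.DataFrame(
            {"log2_fc": [1.0], "t_stat": [1.0], "q_value": [0.5]},
            index=pd.Index(["P0"], name="protein_id"),
        )
        with pytest.raises(ValueError, match="fc_threshold"):
            differential.classify_hits(res, fc_threshold=1.0)
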