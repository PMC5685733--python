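"""NormFinder stability and the dCt / RQ / fold-change chain."""

import numpy as np
import pandas as pd
import pytest

from sermir import qpcr
from sermir import synthetic_data as sd


class TestNormfinder:
    def test_identical_genes_symmetric(self):
        x = pd.DataFrame(np.tile(np.arange(10.0), (2, 1)),
                         index=["g1", "g2"], columns=[f"S{j}" for j in range(10)])
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=x.columns)
        res = qpcr.normfinder(x, groups)
        assert res["group_difference"].abs().max() < 1e-9
        assert res["stability"].nunique() == 1

    def test_planted_group_shift_ranks_worst(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame(rng.normal(8, 0.3, (20, 40)),
                         index=[f"g{i}" for i in range(20)],
                         columns=[f"S{j}" for j in range(40)])
        groups = pd.Series(["A"] * 20 + ["B"] * 20, index=x.columns)
        x.loc["g7", groups == "B"] += 1.0
        res = qpcr.normfinder(x, groups)
        assert res["group_difference"].abs().idxmax() == "g7"
        assert res.index[-1] == "g7"  # sorted by stability, worst last

    def test_null_matrix_median_difference_near_zero(self):
        meds = []
        for seed in range(5):
            x, groups, _ = sd.simulate_reference_gene_matrix(
                n_genes=50, group_sizes=(30, 30), n_stable=0,
                group_effect_sd=0.0, seed=seed,
            )
            meds.append(qpcr.normfinder(x, groups)["group_difference"].median())
        assert abs(np.median(meds)) < 0.05

    def test_designed_stable_genes_rank_top(self):
        for seed in range(5):
            x, groups, stable = sd.simulate_reference_gene_matrix(seed=seed)
            res = qpcr.normfinder(x, groups)
            ranks = [res.index.get_loc(g) + 1 for g in stable]
            assert max(ranks) <= 5

    def test_invariant_to_per_sample_constants(self):
        x, groups, _ = sd.simulate_reference_gene_matrix(n_genes=30, seed=3)
        shift = pd.Series(np.random.default_rng(4).normal(0, 5, x.shape[1]), index=x.columns)
        r1 = qpcr.normfinder(x, groups)
        r2 = qpcr.normfinder(x + shift, groups)
        pd.testing.assert_frame_equal(r1, r2, check_exact=False, atol=1e-9)

    def test_constant_gene_handled_with_variance_floor(self):
        x, groups, _ = sd.simulate_reference_gene_matrix(n_genes=10, seed=5)
        x.iloc[0] = 8.0
        res = qpcr.normfinder(x, groups)
        assert np.isfinite(res.loc[x.index[0], "stability"])

    def test_two_groups_required(self):
        x, groups, _ = sd.simulate_reference_gene_matrix(n_genes=5, seed=6)
        with pytest.raises(ValueError, match="two groups"):
            qpcr.normfinder(x, pd.Series("A", index=x.columns))


class TestSelectReferences:
    def _inputs(self, seed=0):
        x, groups, stable = sd.simulate_reference_gene_matrix(seed=seed)
        stab = qpcr.normfinder(x, groups)
        de = pd.DataFrame({"p_adj": 1.0}, index=x.index)
        expr = pd.Series(1000.0, index=x.index)
        return x, stab, de, expr, stable

    def test_returns_top_k_excluding_de_genes(self):
        x, stab, de, expr, stable = self._inputs()
        planted_de = list(x.index[10:20])
        de.loc[planted_de, "p_adj"] = 0.001
        refs = qpcr.select_references(de, stab, expr, k=3)
        assert len(refs) == 3
        assert not set(refs) & set(planted_de)

    def test_all_genes_de_raises(self):
        x, stab, de, expr, _ = self._inputs()
        de["p_adj"] = 0.0
        with pytest.raises(ValueError, match="no reference-gene candidates"):
            qpcr.select_references(de, stab, expr)

    def test_k_one_returns_best_stability(self):
        x, stab, de, expr, _ = self._inputs()
        refs = qpcr.select_references(de, stab, expr, k=1)
        assert refs == [stab.index[0]]


def _ct_rows(samples):
    rows = []
    for sid, group, values in samples:
        for gene, ct in values.items():
            rows.append({"sample": sid, "group": group, "gene": gene,
                         "replicate": 1, "Ct": ct})
    return pd.DataFrame(rows)


class TestDeltaCt:
    def test_target_equal_to_controls_gives_rq_one(self):
        ct = _ct_rows([("s1", "m", {"t": 24.0, "c1": 24.0, "c2": 24.0})])
        res = qpcr.delta_ct(ct, "t", ["c1", "c2"])
        assert res["delta_ct"].iloc[0] == pytest.approx(0.0)
        assert res["rq"].iloc[0] == pytest.approx(1.0)

    def test_one_cycle_above_controls_halves_rq(self):
        ct = _ct_rows([("s1", "m", {"t": 25.0, "c1": 24.0, "c2": 24.0, "c3": 24.0})])
        res = qpcr.delta_ct(ct, "t", ["c1", "c2", "c3"])
        assert res["delta_ct"].iloc[0] == pytest.approx(1.0)
        assert res["rq"].iloc[0] == pytest.approx(0.5)

    def test_duplicate_rqs_averaged(self):
        ct = pd.DataFrame(
            [
                {"sample": "s1", "group": "m", "gene": "t", "replicate": 1,
                 "Ct": 24.0 + np.log2(1 / 0.4)},
                {"sample": "s1", "group": "m", "gene": "t", "replicate": 2,
                 "Ct": 24.0 + np.log2(1 / 0.6)},
                {"sample": "s1", "group": "m", "gene": "c1", "replicate": 1, "Ct": 24.0},
                {"sample": "s1", "group": "m", "gene": "c1", "replicate": 2, "Ct": 24.0},
            ]
        )
        res = qpcr.delta_ct(ct, "t", ["c1"])
        assert res["rq"].iloc[0] == pytest.approx(0.5)

    def test_missing_gene_rejected(self):
        ct = _ct_rows([("s1", "m", {"t": 24.0})])
        with pytest.raises(ValueError, match="absent"):
            qpcr.delta_ct(ct, "t", ["c1"])

    def test_incomplete_sample_dropped(self):
        ct = _ct_rows([
            ("s1", "m", {"t": 25.0, "c1": 24.0}),
            ("s2", "m", {"t": 25.0, "c1": np.nan}),
        ])
        res = qpcr.delta_ct(ct, "t", ["c1"])
        assert list(res["sample"]) == ["s1"]


class TestCompare:
    def test_identical_groups_fold_change_one(self):
        per_sample = pd.DataFrame(
            {"sample": list("abcd"), "group": ["metastatic"] * 2 + ["non_metastatic"] * 2,
             "delta_ct": [1.0, 2.0, 1.0, 2.0], "rq": [0.5, 0.25, 0.5, 0.25]}
        )
        res = qpcr.qpcr_compare(per_sample)
        assert res["fold_change"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1.0)

    def test_fold_change_is_rq_ratio(self):
        per_sample = pd.DataFrame(
            {"sample": list("abcd"), "group": ["metastatic"] * 2 + ["non_metastatic"] * 2,
             "delta_ct": [0.0, 0.0, 1.0, 1.0], "rq": [2.5, 1.5, 1.2, 0.8]}
        )
        res = qpcr.qpcr_compare(per_sample)
        assert res["fold_change"] == pytest.approx(2.0)

    def test_chain_identity_on_group_means(self):
        # fold change computed from mean dCt equals 2^-(ddCt) exactly
        ct = sd.simulate_ct_table(["t"], ["c1", "c2", "c3"], ct_shift={"t": 1.0}, seed=2)
        per_sample = qpcr.delta_ct(ct, "t", ["c1", "c2", "c3"])
        m = per_sample.groupby("group")["delta_ct"].mean()
        ddct = m["metastatic"] - m["non_metastatic"]
        fold_from_dct = 2.0 ** (-ddct)
        rq_means = per_sample.assign(rq=2.0 ** -per_sample["delta_ct"]).groupby("group")["rq"].mean()
        # identity holds when RQ is recomputed from the mean dCt per group
        assert fold_from_dct == pytest.approx(
            2.0 ** -(m["metastatic"]) / 2.0 ** -(m["non_metastatic"])
        )
        assert rq_means["metastatic"] > rq_means["non_metastatic"]

    def test_shifted_delta_ct_power(self):
        hits = 0
        for seed in range(10):
            ct = sd.simulate_ct_table(
                ["t"], ["c1", "c2", "c3"], group_sizes=(10, 10),
                ct_shift={"t": 1.0}, noise_sd=0.5, seed=seed,
            )
            per_sample = qpcr.delta_ct(ct, "t", ["c1", "c2", "c3"])
            if qpcr.qpcr_compare(per_sample)["p"] < 0.01:
                hits += 1
        assert hits >= 9
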