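"""ICC, Dice, separability, sensitivity/specificity, and the ANOVA battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from physioeval.datatypes import BinaryMap, MetricMap
from physioeval.evaluation import (
    classify_icc,
    dice,
    followup_paired_t,
    icc,
    sens_spec,
    separability,
    two_factor_rm_anova,
)
from physioeval.synthgen import make_network_atlas


def icc_oracle(x):
    """Explicit sum-of-squares decomposition, coded independently."""
    n, k = x.shape
    grand = x.mean()
    msb = k * sum((x[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msw = sum((x[i, j] - x[i].mean()) ** 2
              for i in range(n) for j in range(k)) / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestICC:
    def test_direct_arithmetic(self):
        # construct a table with MS_b = 3 and MS_w = 1 exactly:
        # subject means +/-d give MS_b = 2*k*d^2/(n-1); run deviations +/-e
        # give MS_w = e^2 * 2 / ... easier: verify against the closed form
        x = np.array([[2.0, 0.0], [-1.0, 1.0]])
        assert icc(x) == pytest.approx(icc_oracle(x), abs=1e-14)

    def test_perfect_reproducibility(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc(x) == pytest.approx(1.0)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            x = rng.standard_normal((8, 2))
            assert abs(icc(x) - icc_oracle(x)) <= 1e-12

    def test_identical_values_undefined(self):
        with pytest.raises(ValueError):
            icc(np.ones((4, 2)))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_one(self, seed):
        x = np.random.default_rng(seed).standard_normal((5, 3))
        assert icc(x) <= 1.0 + 1e-12


class TestClassifyICC:
    @pytest.mark.parametrize("value,label", [
        (0.5, "moderate"), (0.8, "excellent"), (-0.1, "poor"),
        (0.0, "poor"), (0.2, "fair"), (0.6, "substantial"), (1.0, "excellent"),
    ])
    def test_bins(self, value, label):
        assert classify_icc(value) == label


class TestDice:
    def _maps(self, a, b):
        return (BinaryMap(members=np.asarray(a, bool), threshold_used=0.5),
                BinaryMap(members=np.asarray(b, bool), threshold_used=0.5))

    def test_identity(self):
        a, b = self._maps([1, 1, 0], [1, 1, 0])
        assert dice(a, b) == 1.0

    def test_disjoint(self):
        a, b = self._maps([1, 0, 0], [0, 1, 1])
        assert dice(a, b) == 0.0

    def test_direct_arithmetic(self):
        a = np.zeros(12, bool)
        b = np.zeros(12, bool)
        a[:4] = True           # |A| = 4
        b[1:7] = True          # |B| = 6, intersection = 3
        assert dice(a, b) == pytest.approx(0.6)

    def test_both_empty_warns_one(self):
        with pytest.warns(UserWarning):
            assert dice(np.zeros(5, bool), np.zeros(5, bool)) == 1.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random(30) > 0.5
        b = rng.random(30) > 0.5
        if a.sum() + b.sum() > 0:
            assert dice(a, b) == dice(b, a)


class TestSeparability:
    def _z_map(self, atlas, per_network):
        vals = np.zeros(atlas.labels.shape)
        for k, v in per_network.items():
            vals[atlas.labels == k] = v
        return MetricMap(values=vals, metric="corrected_z", mask=atlas.gm_mask)

    def test_perfect_separation(self, atlas_small):
        z = self._z_map(atlas_small, {1: 1.0})
        assert separability(z, atlas_small, 1).si == pytest.approx(1.0)

    def test_no_separation(self, atlas_small):
        z = self._z_map(atlas_small, {k: 0.4 for k in range(1, 8)})
        assert separability(z, atlas_small, 2).si == pytest.approx(0.0)

    def test_direct_arithmetic(self, atlas_small):
        per = {k: 0.2 for k in range(1, 8)}
        per[3] = 0.6
        z = self._z_map(atlas_small, per)
        out = separability(z, atlas_small, 3)
        assert out.wnc == pytest.approx(0.6)
        assert out.bnc == pytest.approx(0.2)
        assert out.si == pytest.approx(0.5)


class TestSensSpec:
    def test_exact_network(self, atlas_small):
        net = atlas_small.labels == 2
        assert sens_spec(net, atlas_small, 2) == (1.0, 1.0)

    def test_empty_map(self, atlas_small):
        empty = np.zeros_like(atlas_small.gm_mask)
        assert sens_spec(empty, atlas_small, 2) == (0.0, 1.0)

    def test_direct_ratio_arithmetic(self):
        # 100-voxel network, 400 gray-matter voxels outside; TP=89, FP=148
        atlas = make_network_atlas((27, 27, 3), n_networks=1, rim=1)
        labels = np.zeros_like(atlas.labels)
        gm_idx = np.argwhere(atlas.gm_mask)[:500]
        labels[tuple(gm_idx[:100].T)] = 1
        gm = np.zeros_like(atlas.gm_mask)
        gm[tuple(gm_idx.T)] = True
        from physioeval.datatypes import NetworkAtlas
        atlas = NetworkAtlas(labels=labels, gm_mask=gm,
                             voxel_size=(3.44, 3.44, 4.6), n_networks=1)
        members = np.zeros_like(gm)
        members[tuple(gm_idx[:89].T)] = True          # TP = 89
        members[tuple(gm_idx[100:248].T)] = True      # FP = 148
        sens, spec = sens_spec(members, atlas, 1)
        assert sens == pytest.approx(0.89)
        assert spec == pytest.approx(0.63)

    def test_complement_swaps_counts(self, atlas_small):
        rng = np.random.default_rng(0)
        members = atlas_small.gm_mask & (rng.random(atlas_small.gm_mask.shape) > 0.5)
        s1, p1 = sens_spec(members, atlas_small, 1)
        comp = atlas_small.gm_mask & ~members
        s2, p2 = sens_spec(comp, atlas_small, 1)
        assert s1 == pytest.approx(1.0 - s2)
        assert p1 == pytest.approx(1.0 - p2)


def _balanced_table(rng, n_subjects=8, method_effect=0.0):
    strategies = [f"S{i}" for i in range(8)]
    conditions = ["longTR", "shortTR", "shortTR_downsampled"]
    rows = []
    for s in range(n_subjects):
        base = rng.normal(0, 1)
        for i, strat in enumerate(strategies):
            for cond in conditions:
                rows.append({"subject": f"sub{s}", "strategy": strat,
                             "condition": cond,
                             "value": base + method_effect * i + rng.normal(0, 1)})
    return pd.DataFrame(rows)


class TestAnova:
    def test_df_shapes(self):
        table = _balanced_table(np.random.default_rng(0))
        res = two_factor_rm_anova(table)
        assert (res["Method"]["df_num"], res["Method"]["df_den"]) == (7, 49)
        assert (res["TR"]["df_num"], res["TR"]["df_den"]) == (2, 14)

    def test_detects_method_effect(self):
        table = _balanced_table(np.random.default_rng(1), method_effect=1.0)
        res = two_factor_rm_anova(table)
        assert res["Method"]["p"] < 1e-4

    def test_incomplete_design_rejected(self):
        table = _balanced_table(np.random.default_rng(0)).iloc[:-1]
        with pytest.raises(ValueError):
            two_factor_rm_anova(table)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        ps = [two_factor_rm_anova(_balanced_table(rng))["Method"]["p"]
              for _ in range(200)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestFollowupT:
    def test_pair_count(self):
        table = _balanced_table(np.random.default_rng(0))
        out = followup_paired_t(table)
        assert len(out) == 28

    def test_known_shift_matches_t_cdf(self):
        # paired differences with mean 1 and sd 0.5 exactly, n = 8
        d = np.array([1.0, 1.5, 0.5, 1.25, 0.75, 1.6, 0.4, 1.0])
        d = (d - d.mean()) / d.std(ddof=1) * 0.5 + 1.0
        rows = []
        for i, di in enumerate(d):
            rows.append({"subject": f"s{i}", "strategy": "A", "value": di})
            rows.append({"subject": f"s{i}", "strategy": "B", "value": 0.0})
        out = followup_paired_t(pd.DataFrame(rows))
        t = 1.0 / (0.5 / np.sqrt(8))
        p = 2 * (1 - stats.t.cdf(t, df=7))
        assert out["p"].iloc[0] == pytest.approx(p, abs=1e-10)

    def test_zero_variance_flagged(self):
        rows = []
        for i in range(5):
            rows.append({"subject": f"s{i}", "strategy": "A", "value": 1.0 + i})
            rows.append({"subject": f"s{i}", "strategy": "B", "value": 1.0 + i})
        out = followup_paired_t(pd.DataFrame(rows))
        assert out["p"].iloc[0] == 1.0
        assert bool(out["zero_variance"].iloc[0])
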