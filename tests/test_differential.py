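import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myelometh as mm
from myelometh.differential import significant_set

import oracles
from conftest import make_beta, make_sheet


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.05, 0.05, 0.05], [0.05, 0.05, 0.05]),
        ],
    )
    def test_hand_computed(self, p, expected):
        np.testing.assert_allclose(mm.bh_adjust(p), expected, atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            mm.bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200)
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(mm.bh_adjust(p), oracles.bh_stepup(p), atol=1e-12)

    def test_large_random_vector_matches_oracle(self):
        p = np.random.default_rng(5).random(10_000)
        np.testing.assert_allclose(mm.bh_adjust(p), oracles.bh_stepup(p), atol=1e-12)


class TestDifferential:
    def test_identical_groups_yield_no_calls(self):
        rng = np.random.default_rng(0)
        block = rng.random((50, 5))
        beta = make_beta(np.hstack([block, block]))
        sheet = make_sheet({f"s{j}": ("a" if j < 5 else "b") for j in range(10)})
        res = mm.differential(beta, sheet, "a", "b")
        assert np.allclose(res["delta_beta"], 0.0)
        assert (res["class"] == "ns").all()

    def test_boundary_delta_not_classified(self):
        # strict inequality: a delta exactly at the threshold stays
        # unclassified (values chosen binary-exact so the mean difference
        # is the threshold to the last bit)
        x1 = np.tile([0.25, 0.50, 0.75, 0.50], (1, 4))
        x2 = x1 + 0.25
        beta = make_beta(np.hstack([x1, x2]))
        sheet = make_sheet({f"s{j}": ("a" if j < 16 else "b") for j in range(32)})
        res = mm.differential(beta, sheet, "a", "b", delta_threshold=0.25)
        assert res["delta_beta"].iloc[0] == 0.25
        assert res["p_adj"].iloc[0] < 0.05
        assert res["class"].iloc[0] == "ns"
        assert not bool(res["passes_delta_only"].iloc[0])

    def test_degenerate_probe_gets_p_one(self):
        vals = np.vstack([np.full(8, 0.5), np.linspace(0.1, 0.9, 8)])
        beta = make_beta(vals)
        sheet = make_sheet({f"s{j}": ("a" if j < 4 else "b") for j in range(8)})
        res = mm.differential(beta, sheet, "a", "b")
        assert res["p_raw"].iloc[0] == 1.0

    def test_too_few_samples_errors(self):
        beta = make_beta(np.full((3, 3), 0.5))
        sheet = make_sheet({"s0": "a", "s1": "b", "s2": "b"})
        with pytest.raises(ValueError, match=">=2"):
            mm.differential(beta, sheet, "a", "b")

    def test_untestable_probe_flagged(self):
        vals = np.full((2, 6), 0.5)
        vals[0, :3] = [0.2, np.nan, np.nan]  # one usable value in group a
        beta = make_beta(vals)
        sheet = make_sheet({f"s{j}": ("a" if j < 3 else "b") for j in range(6)})
        res = mm.differential(beta, sheet, "a", "b")
        assert not res["testable"].iloc[0]
        assert res["testable"].iloc[1]

    def test_planted_effects_match_naive_oracle(self):
        """Welch p-values and the significant list agree with a per-probe
        scipy reference on a cohort with 50 planted CpGs."""
        rng = np.random.default_rng(42)
        n_probes, n = 1000, 5
        base = rng.uniform(0.2, 0.6, size=n_probes)
        x1 = np.clip(base[:, None] + rng.normal(0, 0.05, (n_probes, n)), 0, 1)
        x2 = np.clip(base[:, None] + rng.normal(0, 0.05, (n_probes, n)), 0, 1)
        planted = rng.choice(n_probes, 50, replace=False)
        x2[planted] = np.clip(x2[planted] + 0.35, 0, 1)
        beta = make_beta(np.hstack([x1, x2]))
        sheet = make_sheet({f"s{j}": ("a" if j < n else "b") for j in range(2 * n)})
        res = mm.differential(beta, sheet, "a", "b")

        deltas, ps = oracles.welch_per_probe(x1, x2)
        np.testing.assert_allclose(res["delta_beta"], deltas, atol=1e-12)
        np.testing.assert_allclose(res["p_raw"], ps, atol=1e-12)
        p_adj = oracles.bh_stepup(ps)
        called = set(res.index[(res["class"] != "ns")])
        expected = {
            beta.probe_ids[i]
            for i in range(n_probes)
            if p_adj[i] < 0.05 and abs(deltas[i]) > 0.20
        }
        assert called == expected
        # the planted CpGs dominate the significant list
        planted_ids = {beta.probe_ids[i] for i in planted}
        assert len(called & planted_ids) / len(planted_ids) > 0.9

    def test_antisymmetry_and_p_invariance(self, small_two_group):
        _, _, beta, sheet, _ = small_two_group
        fwd = mm.differential(beta, sheet, "control", "PMF-JAK2")
        rev = mm.differential(beta, sheet, "PMF-JAK2", "control")
        np.testing.assert_allclose(fwd["delta_beta"], -rev["delta_beta"], atol=1e-14)
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], atol=1e-14)


class TestPairwise:
    def test_three_groups_three_pairs(self):
        rng = np.random.default_rng(1)
        beta = make_beta(rng.random((20, 9)))
        sheet = make_sheet({f"s{j}": "abc"[j // 3] for j in range(9)})
        out = mm.pairwise_comparisons(beta, sheet, ["b", "c", "a"])
        assert set(out) == {("a", "b"), ("a", "c"), ("b", "c")}

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(2)
        beta = make_beta(rng.uniform(0.3, 0.7, (1000, 20)))
        sheet = make_sheet({f"s{j}": ("a" if j < 10 else "b") for j in range(20)})
        res = mm.differential(beta, sheet, "a", "b")
        frac = (res["p_raw"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < 4 * se


class TestSetOverlap:
    def test_disjoint_sets_empty_intersection(self):
        a = mm.CpGSet("a", {"1", "2"})
        b = mm.CpGSet("b", {"3"})
        _, inter = mm.set_overlap([a, b])
        assert len(inter) == 0

    def test_small_partition(self):
        a = mm.CpGSet("a", {"1", "2", "3"})
        b = mm.CpGSet("b", {"2", "3", "4"})
        table, inter = mm.set_overlap([a, b])
        assert inter.probe_ids == {"2", "3"}
        counts = {
            (row["a"], row["b"]): row["count"] for _, row in table.iterrows()
        }
        assert counts == {(True, False): 1, (True, True): 2, (False, True): 1}

    def test_four_random_sets_match_enumeration(self):
        rng = np.random.default_rng(9)
        universe = [str(i) for i in range(1000)]
        sets = [
            set(rng.choice(universe, 200, replace=False)) for _ in range(4)
        ]
        table, inter = mm.set_overlap(
            [mm.CpGSet(f"s{i}", s) for i, s in enumerate(sets)]
        )
        expected = oracles.venn_counts(sets)
        got = {
            tuple(bool(row[f"s{i}"]) for i in range(4)): row["count"]
            for _, row in table.iterrows()
        }
        assert got == expected
        assert inter.probe_ids == frozenset(set.intersection(*sets))


class TestTransfer:
    def _target(self, seed, planted_probes=(), effect=0.0, n_cpgs=600):
        rng = np.random.default_rng(seed)
        probes = [f"cg{i:08d}" for i in range(n_cpgs)]
        base = rng.uniform(0.3, 0.7, n_cpgs)
        x1 = np.clip(base[:, None] + rng.normal(0, 0.04, (n_cpgs, 8)), 0, 1)
        x2 = np.clip(base[:, None] + rng.normal(0, 0.04, (n_cpgs, 8)), 0, 1)
        idx = [probes.index(p) for p in planted_probes]
        x2[idx] += effect
        beta = make_beta(np.clip(np.hstack([x1, x2]), 0, 1), probes=probes)
        sheet = make_sheet({f"s{j}": ("A" if j < 8 else "B") for j in range(16)})
        return beta, sheet, probes

    def test_null_target_near_zero_means(self):
        beta, sheet, probes = self._target(0)
        hyper = mm.CpGSet("hyper", set(probes[:40]), "hyper")
        hypo = mm.CpGSet("hypo", set(probes[40:80]), "hypo")
        out = mm.transfer_set_analysis([hyper, hypo], beta, sheet, "A", "B", seed=1)
        assert abs(out.stratum_means["hyper"]) < 0.02
        assert abs(out.stratum_means["hypo"]) < 0.02
        assert out.anova_p > 0.01

    def test_planted_hypo_effect_recovered(self):
        planted = [f"cg{i:08d}" for i in range(40)]
        beta, sheet, probes = self._target(1, planted, effect=-0.25)
        hypo = mm.CpGSet("hypo", set(planted), "hypo")
        out = mm.transfer_set_analysis(hypo, beta, sheet, "A", "B", seed=1)
        se = 0.04 * np.sqrt(2 / 8) / np.sqrt(40)
        assert out.stratum_means["hypo"] == pytest.approx(-0.25, abs=3 * se)
        assert out.anova_p < 1e-6

    def test_disjoint_source_errors(self):
        beta, sheet, _ = self._target(2)
        foreign = mm.CpGSet("x", {"cgFOREIGN"}, "hypo")
        with pytest.raises(ValueError, match="no probes"):
            mm.transfer_set_analysis(foreign, beta, sheet, "A", "B")


def test_permutation_null_expected_calls(default_cohort):
    """Global-null check: permuting group labels yields, on average over 20
    permutations, no more dual-threshold calls than alpha * n_cpgs."""
    _, _, beta, sheet, _ = default_cohort
    ids = sheet.samples_in_group("control") + sheet.samples_in_group("PMF-JAK2")
    sub = beta.subset_samples(ids)
    rng = np.random.default_rng(123)
    counts = []
    for _ in range(20):
        labels = rng.permutation(["a"] * 40 + ["b"] * 20)
        sheet_p = make_sheet(dict(zip(ids, labels)))
        res = mm.differential(sub, sheet_p, "a", "b")
        counts.append(int((res["class"] != "ns").sum()))
    assert np.mean(counts) <= 0.05 * sub.shape[0]
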