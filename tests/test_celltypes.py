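import numpy as np
import pandas as pd
import pytest

import myelometh as mm
from myelometh.celltypes import CellTypeReference, build_signature_matrix

import oracles
from conftest import make_beta, make_sheet


def ref_from(values, types=None, probes=None):
    values = np.asarray(values, dtype=float)
    types = types or [f"ct{j}" for j in range(values.shape[1])]
    probes = probes or [f"cg{i:08d}" for i in range(values.shape[0])]
    return CellTypeReference(pd.DataFrame(values, index=probes, columns=types))


class TestStableFilter:
    @pytest.mark.parametrize(
        "means,retained",
        [
            ((0.50, 0.55, 0.62), False),  # max pairwise 0.12 > 0.1
            ((0.50, 0.55, 0.58), True),   # max pairwise 0.08
            ((0.50, 0.55, 0.60), True),   # exactly 0.10: inclusive boundary
        ],
    )
    def test_threshold_rule(self, means, retained):
        ref = ref_from([list(means)])
        stable = mm.stable_cpg_filter(ref, 0.10)
        assert (len(stable) == 1) is retained

    def test_missing_mean_excluded(self):
        ref = ref_from([[0.5, np.nan, 0.5]])
        assert len(mm.stable_cpg_filter(ref)) == 0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vals = rng.random((500, 7))
            vals[rng.random((500, 7)) < 0.01] = np.nan
            ref = ref_from(vals)
            got = sorted(mm.stable_cpg_filter(ref, 0.10).probe_ids)
            want = [ref.probe_ids[i]
                    for i in oracles.stable_probes_double_loop(vals, 0.10)]
            assert got == want


class TestApplyFilter:
    def _results(self, probes, classes):
        df = pd.DataFrame({"class": classes}, index=probes)
        df["delta_beta"] = 0.0
        return df

    def test_all_stable_identity(self):
        res = self._results(["a", "b"], ["hyper", "ns"])
        stable = mm.CpGSet("stable", {"a", "b"})
        filtered, counts = mm.apply_stable_filter(res, stable)
        assert len(filtered) == 2
        assert counts["hyper_before"] == counts["hyper_after"] == 1

    def test_empty_stable_set(self):
        res = self._results(["a"], ["hypo"])
        filtered, counts = mm.apply_stable_filter(res, mm.CpGSet("stable", set()))
        assert len(filtered) == 0
        assert counts == {
            "n_before": 1, "n_after": 0, "hyper_before": 0, "hypo_before": 1,
            "hyper_after": 0, "hypo_after": 0,
        }

    def test_composition_confound_removed(self):
        """A cohort whose only group difference is cell composition: before
        filtering many cell-type-variable CpGs are called; after filtering
        calls drop to alpha-level noise."""
        cfg = mm.SimulationConfig(
            n_cpgs=1000,
            groups=("control", "PMF-JAK2"),
            n_samples_per_group=20,
            n_intrinsic_cpgs_per_group={},
            n_signature_cpgs=0,
            burden_linked_cpgs=0,
            n_celltype_variable_cpgs=300,
            seed=21,
        )
        ref = mm.generate_reference(cfg)
        beta, sheet, truth = mm.generate_cohort(cfg, ref)
        res = mm.differential(beta, sheet, "control", "PMF-JAK2")
        called_before = int((res["class"] != "ns").sum())
        delta_passing_variable = int(
            res.loc[truth.probes("celltype-variable"), "passes_delta_only"].sum()
        )
        assert called_before >= delta_passing_variable > 0
        stable = mm.stable_cpg_filter(ref, 0.10)
        filtered, counts = mm.apply_stable_filter(res, stable)
        after = counts["hyper_after"] + counts["hypo_after"]
        assert after <= 0.05 * len(filtered)


class TestSignatureMatrix:
    def test_two_types_one_marker(self):
        ref = ref_from([[0.1, 0.9], [0.5, 0.55], [0.4, 0.4]])
        out = build_signature_matrix(ref, 1)
        assert out.probe_ids == ["cg00000000"]

    def test_planted_markers_selected(self):
        rng = np.random.default_rng(5)
        vals = np.tile(rng.uniform(0.4, 0.6, (50, 1)), (1, 3))
        vals[:5, 0] = 0.95  # strong markers for type 0
        ref = ref_from(vals)
        out = build_signature_matrix(ref, 5)
        assert set(out.probe_ids) >= {f"cg{i:08d}" for i in range(5)}

    def test_oversized_request_warns_and_returns_all(self):
        ref = ref_from(np.random.default_rng(0).random((10, 2)))
        with pytest.warns(UserWarning, match="exceeds probe count"):
            out = build_signature_matrix(ref, 100)
        assert len(out.probe_ids) == 10


class TestDeconvolution:
    def _signature(self, seed=0, n_probes=500, k=5):
        rng = np.random.default_rng(seed)
        # marker-structured profiles: each type deviates at its own probes
        vals = np.tile(rng.uniform(0.3, 0.7, (n_probes, 1)), (1, k))
        for t in range(k):
            idx = slice(t * (n_probes // k), (t + 1) * (n_probes // k))
            vals[idx, t] = np.clip(vals[idx, t] + rng.choice([-0.5, 0.5]), 0.02, 0.98)
        return ref_from(vals)

    def test_pure_sample_recovered(self):
        sig = self._signature()
        y = sig.mean_beta["ct2"]
        res = mm.estimate_fractions(y, sig)
        np.testing.assert_allclose(res.fractions["ct2"], 1.0, atol=1e-9)
        assert res.residual_rmse < 1e-9

    @pytest.mark.parametrize("solver", ["nnls", "qp"])
    def test_even_mixture_recovered(self, solver):
        sig = self._signature()
        y = 0.5 * sig.mean_beta["ct0"] + 0.5 * sig.mean_beta["ct1"]
        res = mm.estimate_fractions(y, sig, solver=solver)
        np.testing.assert_allclose(res.fractions["ct0"], 0.5, atol=1e-6)
        np.testing.assert_allclose(res.fractions["ct1"], 0.5, atol=1e-6)

    def test_random_mixtures_noiseless_exact(self):
        sig = self._signature(1)
        rng = np.random.default_rng(2)
        for _ in range(20):
            f = rng.dirichlet(np.ones(5))
            y = pd.Series(sig.mean_beta.to_numpy() @ f, index=sig.probe_ids)
            res = mm.estimate_fractions(y, sig)
            assert np.max(np.abs(res.fractions.to_numpy() - f)) < 1e-6

    def test_noisy_mixtures_rmse_bound(self):
        from scipy.special import expit, logit

        sig = self._signature(3)
        rng = np.random.default_rng(4)
        errs = []
        for _ in range(100):
            f = rng.dirichlet(np.ones(5))
            y = sig.mean_beta.to_numpy() @ f
            y = expit(logit(np.clip(y, 1e-6, 1 - 1e-6)) + rng.normal(0, 0.05, len(y)))
            res = mm.estimate_fractions(pd.Series(y, index=sig.probe_ids), sig)
            errs.append(res.fractions.to_numpy() - f)
        rmse = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse < 0.05

    def test_simplex_invariants(self):
        sig = self._signature(5)
        rng = np.random.default_rng(6)
        for _ in range(20):
            y = pd.Series(rng.random(len(sig.probe_ids)), index=sig.probe_ids)
            res = mm.estimate_fractions(y, sig)
            assert (res.fractions >= 0).all()
            assert abs(res.fractions.sum() - 1.0) < 1e-8

    def test_rank_deficient_names_types(self):
        vals = np.random.default_rng(7).random((50, 2))
        ref = ref_from(np.hstack([vals, vals[:, :1]]), types=["a", "b", "a2"])
        y = pd.Series(vals[:, 0], index=ref.probe_ids)
        with pytest.raises(ValueError, match="a.*a2|a2.*a"):
            mm.estimate_fractions(y, ref)

    def test_too_few_shared_probes(self):
        sig = self._signature()
        y = pd.Series([0.5, 0.5], index=sig.probe_ids[:2])
        with pytest.raises(ValueError, match="usable shared probes"):
            mm.estimate_fractions(y, sig)


def test_confound_monotone_in_composition_shift():
    """Raising the granulocyte shift between groups strictly increases the
    number of delta-passing CpGs among cell-type-variable probes."""
    counts = []
    for gran in (0.50, 0.80, 0.95):
        rest = (1 - gran) * np.array([0.10, 0.12, 0.06, 0.14, 0.08]) / 0.50
        alpha_d = np.concatenate([[gran], rest]) * 100
        alpha_c = np.array([0.50, 0.10, 0.12, 0.06, 0.14, 0.08]) * 100
        cfg = mm.SimulationConfig(
            n_cpgs=1200,
            groups=("control", "PMF-JAK2"),
            n_samples_per_group=20,
            dirichlet_alpha_per_group={"control": alpha_c, "PMF-JAK2": alpha_d},
            n_intrinsic_cpgs_per_group={},
            n_signature_cpgs=0,
            burden_linked_cpgs=0,
            n_celltype_variable_cpgs=400,
            seed=31,
        )
        ref = mm.generate_reference(cfg)
        beta, sheet, truth = mm.generate_cohort(cfg, ref)
        res = mm.differential(beta, sheet, "control", "PMF-JAK2")
        counts.append(
            int(res.loc[truth.probes("celltype-variable"), "passes_delta_only"].sum())
        )
    assert counts[0] < counts[1] < counts[2]
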