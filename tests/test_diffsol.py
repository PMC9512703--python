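import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import brute_force_bh
from solphos.diffsol import (
    SolubilityProfile,
    bh_adjust,
    classify_proteins,
    compute_rna_bound,
    compute_solubility,
    diff_phospho_vs_protein,
    moderated_diff,
    squeeze_var,
)
from solphos.normalization import (
    fit_apply_normalization,
    select_calibration_subset,
)


def _frame(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])]
    )


class TestBH:
    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=100)
    )
    def test_matches_bruteforce_stepup(self, pvals):
        assert np.allclose(bh_adjust(pvals), brute_force_bh(pvals))

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()

    def test_monotone_after_sort(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=200)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_nan_propagates(self):
        adj = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(adj[1]) and not np.isnan(adj[0])


class TestModeratedDiff:
    def test_identical_groups_not_changing(self):
        rng = np.random.default_rng(0)
        a = _frame(rng.normal(size=(50, 3)))
        res = moderated_diff(a, a.copy(), paired=False)
        assert (res["log2fc"] == 0).all()
        assert (res["call"] == "not_changing").all()

    def test_prior_df_zero_equals_direct_t(self):
        # independent oracle: textbook two-sample pooled t formula
        rng = np.random.default_rng(1)
        a = _frame(rng.normal(size=(200, 3)))
        b = _frame(rng.normal(size=(200, 3)))
        res = moderated_diff(a, b, paired=False, prior_df=0)
        av, bv = a.to_numpy(), b.to_numpy()
        sp2 = (av.var(1, ddof=1) * 2 + bv.var(1, ddof=1) * 2) / 4
        t_direct = (av.mean(1) - bv.mean(1)) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert np.allclose(res["t"], t_direct, atol=1e-9)
        t_sp, p_sp = stats.ttest_ind(av, bv, axis=1)
        assert np.allclose(res["t"], t_sp, atol=1e-9)
        assert np.allclose(res["p_value"], p_sp, atol=1e-9)

    def test_prior_df_zero_paired_equals_direct_t(self):
        rng = np.random.default_rng(2)
        a = _frame(rng.normal(size=(100, 4)))
        b = _frame(rng.normal(size=(100, 4)))
        res = moderated_diff(a, b, paired=True, prior_df=0)
        t_sp, p_sp = stats.ttest_rel(a.to_numpy(), b.to_numpy(), axis=1)
        assert np.allclose(res["t"], t_sp, atol=1e-9)
        assert np.allclose(res["p_value"], p_sp, atol=1e-9)

    def test_null_calibration(self):
        # 2,000 null features: BH-adjusted false-call fraction stays near 0
        rng = np.random.default_rng(11)
        a = _frame(rng.normal(size=(2000, 3)))
        b = _frame(rng.normal(size=(2000, 3)))
        res = moderated_diff(a, b, paired=False)
        frac = float((res["adj_p"] < 0.05).mean())
        mc_se = np.sqrt(0.05 * 0.95 / 2000)
        assert frac <= 0.05 + 3 * mc_se

    def test_moderated_shrinks_toward_ordinary_with_large_prior(self):
        rng = np.random.default_rng(12)
        a = _frame(rng.normal(size=(500, 3)))
        b = _frame(rng.normal(0.2, size=(500, 3)))
        ordinary = moderated_diff(a, b, prior_df=0)
        moderated = moderated_diff(a, b)
        # same effects, different variance pooling
        assert np.allclose(ordinary["log2fc"], moderated["log2fc"])
        assert moderated["df_prior"].iloc[0] > 0

    def test_homoscedastic_noise_gives_large_prior_df(self):
        # equal true variances across features: d0 should be large and
        # moderated ~ ordinary t on average
        rng = np.random.default_rng(13)
        a = _frame(rng.normal(scale=1.0, size=(3000, 3)))
        b = _frame(rng.normal(scale=1.0, size=(3000, 3)))
        res = moderated_diff(a, b)
        assert res["df_prior"].iloc[0] > 3

    def test_too_few_replicates_rejected(self):
        a = _frame(np.ones((5, 1)))
        with pytest.raises(ValueError):
            moderated_diff(a, a, paired=False)

    def test_call_thresholds(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(300, 3)) * 0.05
        a = base.copy()
        a[:30] += 2.0
        res = moderated_diff(_frame(a), _frame(base), paired=True)
        assert (res["call"][:30] == "up").all()
        assert (res["call"][30:] == "not_changing").all()


class TestSqueezeVar:
    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(5)
        s2 = stats.chi2.rvs(3, size=1000, random_state=rng) / 3
        d0, s0sq, post = squeeze_var(s2, 3)
        lo = np.minimum(s2, s0sq) - 1e-12
        hi = np.maximum(s2, s0sq) + 1e-12
        assert ((post >= lo) & (post <= hi)).all()

    def test_recovers_prior_scale(self):
        # variances drawn from s0^2 * chi2_d / d with s0^2 = 4
        rng = np.random.default_rng(6)
        s2 = 4.0 * stats.chi2.rvs(3, size=20000, random_state=rng) / 3
        d0, s0sq, _ = squeeze_var(s2, 3)
        assert s0sq == pytest.approx(4.0, rel=0.1)


def _profile_from(table, truth, method="median"):
    calib = select_calibration_subset(table)
    norm, _ = fit_apply_normalization(table, calib, method=method)
    return compute_solubility(norm)


class TestSolubility:
    def test_equal_channels_s_zero(self, noiseless_dataset):
        table, truth = noiseless_dataset
        profile = _profile_from(table, truth)
        soluble = truth.proteins.index[
            truth.proteins["solubility_class"] == "predominantly_soluble"
        ]
        assert np.allclose(profile.s.loc[soluble], 0.0, atol=1e-9)

    def test_planted_effect_recovered_exactly(self, noiseless_dataset):
        table, truth = noiseless_dataset
        profile = _profile_from(table, truth)
        insens = truth.proteins.index[
            truth.proteins["solubility_class"] == "rnase_insensitive_insoluble"
        ]
        assert np.allclose(profile.s.loc[insens], -1.0, atol=1e-9)

    def test_rna_bound_rescue(self, noiseless_dataset):
        table, truth = noiseless_dataset
        profile = _profile_from(table, truth)
        rbf = compute_rna_bound(profile)
        sens = truth.proteins.index[
            truth.proteins["solubility_class"] == "rnase_sensitive_insoluble"
        ]
        ins = truth.proteins.index[
            truth.proteins["solubility_class"] == "rnase_insensitive_insoluble"
        ]
        assert np.allclose(rbf.loc[sens], -1.0, atol=1e-9)
        assert np.allclose(rbf.loc[ins], 0.0, atol=1e-9)

    def test_manual_ratio_arithmetic(self):
        # NP40 = SDS/2 -> S = -1; preserved ratio 0.25 vs digested 1 -> RBF -2
        cols = {}
        meta = []
        for lys in ("preserved", "digested"):
            for det in ("NP40", "SDS"):
                for rep in (1, 2):
                    sid = f"{det}_{lys}_r{rep}"
                    ratio = 0.25 if (det == "NP40" and lys == "preserved") else 1.0
                    cols[sid] = [np.log2(100.0 * ratio)]
                    meta.append({"sample_id": sid, "detergent": det,
                                 "lysate": lys, "replicate": rep})
        from solphos.normalization import IntensityTable
        table = IntensityTable(
            values=pd.DataFrame(cols, index=["pX"]),
            samples=pd.DataFrame(meta).set_index("sample_id"),
            log2=True,
        )
        profile = compute_solubility(table)
        assert np.allclose(profile.lysate("preserved"), -2.0)
        assert np.allclose(compute_rna_bound(profile), -2.0)

    def test_unmatched_metadata_rejected(self, noiseless_dataset):
        from solphos.normalization import IntensityTable
        table, _ = noiseless_dataset
        bad_samples = table.samples.copy()
        bad_samples.loc[bad_samples.index[0], "detergent"] = "SDS"
        bad = IntensityTable(values=np.log2(table.values),
                             samples=bad_samples, log2=True)
        with pytest.raises(ValueError, match="unmatched"):
            compute_solubility(bad)


class TestClassifyProteins:
    @staticmethod
    def _diff(fc, p, index):
        return pd.DataFrame(
            {"log2fc": fc, "adj_p": p,
             "call": ["down" if f <= -0.5 and q < 0.01 else "not_changing"
                      for f, q in zip(fc, p)]},
            index=index,
        )

    def test_threshold_rules(self):
        idx = pd.Index(["a", "b", "c"])
        # a: ratio 0.6 (log2 -0.737), sig, no rnase change -> insensitive
        # b: ratio 0.9 -> soluble regardless of p
        # c: insoluble + rescued -> sensitive
        pres = self._diff([np.log2(0.6), np.log2(0.9), -1.0],
                          [1e-4, 1e-6, 1e-4], idx)
        dig = self._diff([np.log2(0.6), 0.0, 0.0], [1e-4, 1.0, 1.0], idx)
        rnase = self._diff([0.0, 0.0, -1.0], [1.0, 1.0, 1e-4], idx)
        cls = classify_proteins(pres, dig, rnase)
        assert cls.loc["a", "solubility_class"] == "rnase_insensitive_insoluble"
        assert cls.loc["b", "solubility_class"] == "predominantly_soluble"
        assert cls.loc["c", "solubility_class"] == "rnase_sensitive_insoluble"

    def test_recovery_on_simulated_dataset(self):
        from solphos.pipeline import PipelineConfig, run_pipeline
        from solphos.simulate import SimulationConfig
        cfg = PipelineConfig(
            simulation=SimulationConfig(n_proteins=2000, seed=7)
        )
        summary = run_pipeline(cfg)
        conf = summary["protein_class_confusion"]
        for cls_name, row in conf.items():
            total = sum(row.values())
            assert row.get(cls_name, 0) / total >= 0.95, (cls_name, row)


class TestPhosphoVsProtein:
    def test_zero_noise_shift_recovery(self, noiseless_phospho, noiseless_dataset):
        table, truth = noiseless_dataset
        pep_table, pep_truth = noiseless_phospho
        prot_profile = _profile_from(table, truth)
        pep_it = pep_table.to_intensity_table()
        calib = select_calibration_subset(pep_it)
        pep_norm, _ = fit_apply_normalization(pep_it, calib, method="median")
        pep_profile = compute_solubility(pep_norm)
        res = diff_phospho_vs_protein(
            pep_profile, prot_profile, pep_table.peptides["protein_id"],
            mode="solubility",
        )
        planted = pep_truth.peptides.loc[res.index]
        expected = planted["sol_shift"] + planted["rna_shift"]
        assert np.allclose(res["log2fc"], expected, atol=1e-9)
        rna = diff_phospho_vs_protein(
            pep_profile, prot_profile, pep_table.peptides["protein_id"],
            mode="rna_bound",
        )
        assert np.allclose(
            rna["log2fc"], planted.loc[rna.index, "rna_shift"], atol=1e-9
        )

    def test_sign_convention_insoluble_shift_negative_fc(self, noiseless_phospho,
                                                         noiseless_dataset):
        table, truth = noiseless_dataset
        pep_table, pep_truth = noiseless_phospho
        prot_profile = _profile_from(table, truth)
        pep_it = pep_table.to_intensity_table()
        pep_norm, _ = fit_apply_normalization(
            pep_it, select_calibration_subset(pep_it), method="median"
        )
        res = diff_phospho_vs_protein(
            compute_solubility(pep_norm), prot_profile,
            pep_table.peptides["protein_id"], mode="solubility",
        )
        planted = pep_truth.peptides.loc[res.index]
        more_insoluble = planted[(planted["sol_shift"] + planted["rna_shift"]) < 0]
        assert (res.loc[more_insoluble.index, "log2fc"] < 0).all()

    def test_orphan_peptides_reported(self, noiseless_phospho, noiseless_dataset):
        table, truth = noiseless_dataset
        pep_table, _ = noiseless_phospho
        prot_profile = _profile_from(table, truth)
        pep_it = pep_table.to_intensity_table()
        pep_norm, _ = fit_apply_normalization(
            pep_it, select_calibration_subset(pep_it), method="median"
        )
        pep_profile = compute_solubility(pep_norm)
        mapping = pep_table.peptides["protein_id"].copy()
        mapping.iloc[0] = "NOPE"
        res = diff_phospho_vs_protein(pep_profile, prot_profile, mapping)
        assert mapping.index[0] in res.attrs["orphans"]
        assert mapping.index[0] not in res.index

    def test_planted_effect_sensitivity_and_fdp(self):
        from solphos.simulate import (
            PhosphoSimSpec, SimulationConfig,
            simulate_phospho_dataset, simulate_solubility_dataset,
        )
        cfg = SimulationConfig(n_proteins=1500, noise_sd=0.15, seed=11)
        table, truth = simulate_solubility_dataset(cfg)
        spec = PhosphoSimSpec(mean_sites_per_protein=2.0,
                              fraction_sol_shifted=0.1,
                              fraction_rna_shifted=0.0,
                              qc_fail_fraction=0.0)
        pep_table, pep_truth = simulate_phospho_dataset(truth, spec)
        prot_profile = _profile_from(table, truth, method="glog")
        pep_it = pep_table.to_intensity_table()
        pep_norm, _ = fit_apply_normalization(
            pep_it, select_calibration_subset(pep_it), method="glog"
        )
        res = diff_phospho_vs_protein(
            compute_solubility(pep_norm), prot_profile,
            pep_table.peptides["protein_id"], mode="solubility",
        )
        planted = pep_truth.peptides.loc[res.index]
        truly = planted["sol_shift"] != 0
        called = res["call"] != "not_changing"
        sensitivity = (called & truly).sum() / truly.sum()
        fdp = (called & ~truly).sum() / max(called.sum(), 1)
        assert sensitivity >= 0.9, sensitivity
        assert fdp <= 0.1, fdp
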