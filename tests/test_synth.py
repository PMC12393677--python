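import numpy as np
import pandas as pd
import pytest

from lbptrial import composition, synth


class TestConfigValidation:
    def test_zero_participants_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            synth.CohortConfig(n_participants=0)

    def test_non_integer_arm_ratio_rejected(self):
        with pytest.raises(ValueError, match="arm_ratio"):
            synth.CohortConfig(arm_ratio=(1.5, 1))

    def test_probability_bounds(self):
        with pytest.raises(ValueError, match="lbp_colonization_prob"):
            synth.CohortConfig(lbp_colonization_prob=1.2)

    def test_bad_topic_profiles_rejected(self):
        prof = pd.DataFrame([[0.5, 0.2]], columns=["a", "b"])  # sums to 0.7
        with pytest.raises(ValueError, match="sum to 1"):
            synth.CohortConfig(topic_species_profiles=prof)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        cfg = synth.CohortConfig(n_participants=25, seed=42)
        a = synth.generate_cohort(cfg)
        b = synth.generate_cohort(synth.CohortConfig(n_participants=25,
                                                     seed=42))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        pd.testing.assert_frame_equal(a.cytokines, b.cytokines)
        pd.testing.assert_frame_equal(a.strains, b.strains)

    def test_different_seed_differs(self):
        a = synth.generate_cohort(synth.CohortConfig(n_participants=25,
                                                     seed=1))
        b = synth.generate_cohort(synth.CohortConfig(n_participants=25,
                                                     seed=2))
        assert not a.counts.equals(b.counts)


class TestColonizationEffect:
    def test_null_effect_arms_equal(self):
        """Equal colonization probabilities leave only sampling noise
        between arm-wise week-4 L. crispatus-dominance rates."""
        cfg = synth.CohortConfig(n_participants=450, seed=5,
                                 lbp_colonization_prob=0.2,
                                 placebo_colonization_prob=0.2,
                                 missing_visit_prob=0.0)
        co = synth.generate_cohort(cfg)
        wk4 = co.truth["samples"].query("visit == 'wk4'")
        rates = wk4.groupby("arm")["category"].apply(
            lambda s: (s == "LC_DOM").mean())
        ns = wk4.groupby("arm").size()
        se = np.sqrt(0.2 * 0.8 * (1 / ns["LBP"] + 1 / ns["placebo"]))
        assert abs(rates["LBP"] - rates["placebo"]) < 3.5 * se

    def test_week12_benefit_ratio_in_monte_carlo_band(self):
        """The week-12 arm-wise dominance rates must reproduce the
        configured 0.30 vs 0.09 colonization effect; the acceptance band
        comes from brute-force simulation of the same binomials."""
        cfg = synth.CohortConfig(n_participants=300, seed=9,
                                 lbp_colonization_prob=0.30,
                                 placebo_colonization_prob=0.09,
                                 missing_visit_prob=0.0)
        co = synth.generate_cohort(cfg)
        wk12 = co.truth["samples"].query("visit == 'wk12'")
        k = wk12.groupby("arm")["category"].apply(
            lambda s: (s == "LC_DOM").sum())
        n = wk12.groupby("arm").size()
        ratio = (k["LBP"] / n["LBP"]) / (k["placebo"] / n["placebo"])

        # brute-force binomial oracle for the Monte-Carlo 95% band
        rng = np.random.default_rng(12345)
        sims = (rng.binomial(n["LBP"], 0.30, 4000) / n["LBP"]) / np.maximum(
            rng.binomial(n["placebo"], 0.09, 4000) / n["placebo"], 1e-9)
        lo, hi = np.quantile(sims, [0.025, 0.975])
        assert lo < ratio < hi

    def test_counts_sum_to_depth_and_props_to_one(self, small_cohort):
        sums = small_cohort.counts.sum(axis=1)
        assert (sums > 0).all()
        props = composition.relative_abundance(small_cohort.counts)
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_every_count_sample_has_metadata(self, small_cohort):
        assert small_cohort.counts.index.isin(
            small_cohort.metadata.index).all()

    def test_markov_kernel_goodness_of_fit(self):
        """Observed post-randomization transitions are consistent with the
        configured kernel (chi-square GOF per source category)."""
        from scipy import stats

        cfg = synth.CohortConfig(n_participants=600, seed=21,
                                 persistence_prob=0.7,
                                 missing_visit_prob=0.0)
        co = synth.generate_cohort(cfg)
        truth = co.truth["samples"]
        post = truth[truth["visit"].isin(["wk4", "wk8", "wk12", "wk24"])]
        for arm, p_col in (("LBP", 0.30), ("placebo", 0.09)):
            sub = post[post["arm"] == arm]
            counts, _ = composition.transition_table(
                sub["category"], sub, ["wk4", "wk8", "wk12", "wk24"])
            base = synth._arm_base_distribution(p_col)
            base = {c.value: v for c, v in base.items()}
            for src in counts.index:
                row = counts.loc[src]
                if row.sum() < 30:
                    continue
                expected = []
                for dst in counts.columns:
                    if dst == src:
                        expected.append(0.7)
                    else:
                        others = {c: v for c, v in base.items() if c != src}
                        expected.append(
                            0.3 * others[dst] / sum(others.values()))
                _, p = stats.chisquare(row.values,
                                       row.sum() * np.array(expected))
                assert p > 0.01, f"{arm} {src}: kernel mismatch (p={p:.4f})"


class TestCytokineGeneration:
    def test_independent_noise_when_no_size_factor(self):
        cfg = synth.CohortConfig(
            n_participants=120, seed=3, size_factor_sd=0.0,
            cytokine_effects={a: 0.0 for a in synth.ANALYTES})
        co = synth.generate_cohort(cfg)
        wide = co.cytokines.pivot(index="sample", columns="analyte",
                                  values="concentration")
        corr = np.log10(wide).corr().values
        off = corr[~np.eye(len(corr), dtype=bool)]
        assert np.abs(off).mean() < 0.05

    def test_size_factor_drives_pc1_fraction(self):
        """With a large shared size factor, the leading eigenvalue fraction
        approaches the value implied by the configured variances, computed
        by brute-force eigendecomposition of the implied correlation
        matrix."""
        cfg = synth.CohortConfig(
            n_participants=250, seed=4, size_factor_sd=1.0,
            cytokine_noise_sd=0.35,
            cytokine_effects={a: 0.0 for a in synth.ANALYTES},
            lloq_log10_offset=-np.inf, uloq_log10_offset=np.inf)
        co = synth.generate_cohort(cfg)
        wide = np.log10(co.cytokines.pivot(
            index="sample", columns="analyte", values="concentration"))
        Z = (wide - wide.mean()) / wide.std(ddof=1)
        emp = np.linalg.eigvalsh(np.cov(Z.values.T))[::-1]
        emp_frac = emp[0] / emp.sum()

        p = len(synth.ANALYTES)
        rho = 1.0**2 / (1.0**2 + 0.35**2)
        R = np.full((p, p), rho)
        np.fill_diagonal(R, 1.0)
        theo = np.linalg.eigvalsh(R)[::-1]
        theo_frac = theo[0] / theo.sum()
        assert emp_frac == pytest.approx(theo_frac, abs=0.05)

    def test_infinite_bounds_mean_no_censoring(self):
        cfg = synth.CohortConfig(n_participants=40, seed=6,
                                 lloq_log10_offset=-np.inf,
                                 uloq_log10_offset=np.inf)
        co = synth.generate_cohort(cfg)
        assert (co.cytokines["flag"] == "in_range").all()


class TestStrainGeneration:
    def _transition_states(self, cohort):
        """Per-participant consecutive eligible-visit CTV-05 state pairs."""
        from lbptrial import strains as st

        props = composition.relative_abundance(cohort.counts)
        lc = props[composition.L_CRISPATUS]
        profiles = st.profiles_from_table(cohort.strains, lc)
        meta = cohort.metadata
        lbp = meta[(meta["arm"] == "LBP")
                   & ~meta["visit"].isin(["preMTZ", "postMTZ"])]
        return st.strain_transitions(
            profiles, lbp, ["wk4", "wk8", "wk12", "wk24"])

    def test_zero_takeover_means_no_native_replacement(self):
        cfg = synth.CohortConfig(n_participants=200, seed=8,
                                 native_takeover_prob=0.0,
                                 strain_failure_prob=0.0,
                                 missing_visit_prob=0.0)
        co = synth.generate_cohort(cfg)
        counts, _ = self._transition_states(co)
        assert counts.loc["MIXED", "LOW_CTV05"] == 0
        assert counts.loc["HIGH_CTV05", "LOW_CTV05"] == 0

    def test_zero_false_positive_rate_means_no_placebo_ctv05(self):
        cfg = synth.CohortConfig(n_participants=120, seed=8,
                                 placebo_ctv05_fp_rate=0.0)
        co = synth.generate_cohort(cfg)
        placebo = co.metadata.index[co.metadata["arm"] == "placebo"]
        sub = co.strains[co.strains["sample"].isin(placebo)]
        assert not sub.loc[sub["status"] == "ok", "is_lbp"].any()

    def test_takeover_rate_in_binomial_band(self):
        cfg = synth.CohortConfig(n_participants=500, seed=10,
                                 native_takeover_prob=0.35,
                                 strain_failure_prob=0.0,
                                 missing_visit_prob=0.0)
        co = synth.generate_cohort(cfg)
        counts, _ = self._transition_states(co)
        row = counts.loc["MIXED", ["HIGH_CTV05", "MIXED", "LOW_CTV05"]]
        n = row.sum()
        assert n >= 25, "too few mixed-state pairs to test"
        rate = counts.loc["MIXED", "LOW_CTV05"] / n
        se = np.sqrt(0.35 * 0.65 / n)
        assert abs(rate - 0.35) < 3 * se
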