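"""End-to-end validation computations on synthetic study conditions.

Each function regenerates its inputs and recomputes a headline quantity of
the pipeline from scratch: the published-table benefit ratios from their
2x2 counts, topic-model recovery on a planted four-subcommunity cohort,
size-effect adjustment fidelity, permutation-test calibration, the type-I
error of the heterogeneity F test, multiblock block-importance recovery,
and the strain-category rules on a hand-built threshold fixture.  The test
suite asserts on these quantities and the acceptance script reports them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from lbptrial import (assoc, composition, cytokines, effects, mbplsda,
                      strains, synth, topics)

#: Published 2x2 counts: (treatment successes, n, comparator successes, n)
TABLE1_COUNTS = {
    "lc_wk12": (37, 123, 5, 56),
    "lc_wk24": (39, 113, 4, 52),
    "lacto_wk12": (69, 123, 27, 56),
    "lacto_wk24": (65, 113, 17, 52),
}


def table1_reproduction() -> dict:
    """Benefit ratios, Wald CIs, and arm percentages from the trial's
    published microbiota-endpoint counts."""
    out = {}
    for name, (a, n1, b, n2) in TABLE1_COUNTS.items():
        t = effects.TwoByTwo(a, n1, b, n2)
        est = effects.benefit_ratio(t)
        pct = effects.arm_percentages(t)
        out[name] = {
            "ratio": round(est.ratio, 2),
            "ci_low": round(est.ci_low, 2),
            "ci_high": round(est.ci_high, 2),
            "pct_treatment": pct[0],
            "pct_comparator": pct[1],
            "n": n1 + n2,
        }
    return out


def topic_recovery(seed: int = 0, n_participants: int = 50,
                   k_grid=range(2, 9)) -> dict:
    """Fit the constrained topic model on a 300-sample synthetic cohort
    with four planted non-Lactobacillus subcommunities and report the
    selected K, profile recovery, and the composition-conservation error."""
    cfg = synth.CohortConfig(n_participants=n_participants, seed=seed,
                             depth_median=30_000.0,
                             missing_visit_prob=0.0)
    co = synth.generate_cohort(cfg)
    models = {K: topics.fit_topic_model(co.counts, co.taxonomy, K,
                                        seed=seed)
              for K in k_grid}
    alignment = topics.align_topics(models)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        K = topics.select_K(alignment)
    model = models[4]
    _, tv = topics.match_topics(model.beta, co.truth["nonlacto_profiles"])
    conservation = float(
        (model.p_hat.sum(axis=1)
         - model.Pi_hat.reindex(model.p_hat.index)).abs().max())
    return {
        "selected_K": K,
        "max_tv": float(tv.max()),
        "mean_tv": float(tv.mean()),
        "conservation_error": conservation,
        "n_samples": len(co.counts),
    }


def size_effect_adjustment(seed: int = 0, n_participants: int = 80) -> dict:
    """Generate cytokines with a dominating swab-size factor, run PC1
    subtraction, and measure the residual correlation with the true size
    factor plus sign preservation of the planted microbiota effects."""
    cfg = synth.CohortConfig(n_participants=n_participants, seed=seed,
                             size_factor_sd=1.2,
                             missing_visit_prob=0.0)
    co = synth.generate_cohort(cfg)
    panel = cytokines.impute_out_of_range(co.cytokines)
    cytokines.adjust_panel(panel)
    sf = co.truth["size_factors"].reindex(panel.adjusted.index)
    corr = panel.adjusted.apply(
        lambda col: np.corrcoef(col.values, sf.values)[0, 1])
    lacto = co.truth["samples"]["lacto_prop"].reindex(panel.adjusted.index)
    preserved, total = 0, 0
    for analyte, effect in cfg.cytokine_effects.items():
        if effect == 0 or analyte not in panel.adjusted.columns:
            continue
        slope = np.polyfit(lacto.values, panel.adjusted[analyte].values,
                           1)[0]
        total += 1
        preserved += int(np.sign(slope) == np.sign(effect))
    return {
        "max_abs_corr_with_size_factor": float(corr.abs().max()),
        "sign_preserved_fraction": preserved / total,
        "pc1_variance_fraction": float(panel.variance_fractions[0]),
        "n_samples": len(panel.adjusted),
    }


def rv_calibration(seed: int = 0, n: int = 80, n_replicates: int = 500,
                   n_perm: int = 199) -> dict:
    """Null calibration of the RV permutation test: under independent
    tables the p-value must be uniform; RV of a table with itself is 1."""
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for b in range(n_replicates):
        X = rng.normal(size=(n, 5))
        Y = rng.normal(size=(n, 4))
        res = assoc.rv_permutation_test(X, Y, n_perm=n_perm,
                                        seed=int(rng.integers(2**31)))
        pvals[b] = res.p_value
    ks = stats.kstest(pvals, "uniform")
    X = rng.normal(size=(n, 5))
    return {
        "ks_p": float(ks.pvalue),
        "rv_self": assoc.rv_coefficient(X, X),
        "mean_null_p": float(pvals.mean()),
        "n_replicates": n_replicates,
    }


def heterogeneity_calibration(seed: int = 0, n: int = 180,
                              n_replicates: int = 1000) -> dict:
    """Type-I error of the analysis-of-deviance F test under a null with
    four strata and a real arm effect but no interaction."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        arm = pd.Series(np.where(rng.random(n) < 2 / 3, "LBP", "placebo"))
        strata = rng.integers(0, 4, n)
        C = pd.get_dummies(pd.Series(strata), prefix="s",
                           drop_first=True).astype(float)
        eta = -1.0 + 0.8 * (arm == "LBP").values
        y = pd.Series(rng.binomial(1, 1 / (1 + np.exp(-eta))))
        res = effects.heterogeneity_test(y, arm, C)
        rejections += res.p_value < 0.05
    bh = effects.bh_adjust([0.01, 0.02, 0.03, 0.04])
    return {
        "type1_error": rejections / n_replicates,
        "bh_matches_hand_computation": bool(
            np.allclose(bh, [0.04, 0.04, 0.04, 0.04])),
        "n_replicates": n_replicates,
    }


def mbplsda_block_recovery(seed: int = 0, n_replicates: int = 50,
                           n_participants: int = 120) -> dict:
    """Across replicate cohorts, how often does the previous-visit
    (post-MTZ) environment block — the one built to drive week-4
    colonization — attain the top relative cumulative importance?"""
    hits = 0
    for rep in range(n_replicates):
        co = synth.generate_cohort(synth.CohortConfig(
            n_participants=n_participants, seed=seed * 100_003 + rep))
        part = co.truth["participants"]
        y = part["wk4_category"].loc[part["arm"] == "LBP"]
        blocks = {b: df.loc[y.index]
                  for b, df in co.covariate_blocks.items()}
        fit = mbplsda.fit_mbplsda(blocks, y, n_components=2)
        hits += fit.relative_importance.idxmax() == "post_mtz_environment"
    return {"top_block_rate": hits / n_replicates,
            "n_replicates": n_replicates}


def _two_component_blocks(rng, n=120, noise=0.9):
    """Blocks whose class signal lives in a planted 2-D latent space."""
    y = pd.Series(rng.integers(0, 3, n)).map({0: "A", 1: "B", 2: "C"})
    lat = pd.get_dummies(y).values @ np.array(
        [[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
    lat = lat + 0.8 * rng.normal(size=(n, 2))
    load = rng.normal(size=(2, 4))
    sig = lat @ load + noise * rng.normal(size=(n, 4))
    blocks = {
        "noise1": pd.DataFrame(rng.normal(size=(n, 8)),
                               columns=[f"n1_{i}" for i in range(8)]),
        "signal": pd.DataFrame(sig, columns=[f"s{i}" for i in range(4)]),
        "noise2": pd.DataFrame(rng.normal(size=(n, 8)),
                               columns=[f"n2_{i}" for i in range(8)]),
    }
    return blocks, y


def cv_component_selection(seed: int = 0, n_replicates: int = 5) -> dict:
    """Modal cross-validated component count on data generated from a
    two-component latent structure."""
    selections = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(seed * 7919 + rep)
        blocks, y = _two_component_blocks(rng)
        cv = mbplsda.cross_validate(blocks, y, component_grid=(1, 2, 3, 4),
                                    n_splits=40, seed=seed * 31 + rep)
        selections.append(cv.selected_components)
    modal = int(pd.Series(selections).mode().iloc[0])
    return {"modal_components": modal, "selections": selections,
            "n_replicates": n_replicates}


def strain_rule_fixture() -> dict:
    """Hand-built fixture exercising every strain-category threshold and
    the consecutive-visit transition rules."""
    cases = [
        # (L. crispatus abundance, CTV-05 fraction, expected category)
        (0.40, 0.95, "HIGH_CTV05"),
        (0.40, 0.9000001, "HIGH_CTV05"),
        (0.40, 0.90, "MIXED"),       # inclusive upper Mixed boundary
        (0.40, 0.50, "MIXED"),
        (0.40, 0.10, "MIXED"),       # inclusive lower Mixed boundary
        (0.40, 0.0999, "LOW_CTV05"),
        (0.40, 0.00, "LOW_CTV05"),
        (0.049, 0.99, "UNDETERMINED"),  # below the 5% eligibility floor
        (0.05, 0.99, "HIGH_CTV05"),     # floor itself is eligible
    ]
    correct = 0
    for lc, ctv, expected in cases:
        fr = {"CTV-05": ctv, "native": 1.0 - ctv}
        if ctv == 0.0:
            fr = {"native": 1.0}
        prof = strains.StrainProfile(
            "s", lc, fr, {k: k == "CTV-05" for k in fr})
        correct += strains.categorize_strains(prof).value == expected

    # transition fixture: HIGH -> HIGH -> below-floor, with a gap elsewhere
    profiles, meta_rows = {}, []
    seq = [("p1", "wk4", 0.6, 0.95), ("p1", "wk8", 0.5, 0.95),
           ("p1", "wk12", 0.02, 0.0),
           ("p2", "wk4", 0.6, 0.5), ("p2", "wk12", 0.6, 0.05)]
    for pid, visit, lc, ctv in seq:
        s = f"{pid}_{visit}"
        fr = {"CTV-05": ctv, "native": 1 - ctv} if ctv > 0 else \
            {"native": 1.0}
        profiles[s] = strains.StrainProfile(
            s, lc, fr, {k: k == "CTV-05" for k in fr})
        meta_rows.append({"participant": pid, "visit": visit})
    meta = pd.DataFrame(meta_rows, index=list(profiles))
    counts, _ = strains.strain_transitions(
        profiles, meta, ["wk4", "wk8", "wk12", "wk24"])
    transitions_ok = (
        counts.loc["HIGH_CTV05", "HIGH_CTV05"] == 1
        and counts.loc["HIGH_CTV05", strains.LT5_LABEL] == 1
        and counts.values.sum() == 2  # the p2 gap contributes no pair
    )
    return {
        "category_accuracy": correct / len(cases),
        "n_cases": len(cases),
        "transitions_ok": bool(transitions_ok),
    }
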