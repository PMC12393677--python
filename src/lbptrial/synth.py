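"""Synthetic trial cohorts with the structure the analysis stages assume.

The generator emulates a 2:1-randomized longitudinal trial of a vaginal
live-biotherapeutic product (LBP) containing *L. crispatus* CTV-05, given
after a course of metronidazole (MTZ): topic-structured species compositions,
post-antibiotic biomass collapse, an arm-dependent *L. crispatus*
colonization effect at week 4 that then evolves under a Markov persistence
model, cytokines contaminated by a latent swab-size factor and censored at
limits of quantification, and LBP-strain / native-strain replacement
dynamics.  Latent states are recorded in a ``truth`` table so parameter
recovery can be tested downstream.

Every random draw flows from a single seed through
``numpy.random.SeedSequence`` stream splitting, so the cytokine and strain
tables can be regenerated independently of the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lbptrial.composition import ColonizationCategory, L_CRISPATUS

VISITS = ["preMTZ", "postMTZ", "wk4", "wk8", "wk12", "wk24"]

LACTO_SPECIES = [
    L_CRISPATUS,
    "Lactobacillus iners",
    "Lactobacillus jensenii",
    "Lactobacillus gasseri",
    "Lactobacillus mulieris",
]

NONLACTO_SPECIES = [
    "Ca. Lachnocurva vaginae",
    "Gardnerella swidsinskii/leopoldii",
    "Gardnerella vaginalis",
    "Prevotella amnii",
    "Prevotella bivia",
    "Prevotella timonensis",
    "Fannyhessea vaginae",
    "Sneathia amnii",
    "Megasphaera lornae",
    "Mobiluncus mulieris",
    "Dialister micraerophilus",
    "Peptoniphilus lacrimalis",
]

ANALYTES = [
    "IL-1a", "IL-1b", "TNF-a", "IL-6", "IL-8",
    "IP-10", "MIG", "ITAC", "MIP-1a", "MIP-1b", "MIP-3a",
]

#: Per-analyte slope of log10 concentration on total Lactobacillus
#: proportion.  Pro-inflammatory analytes fall as Lactobacillus rises;
#: the interferon-induced chemokines rise with it; IL-6 is flat.
DEFAULT_CYTOKINE_EFFECTS = {
    "IL-1a": -0.6, "IL-1b": -0.8, "TNF-a": -0.7, "IL-6": 0.0, "IL-8": -0.3,
    "IP-10": 0.8, "MIG": 0.7, "ITAC": 0.6,
    "MIP-1a": -0.2, "MIP-1b": -0.2, "MIP-3a": -0.3,
}

_ANALYTE_BASE = {
    "IL-1a": 1.6, "IL-1b": 2.0, "TNF-a": 0.8, "IL-6": 1.2, "IL-8": 2.6,
    "IP-10": 2.2, "MIG": 1.8, "ITAC": 0.9, "MIP-1a": 1.1, "MIP-1b": 1.4,
    "MIP-3a": 1.7,
}


def default_taxonomy() -> pd.DataFrame:
    """Species-level taxonomy table with genus and Lactobacillus flags."""
    rows = []
    for sp in LACTO_SPECIES:
        rows.append({"species": sp, "genus": "Lactobacillus",
                     "is_lactobacillus": True})
    for sp in NONLACTO_SPECIES:
        rows.append({"species": sp, "genus": sp.split(" ")[0],
                     "is_lactobacillus": False})
    return pd.DataFrame(rows).set_index("species")


def default_nonlacto_profiles() -> pd.DataFrame:
    """Four planted non-Lactobacillus topic profiles (rows sum to 1).

    One topic each dominated by *Ca.* Lachnocurva vaginae (BVAB1),
    *G. swidsinskii/leopoldii*, *P. amnii*, and *P. bivia* — the anaerobe
    consortia typical of BV-like communities.
    """
    p = pd.DataFrame(0.0, index=["T_BVAB1", "T_Gsl", "T_Pamnii", "T_Pbivia"],
                     columns=NONLACTO_SPECIES)
    p.loc["T_BVAB1", ["Ca. Lachnocurva vaginae", "Megasphaera lornae",
                      "Sneathia amnii", "Prevotella timonensis",
                      "Dialister micraerophilus"]] = [0.62, 0.12, 0.10, 0.09, 0.07]
    p.loc["T_Gsl", ["Gardnerella swidsinskii/leopoldii", "Gardnerella vaginalis",
                    "Fannyhessea vaginae", "Prevotella bivia",
                    "Peptoniphilus lacrimalis"]] = [0.58, 0.15, 0.12, 0.08, 0.07]
    p.loc["T_Pamnii", ["Prevotella amnii", "Sneathia amnii",
                       "Prevotella timonensis", "Mobiluncus mulieris",
                       "Megasphaera lornae"]] = [0.60, 0.13, 0.11, 0.09, 0.07]
    p.loc["T_Pbivia", ["Prevotella bivia", "Gardnerella vaginalis",
                       "Dialister micraerophilus", "Fannyhessea vaginae",
                       "Mobiluncus mulieris"]] = [0.56, 0.15, 0.11, 0.10, 0.08]
    return p.div(p.sum(axis=1), axis=0)


@dataclass
class CohortConfig:
    """Parameters of the synthetic trial cohort.

    Defaults mirror the trial design and reported cohort features: 213
    analyzable participants randomized 2:1, six scheduled visits, four
    non-Lactobacillus subcommunities, a 30% vs 9% arm-wise chance of
    durable *L. crispatus*-dominant colonization, sequencing depth
    log-normal around a median of 31,000 reads, and a swab-size factor
    large enough to dominate the leading principal component of the
    cytokine panel.
    """

    n_participants: int = 213
    arm_ratio: tuple[int, int] = (2, 1)
    visits: tuple[str, ...] = tuple(VISITS)
    K_topics: int = 4
    topic_species_profiles: pd.DataFrame | None = None
    lbp_colonization_prob: float = 0.30
    placebo_colonization_prob: float = 0.09
    persistence_prob: float = 0.70
    native_takeover_prob: float = 0.35
    size_factor_sd: float = 0.5
    cytokine_noise_sd: float = 0.35
    cytokine_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CYTOKINE_EFFECTS))
    missing_visit_prob: float = 0.05
    lloq_log10_offset: float = -1.3   # LLOQ = 10**(base + offset); -inf disables
    uloq_log10_offset: float = 1.6    # ULOQ = 10**(base + offset); +inf disables
    depth_median: float = 31_000.0
    depth_log_sd: float = 0.4
    dirichlet_scale: float = 50.0
    strain_failure_prob: float = 0.08
    placebo_ctv05_fp_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        a, b = self.arm_ratio
        if a != int(a) or b != int(b) or a <= 0 or b <= 0:
            raise ValueError("arm_ratio must be a pair of positive integers")
        for name in ("lbp_colonization_prob", "placebo_colonization_prob",
                     "persistence_prob", "native_takeover_prob",
                     "missing_visit_prob", "strain_failure_prob",
                     "placebo_ctv05_fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.visits) != len(set(self.visits)):
            raise ValueError("visit labels must be unique and ordered")
        if self.topic_species_profiles is not None:
            prof = self.topic_species_profiles
            if (prof.values < 0).any() or not np.allclose(
                    prof.sum(axis=1), 1.0):
                raise ValueError("topic profiles must be nonnegative and "
                                 "sum to 1 per topic")


@dataclass
class SyntheticCohort:
    """Bundle of generated tables plus the latent truth record."""

    counts: pd.DataFrame            # samples x species integer counts
    taxonomy: pd.DataFrame          # species -> genus, is_lactobacillus
    metadata: pd.DataFrame          # sample -> participant, arm, visit, ...
    cytokines: pd.DataFrame         # tidy: sample, analyte, concentration, ...
    strains: pd.DataFrame           # tidy: sample, strain_id, fraction, is_lbp
    covariate_blocks: dict[str, pd.DataFrame]
    truth: dict

    def validate(self) -> None:
        if not self.counts.index.isin(self.metadata.index).all():
            raise ValueError("counts contain samples missing from metadata")


# --- latent category process ----------------------------------------------

_PRE_MTZ_DIST = {ColonizationCategory.LC_DOM: 0.01,
                 ColonizationCategory.OTHER_LACTO_DOM: 0.04,
                 ColonizationCategory.NON_LACTO_DOM: 0.95}
_POST_MTZ_DIST = {ColonizationCategory.LC_DOM: 0.02,
                  ColonizationCategory.OTHER_LACTO_DOM: 0.70,
                  ColonizationCategory.NON_LACTO_DOM: 0.28}

_CATS = [ColonizationCategory.LC_DOM, ColonizationCategory.OTHER_LACTO_DOM,
         ColonizationCategory.NON_LACTO_DOM]


def _arm_base_distribution(p_col: float) -> dict[ColonizationCategory, float]:
    """Post-randomization category distribution given colonization prob."""
    return {ColonizationCategory.LC_DOM: p_col,
            ColonizationCategory.OTHER_LACTO_DOM: 0.55 * (1 - p_col),
            ColonizationCategory.NON_LACTO_DOM: 0.45 * (1 - p_col)}


def _draw_from(rng: np.random.Generator, dist: dict) -> ColonizationCategory:
    cats = list(dist)
    probs = np.array([dist[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=probs / probs.sum())]


def _markov_step(rng: np.random.Generator, current: ColonizationCategory,
                 base: dict, persistence: float) -> ColonizationCategory:
    # Stay with the persistence probability; otherwise redraw from the
    # arm's base distribution restricted to the other two categories, so
    # the diagonal of the empirical transition table equals `persistence`
    # and arm-wise marginals stay near the configured colonization rates.
    if rng.random() < persistence:
        return current
    others = {c: p for c, p in base.items() if c is not current}
    return _draw_from(rng, others)


def _category_topic_mean(cat: ColonizationCategory, K: int,
                         preferred_topic: int) -> np.ndarray:
    """Mean weight over [4 Lactobacillus topics] + [K non-Lacto topics]."""
    w = np.zeros(4 + K)
    if cat is ColonizationCategory.LC_DOM:
        w[:4] = [0.76, 0.05, 0.02, 0.02]
        w[4:] = 0.15 / K
    elif cat is ColonizationCategory.OTHER_LACTO_DOM:
        w[:4] = [0.05, 0.62, 0.05, 0.04]
        w[4:] = 0.24 / K
    else:
        w[:4] = [0.02, 0.07, 0.02, 0.02]
        w[4:] = 0.27 / K
        w[4 + preferred_topic] += 0.60
    return w / w.sum()


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    The per-visit pipeline is: (i) a latent colonization category from the
    arm-dependent Markov persistence model, (ii) topic weights from a
    category-conditioned Dirichlet (concentration = ``dirichlet_scale`` times
    the category's mean mix), (iii) species counts from a multinomial over
    the mixed topic profiles at a log-normally distributed depth.  Bacterial
    load collapses at the post-MTZ visit (wide, low-median) and rebounds at
    later visits (narrow, high-median).  Reproducible given ``config.seed``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_design = np.random.default_rng(streams[0])
    rng_comp = np.random.default_rng(streams[1])
    rng_missing = np.random.default_rng(streams[2])

    taxonomy = default_taxonomy()
    profiles = (config.topic_species_profiles
                if config.topic_species_profiles is not None
                else default_nonlacto_profiles())
    K = len(profiles)
    if config.topic_species_profiles is None and K != config.K_topics:
        # trim/extend default grid only when K differs from 4
        raise ValueError("K_topics != 4 requires explicit "
                         "topic_species_profiles")

    species = LACTO_SPECIES + list(profiles.columns)
    n_species = len(species)

    # full-community profile per topic: 4 pure/pooled Lactobacillus topics
    # followed by the K non-Lactobacillus topics
    lacto_topic_profiles = np.zeros((4, n_species))
    lacto_topic_profiles[0, species.index(L_CRISPATUS)] = 1.0
    lacto_topic_profiles[1, species.index("Lactobacillus iners")] = 1.0
    lacto_topic_profiles[2, species.index("Lactobacillus jensenii")] = 1.0
    # "Other L." pooled topic over the remaining Lactobacillus species
    lacto_topic_profiles[3, species.index("Lactobacillus gasseri")] = 0.6
    lacto_topic_profiles[3, species.index("Lactobacillus mulieris")] = 0.4
    nonlacto_full = np.zeros((K, n_species))
    for k, (_, row) in enumerate(profiles.iterrows()):
        for sp, v in row.items():
            nonlacto_full[k, species.index(sp)] = v
    topic_profiles = np.vstack([lacto_topic_profiles, nonlacto_full])

    # participants and arms (2:1 interleaved assignment)
    a, b = config.arm_ratio
    participants = [f"P{i:04d}" for i in range(config.n_participants)]
    arms = ["LBP" if (i % (a + b)) < a else "placebo"
            for i in range(config.n_participants)]

    # latent colonization propensity; week-4 category via its quantiles so
    # arm-wise marginals equal the configured colonization probabilities
    u = rng_design.normal(size=config.n_participants)
    preferred = rng_design.integers(0, K, size=config.n_participants)

    meta_rows, count_rows, truth_rows = [], [], []
    category_seq: dict[str, dict[str, ColonizationCategory]] = {}
    for i, (pid, arm) in enumerate(zip(participants, arms)):
        p_col = (config.lbp_colonization_prob if arm == "LBP"
                 else config.placebo_colonization_prob)
        base = _arm_base_distribution(p_col)
        t1 = stats.norm.ppf(p_col)
        t2 = stats.norm.ppf(
            p_col + base[ColonizationCategory.OTHER_LACTO_DOM])
        seq = {}
        for visit in config.visits:
            if visit == "preMTZ":
                cat = _draw_from(rng_design, _PRE_MTZ_DIST)
            elif visit == "postMTZ":
                cat = _draw_from(rng_design, _POST_MTZ_DIST)
            elif visit == "wk4":
                if u[i] < t1:
                    cat = ColonizationCategory.LC_DOM
                elif u[i] < t2:
                    cat = ColonizationCategory.OTHER_LACTO_DOM
                else:
                    cat = ColonizationCategory.NON_LACTO_DOM
            else:
                cat = _markov_step(rng_design, cat, base,
                                   config.persistence_prob)
            seq[visit] = cat
        category_seq[pid] = seq

    for i, (pid, arm) in enumerate(zip(participants, arms)):
        for visit in config.visits:
            if rng_missing.random() < config.missing_visit_prob:
                continue
            cat = category_seq[pid][visit]
            sample = f"{pid}_{visit}"
            mean = _category_topic_mean(cat, K, preferred[i])
            weights = rng_comp.dirichlet(config.dirichlet_scale * mean)
            mix = weights @ topic_profiles
            depth = int(np.round(config.depth_median
                                 * np.exp(rng_comp.normal(
                                     0.0, config.depth_log_sd))))
            counts = rng_comp.multinomial(depth, mix / mix.sum())
            props = counts / depth
            lacto_prop = props[:len(LACTO_SPECIES)].sum()
            lc_prop = props[species.index(L_CRISPATUS)]

            if visit == "postMTZ":
                load = 2.69 + 2.0 * u[i] + rng_comp.normal(0.0, 2.5)
                ph = 4.9 + 0.5 * u[i] + rng_comp.normal(0.0, 0.4)
            else:
                load = rng_comp.normal(7.52, 0.62)
                ph = {ColonizationCategory.LC_DOM: 4.0,
                      ColonizationCategory.OTHER_LACTO_DOM: 4.4,
                      ColonizationCategory.NON_LACTO_DOM: 5.2}[cat] \
                    + rng_comp.normal(0.0, 0.3)
            if visit == "preMTZ":
                load = rng_comp.normal(7.3, 0.6)

            meta_rows.append({
                "sample": sample, "participant": pid, "arm": arm,
                "visit": visit,
                "bv_flag": cat is ColonizationCategory.NON_LACTO_DOM
                and rng_comp.random() < 0.5,
                "ph": round(max(ph, 3.5), 2),
                "log10_bacterial_load": round(max(load, 0.0), 3),
            })
            count_rows.append(pd.Series(counts, index=species, name=sample))
            truth_rows.append({
                "sample": sample, "participant": pid, "arm": arm,
                "visit": visit, "category": cat.value,
                "lacto_prop": lacto_prop, "lc_prop": lc_prop,
                "topic_weights": weights,
            })

    counts_df = pd.DataFrame(count_rows)
    counts_df.index.name = "sample"
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    truth_samples = pd.DataFrame(
        [{k: v for k, v in r.items() if k != "topic_weights"}
         for r in truth_rows]).set_index("sample")

    truth = {
        "samples": truth_samples,
        "topic_weights": pd.DataFrame(
            np.vstack([r["topic_weights"] for r in truth_rows]),
            index=truth_samples.index,
            columns=["LC", "L_iners", "L_jensenii", "Other_L"]
            + list(profiles.index)),
        "topic_profiles": pd.DataFrame(
            topic_profiles,
            index=["LC", "L_iners", "L_jensenii", "Other_L"]
            + list(profiles.index), columns=species),
        "nonlacto_profiles": profiles,
        "participants": pd.DataFrame({
            "participant": participants, "arm": arms,
            "colonization_propensity": u,
            "wk4_category": [category_seq[p]["wk4"].value
                             for p in participants],
        }).set_index("participant"),
    }

    cytokines = generate_cytokines(truth, config, streams[3])
    strains_df = generate_strains(truth, config, streams[4])
    blocks = _covariate_blocks(truth, metadata, config, streams[5])

    cohort = SyntheticCohort(
        counts=counts_df, taxonomy=taxonomy, metadata=metadata,
        cytokines=cytokines, strains=strains_df,
        covariate_blocks=blocks, truth=truth)
    cohort.validate()
    return cohort


# --- cytokines --------------------------------------------------------------

def generate_cytokines(truth: dict, config: CohortConfig,
                       seed=None) -> pd.DataFrame:
    """Tidy cytokine table with a latent swab-size factor and LOQ censoring.

    log10 concentration = analyte base + size factor + effect x
    (total Lactobacillus proportion) + noise.  Values outside the per-analyte
    quantification limits are reported at the limit with a censoring flag.
    """
    rng = np.random.default_rng(config.seed * 7919 + 11 if seed is None
                                else seed)
    samples = truth["samples"]
    size_factor = pd.Series(
        rng.normal(0.0, config.size_factor_sd, size=len(samples)),
        index=samples.index, name="size_factor")
    truth["size_factors"] = size_factor

    rows = []
    for analyte in ANALYTES:
        base = _ANALYTE_BASE[analyte]
        effect = config.cytokine_effects.get(analyte, 0.0)
        lloq = 10.0 ** (base + config.lloq_log10_offset)
        uloq = (np.inf if np.isinf(config.uloq_log10_offset)
                else 10.0 ** (base + config.uloq_log10_offset))
        if lloq >= uloq:
            raise ValueError(f"inverted LOQ bounds for {analyte}")
        log10c = (base + size_factor.values
                  + effect * samples["lacto_prop"].values
                  + rng.normal(0.0, config.cytokine_noise_sd,
                               size=len(samples)))
        conc = 10.0 ** log10c
        flag = np.where(conc < lloq, "below_lloq",
                        np.where(conc > uloq, "above_uloq", "in_range"))
        reported = np.where(flag == "below_lloq", lloq,
                            np.where(flag == "above_uloq", uloq, conc))
        for s, c, f in zip(samples.index, reported, flag):
            rows.append({"sample": s, "analyte": analyte,
                         "concentration": c, "flag": f,
                         "lloq": lloq, "uloq": uloq})
    return pd.DataFrame(rows)


# --- strains ----------------------------------------------------------------

_STRAIN_STATES = ["HIGH", "MIXED", "LOW"]


def generate_strains(truth: dict, config: CohortConfig,
                     seed=None) -> pd.DataFrame:
    """Tidy strain-proportion table for samples with >= 5% *L. crispatus*.

    LBP-arm samples carry CTV-05 / native-strain mixtures whose CTV-05
    share evolves across visits: mixed states resolve to native dominance
    with ``native_takeover_prob`` per visit and native dominance is never
    re-taken by CTV-05.  Placebo samples carry native strains only, apart
    from a configurable small false-positive CTV-05 rate.
    """
    rng = np.random.default_rng(config.seed * 7919 + 13 if seed is None
                                else seed)
    samples = truth["samples"]
    n_native_choices = np.array([0, 1, 2, 3])
    n_native_probs = np.array([0.30, 0.45, 0.18, 0.07])

    rows = []
    n_native_by_pid = {}
    for pid, grp in samples.groupby("participant", sort=False):
        arm = grp["arm"].iloc[0]
        n_native = int(rng.choice(n_native_choices, p=n_native_probs))
        if arm == "placebo" and n_native == 0:
            n_native = 1  # placebo L. crispatus must come from somewhere
        n_native_by_pid[pid] = n_native
        native_ids = [f"{pid}_native{j+1}" for j in range(n_native)]
        state = None
        order = {v: i for i, v in enumerate(config.visits)}
        for s, row in grp.sort_values(
                "visit", key=lambda v: v.map(order)).iterrows():
            if row["lc_prop"] < 0.05:
                state = state  # category resets only via eligibility
                continue
            failed = rng.random() < config.strain_failure_prob
            if failed:
                rows.append({"sample": s, "strain_id": "NA",
                             "fraction": np.nan, "is_lbp": False,
                             "status": "failed"})
                continue
            pre_randomization = row["visit"] in ("preMTZ", "postMTZ")
            if arm == "placebo" or pre_randomization:
                fp = rng.random() < config.placebo_ctv05_fp_rate
                ctv = rng.uniform(0.01, 0.09) if fp else 0.0
            else:
                if state is None:
                    state = rng.choice(_STRAIN_STATES,
                                       p=[0.80, 0.15, 0.05])
                else:
                    state = _strain_step(rng, state,
                                         config.native_takeover_prob)
                if n_native == 0:
                    state = "HIGH"
                ctv = {"HIGH": rng.uniform(0.905, 1.0),
                       "MIXED": rng.uniform(0.12, 0.88),
                       "LOW": rng.uniform(0.0, 0.095)}[state]
            fracs = {}
            if ctv > 0:
                fracs["CTV-05"] = ctv
            if 1.0 - ctv > 1e-12 and native_ids:
                shares = rng.dirichlet(np.full(len(native_ids), 2.0))
                for nid, sh in zip(native_ids, shares):
                    fracs[nid] = (1.0 - ctv) * sh
            elif not native_ids:
                fracs["CTV-05"] = 1.0
            tot = sum(fracs.values())
            for sid, f in fracs.items():
                rows.append({"sample": s, "strain_id": sid,
                             "fraction": f / tot,
                             "is_lbp": sid == "CTV-05", "status": "ok"})
    truth["n_native_strains"] = pd.Series(n_native_by_pid,
                                          name="n_native_strains")
    return pd.DataFrame(
        rows, columns=["sample", "strain_id", "fraction", "is_lbp", "status"])


def _strain_step(rng: np.random.Generator, state: str,
                 takeover: float) -> str:
    if state == "HIGH":
        return "MIXED" if rng.random() < 0.15 else "HIGH"
    if state == "MIXED":
        if rng.random() < takeover:
            return "LOW"
        # CTV-05 essentially never re-takes a mixed community
        return "HIGH" if rng.random() < 0.04 else "MIXED"
    return "LOW"


# --- covariate blocks -------------------------------------------------------

def _covariate_blocks(truth: dict, metadata: pd.DataFrame,
                      config: CohortConfig, seed) -> dict[str, pd.DataFrame]:
    """Participant-level thematic covariate blocks for the MB-PLS-DA stage.

    The post-MTZ environment block (bacterial load, pH, alpha diversity at
    the randomization visit) is driven by the same latent propensity that
    determines the week-4 colonization category, so it is the truly
    discriminative block; demographics and behavior are pure noise.
    """
    rng = np.random.default_rng(seed)
    part = truth["participants"]
    u = part["colonization_propensity"].values
    n = len(part)

    demographics = pd.DataFrame({
        "age": rng.normal(31, 6, n).round(1),
        "education_years": rng.normal(14, 2.5, n).round(1),
        "parity": rng.integers(0, 4, n),
    }, index=part.index)

    pre_env = pd.DataFrame({
        "pre_mtz_ph": (5.4 + rng.normal(0, 0.4, n)).round(2),
        "pre_mtz_alpha_div": (1.8 + rng.normal(0, 0.4, n)).round(3),
    }, index=part.index)

    post_env = pd.DataFrame({
        "post_mtz_load": (2.69 + 2.0 * u + rng.normal(0, 2.0, n)).round(3),
        "post_mtz_ph": (4.9 + 0.5 * u + rng.normal(0, 0.35, n)).round(2),
        "post_mtz_alpha_div": (1.0 + 0.45 * u
                               + rng.normal(0, 0.4, n)).round(3),
    }, index=part.index)

    behavior = pd.DataFrame({
        "sex_acts_per_week": rng.poisson(1.5, n),
        "douching": rng.binomial(1, 0.15, n),
        "adherence_pct": rng.uniform(70, 100, n).round(1),
    }, index=part.index)

    return {"demographics": demographics,
            "pre_mtz_environment": pre_env,
            "post_mtz_environment": post_env,
            "behavior": behavior}


# --- IO ---------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write counts as TSV and the tidy tables as CSV under ``outdir``."""
    import json
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.counts.to_csv(out / "counts.tsv", sep="\t")
    cohort.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t")
    cohort.metadata.to_csv(out / "metadata.csv")
    cohort.cytokines.to_csv(out / "cytokines.csv", index=False)
    cohort.strains.to_csv(out / "strains.csv", index=False)
    for name, block in cohort.covariate_blocks.items():
        block.to_csv(out / f"block_{name}.csv")
    truth_json = {
        "participants": cohort.truth["participants"].to_dict(orient="index"),
    }
    (out / "truth.json").write_text(json.dumps(truth_json, default=str))
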