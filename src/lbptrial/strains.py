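"""LBP-strain vs native-strain category dynamics.

Strain inference is only attempted on samples whose total *L. crispatus*
relative abundance reaches 5%; eligible samples are classified by the
fractional abundance of the LBP strain (CTV-05): above 90% "High-CTV-05",
10-90% "Mixed", below 10% "Low-CTV-05" (i.e. native-strain dominance).
Boundary fractions of exactly 0.9 or 0.1 fall in Mixed.  Transitions are
tabulated across consecutive scheduled post-randomization visits, with a
"below-eligibility" destination for visits dropping under the 5% floor.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LT5_LABEL = "LT5_LCRISPATUS"  # < 5% L. crispatus: inference not attempted


class StrainCategory(str, enum.Enum):
    HIGH_CTV05 = "HIGH_CTV05"
    MIXED = "MIXED"
    LOW_CTV05 = "LOW_CTV05"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class StrainProfile:
    """Per-sample strain composition with eligibility bookkeeping."""

    sample: str
    lc_abundance: float             # total L. crispatus relative abundance
    fractions: dict[str, float]     # strain id -> fractional abundance
    is_lbp: dict[str, bool]
    status: str = "ok"              # ok | failed | not_attempted

    def __post_init__(self) -> None:
        if self.status == "ok":
            tot = sum(self.fractions.values())
            if abs(tot - 1.0) > 1e-6:
                raise ValueError(
                    f"strain fractions of {self.sample} sum to {tot:.4f}, "
                    "not 1")

    @property
    def ctv05_fraction(self) -> float:
        return sum(f for s, f in self.fractions.items() if self.is_lbp[s])


def categorize_strains(profile: StrainProfile,
                       eligibility_floor: float = 0.05) -> StrainCategory:
    """Classify a sample's strain state.

    UNDETERMINED when *L. crispatus* is below the eligibility floor or
    inference failed; otherwise by the CTV-05 fraction with an inclusive
    Mixed band at [0.1, 0.9].
    """
    if profile.lc_abundance < eligibility_floor:
        return StrainCategory.UNDETERMINED
    if profile.status != "ok":
        return StrainCategory.UNDETERMINED
    f = profile.ctv05_fraction
    if f > 0.9:
        return StrainCategory.HIGH_CTV05
    if f >= 0.1:
        return StrainCategory.MIXED
    return StrainCategory.LOW_CTV05


def profiles_from_table(strain_table: pd.DataFrame,
                        lc_abundance: pd.Series,
                        eligibility_floor: float = 0.05
                        ) -> dict[str, StrainProfile]:
    """Build :class:`StrainProfile` objects from a tidy strain table.

    ``strain_table`` has columns (sample, strain_id, fraction, is_lbp) and
    optionally ``status``; ``lc_abundance`` maps every sample of interest to
    its total *L. crispatus* relative abundance.  Samples under the
    eligibility floor or absent from the table become ``not_attempted``.
    """
    profiles: dict[str, StrainProfile] = {}
    by_sample = dict(tuple(strain_table.groupby("sample", sort=False)))
    for sample, lc in lc_abundance.items():
        grp = by_sample.get(sample)
        if lc < eligibility_floor or grp is None:
            profiles[sample] = StrainProfile(sample, float(lc), {}, {},
                                             status="not_attempted")
            continue
        if "status" in grp.columns and (grp["status"] == "failed").any():
            profiles[sample] = StrainProfile(sample, float(lc), {}, {},
                                             status="failed")
            continue
        fr = dict(zip(grp["strain_id"], grp["fraction"].astype(float)))
        lbp = dict(zip(grp["strain_id"], grp["is_lbp"].astype(bool)))
        tot = sum(fr.values())
        fr = {s: f / tot for s, f in fr.items()}
        profiles[sample] = StrainProfile(sample, float(lc), fr, lbp)
    return profiles


def strain_transitions(
    profiles: dict[str, StrainProfile],
    metadata: pd.DataFrame,
    visit_order: list[str],
    participant_col: str = "participant",
    visit_col: str = "visit",
    eligibility_floor: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strain-category transition table over consecutive scheduled visits.

    Rows are the category at visit t, columns the category at visit t+1,
    including a below-eligibility destination/source for samples under the
    *L. crispatus* floor.  Pairs whose second visit had a technically failed
    inference are excluded; a pair is only formed from two consecutively
    scheduled visits both present in the metadata.
    """
    labels = [c.value for c in (StrainCategory.HIGH_CTV05,
                                StrainCategory.MIXED,
                                StrainCategory.LOW_CTV05)] + [LT5_LABEL]

    def label_of(p: StrainProfile) -> str | None:
        if p.lc_abundance < eligibility_floor:
            return LT5_LABEL
        if p.status != "ok":
            return None  # failed inference: pair unusable
        return categorize_strains(p, eligibility_floor).value

    rank = {v: i for i, v in enumerate(visit_order)}
    counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    meta = metadata.loc[[s for s in metadata.index if s in profiles]]
    n_pairs = 0
    for _, grp in meta.groupby(participant_col, sort=False):
        obs = {rank[v]: s for s, v in grp[visit_col].items() if v in rank}
        for r in sorted(obs):
            if r + 1 not in obs:
                continue
            a = label_of(profiles[obs[r]])
            b = label_of(profiles[obs[r + 1]])
            if a is None or b is None:
                continue
            counts.loc[a, b] += 1
            n_pairs += 1
    if n_pairs == 0:
        logger.warning("no usable consecutive visit pairs")
    props = counts.div(counts.sum(axis=1).replace(0, np.nan), axis=0)
    return counts, props


def native_strain_histogram(
    profiles: dict[str, StrainProfile],
    metadata: pd.DataFrame,
    participant_col: str = "participant",
    detection_floor: float = 0.1,
) -> pd.Series:
    """Participants by number of distinct native strains ever detected.

    A native (non-LBP) strain counts when it reaches the detection floor
    (default 10% fractional abundance) in at least one of the participant's
    samples; the histogram is keyed 0, 1, 2, "3+".
    """
    meta = metadata.loc[[s for s in metadata.index if s in profiles]]
    hist = {0: 0, 1: 0, 2: 0, "3+": 0}
    for _, grp in meta.groupby(participant_col, sort=False):
        native: set[str] = set()
        any_ok = False
        for s in grp.index:
            p = profiles[s]
            if p.status != "ok":
                continue
            any_ok = True
            native |= {sid for sid, f in p.fractions.items()
                       if not p.is_lbp[sid] and f >= detection_floor}
        if not any_ok:
            continue
        n = len(native)
        hist[n if n < 3 else "3+"] += 1
    return pd.Series(hist, name="n_participants")
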