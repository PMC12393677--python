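"""Compositional primitives for sample x species count tables.

Counts live in a pandas DataFrame (rows = samples, columns = species); the
taxonomy is a DataFrame indexed by species with a ``genus`` column and an
``is_lactobacillus`` flag.  All downstream modules consume the proportion
tables and colonization categories produced here.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd

L_CRISPATUS = "Lactobacillus crispatus"


class ColonizationCategory(str, enum.Enum):
    """Three-way vaginal community classification.

    ``LC_DOM``
        *L. crispatus*-dominant: >= 50% *L. crispatus* relative abundance.
    ``OTHER_LACTO_DOM``
        *Lactobacillus*-dominant but not *L. crispatus*-dominant: summed
        *Lactobacillus* genus >= 50% while *L. crispatus* < 50%.
    ``NON_LACTO_DOM``
        Summed *Lactobacillus* < 50%.
    """

    LC_DOM = "LC_DOM"
    OTHER_LACTO_DOM = "OTHER_LACTO_DOM"
    NON_LACTO_DOM = "NON_LACTO_DOM"


def validate_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Check that a taxonomy table has genus and Lactobacillus annotations."""
    missing = {"genus", "is_lactobacillus"} - set(taxonomy.columns)
    if missing:
        raise ValueError(f"taxonomy is missing columns: {sorted(missing)}")
    if taxonomy["genus"].isna().any():
        bad = taxonomy.index[taxonomy["genus"].isna()].tolist()
        raise ValueError(f"taxonomy rows without genus: {bad}")
    return taxonomy


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a sample x species count table to row-wise proportions.

    Raises
    ------
    ValueError
        If any sample has an all-zero row (its composition is undefined);
        the error message names the offending sample(s).
    """
    if (counts.values < 0).any():
        raise ValueError("count table contains negative entries")
    totals = counts.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"samples with zero total count: {list(zero.index)}"
        )
    return counts.div(totals, axis=0)


def lactobacillus_fraction(
    proportions: pd.DataFrame, taxonomy: pd.DataFrame
) -> pd.Series:
    """Summed *Lactobacillus*-genus proportion per sample."""
    validate_taxonomy(taxonomy)
    lacto = taxonomy.index[taxonomy["is_lactobacillus"].astype(bool)]
    cols = [c for c in proportions.columns if c in set(lacto)]
    return proportions[cols].sum(axis=1)


def classify_colonization(
    proportions: pd.DataFrame,
    taxonomy: pd.DataFrame,
    threshold: float = 0.5,
) -> pd.Series:
    """Assign each sample a :class:`ColonizationCategory`.

    The threshold is inclusive on both rules (>= 50% counts as dominant).
    Scale-invariant: passing raw counts gives the same categories as
    proportions because only ratios to the row total enter the rules.
    """
    validate_taxonomy(taxonomy)
    props = relative_abundance(proportions) if not np.allclose(
        proportions.sum(axis=1), 1.0, atol=1e-6
    ) else proportions
    lc = props.get(L_CRISPATUS, pd.Series(0.0, index=props.index))
    lacto = lactobacillus_fraction(props, taxonomy)
    out = pd.Series(
        ColonizationCategory.NON_LACTO_DOM, index=props.index, dtype=object
    )
    out[lacto >= threshold] = ColonizationCategory.OTHER_LACTO_DOM
    out[lc >= threshold] = ColonizationCategory.LC_DOM
    return out


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity, 1 - sum(min(p_v, q_v)), for proportions.

    For relative-abundance vectors this equals the classical
    count-based formula.  Inputs must cover the same species in the
    same order (pandas Series are aligned by index first).
    """
    if isinstance(p, pd.Series) and isinstance(q, pd.Series):
        if set(p.index) != set(q.index):
            raise ValueError("species sets differ between the two vectors")
        q = q.reindex(p.index)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("mismatched species sets")
    # clamp float noise so the value stays in [0, 1]
    return float(min(1.0, max(0.0, 1.0 - np.minimum(p, q).sum())))


def bray_curtis_matrix(proportions: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Bray-Curtis dissimilarity for a proportion table."""
    x = proportions.values
    # 1 - sum min(p, q) pairwise; vectorized over sample pairs
    n = x.shape[0]
    d = np.empty((n, n))
    for i in range(n):
        d[i] = 1.0 - np.minimum(x, x[i]).sum(axis=1)
        d[i, i] = 0.0
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)  # symmetry + range vs float noise
    return pd.DataFrame(d, index=proportions.index, columns=proportions.index)


def alpha_diversity(
    proportions: pd.DataFrame, index: str = "shannon"
) -> pd.Series:
    """Per-sample alpha diversity.

    ``shannon`` (default) is entropy in nats, -sum p ln p; ``simpson`` is
    1 - sum p^2; ``richness`` counts species with nonzero proportion.
    """
    x = proportions.values.astype(float)
    if index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(x > 0, x * np.log(x), 0.0)
        vals = -terms.sum(axis=1)
    elif index == "simpson":
        vals = 1.0 - (x**2).sum(axis=1)
    elif index == "richness":
        vals = (x > 0).sum(axis=1).astype(float)
    else:
        raise ValueError(f"unknown diversity index: {index!r}")
    return pd.Series(vals, index=proportions.index, name=index)


def transition_table(
    categories: pd.Series,
    metadata: pd.DataFrame,
    visit_order: list[str],
    participant_col: str = "participant",
    visit_col: str = "visit",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category transition counts across consecutive scheduled visits.

    ``categories`` is indexed by sample ID; ``metadata`` maps sample ID to
    participant and visit.  A pair contributes only when a participant was
    observed at two *consecutive* scheduled visits: a missing middle visit
    breaks the chain, so no pair spans the gap.

    Returns ``(counts, row_proportions)`` with rows = category at visit t,
    columns = category at visit t+1.
    """
    meta = metadata.loc[categories.index]
    dup = meta.duplicated(subset=[participant_col, visit_col])
    if dup.any():
        raise ValueError(
            "duplicate (participant, visit) rows: "
            f"{meta.loc[dup, [participant_col, visit_col]].values.tolist()}"
        )
    rank = {v: i for i, v in enumerate(visit_order)}
    levels = sorted({str(c) for c in categories}, key=str)
    counts = pd.DataFrame(0, index=levels, columns=levels, dtype=int)
    for _, grp in meta.groupby(participant_col, sort=False):
        obs = {rank[v]: s for s, v in grp[visit_col].items() if v in rank}
        for r in sorted(obs):
            if r + 1 in obs:
                a = str(categories.loc[obs[r]])
                b = str(categories.loc[obs[r + 1]])
                counts.loc[a, b] += 1
    row_tot = counts.sum(axis=1)
    props = counts.div(row_tot.replace(0, np.nan), axis=0)
    return counts, props
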