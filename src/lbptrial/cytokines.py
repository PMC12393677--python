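"""Cytokine panel preprocessing: LOQ handling, exclusion, PC1 adjustment.

Immunoassay concentrations (pg/mL) arrive in a tidy table with per-analyte
lower and upper limits of quantification (LLOQ/ULOQ) and censoring flags.
Processing follows the standard sequence for swab-eluate panels: censored
values are imputed (LLOQ/2 below, ULOQ above), concentrations are
log10-transformed, heavily censored analytes are excluded, and the shared
"size effect" — between-swab variation in collected biomass that inflates
all analytes jointly — is removed by zeroing the first principal component
of the standardized log matrix and back-transforming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["sample", "analyte", "concentration", "flag",
                    "lloq", "uloq"]


@dataclass
class CytokinePanel:
    """Wide log10-concentration matrix plus censoring bookkeeping.

    ``log10`` is samples x analytes after imputation; ``flags`` the matching
    censoring flags; ``included`` the per-analyte inclusion indicator;
    ``adjusted`` the PC1-subtracted matrix (None until adjustment runs).
    """

    log10: pd.DataFrame
    flags: pd.DataFrame
    loq: pd.DataFrame               # analyte -> lloq, uloq
    included: pd.Series | None = None
    adjusted: pd.DataFrame | None = None
    variance_fractions: np.ndarray | None = None


def impute_out_of_range(tidy: pd.DataFrame) -> CytokinePanel:
    """Impute censored entries and log10-transform a tidy cytokine table.

    Below-LLOQ entries are set to LLOQ/2 and above-ULOQ entries to the ULOQ
    before the log transform; in-range values pass through unchanged.
    """
    missing = set(REQUIRED_COLUMNS) - set(tidy.columns)
    if missing:
        raise ValueError(f"cytokine table missing columns: {sorted(missing)}")
    t = tidy.copy()
    if ((t["flag"] != "in_range") & (t["lloq"].isna() | t["uloq"].isna())).any():
        raise ValueError("censored entry without LOQ metadata")
    if (t["lloq"] >= t["uloq"]).any():
        bad = t.loc[t["lloq"] >= t["uloq"], "analyte"].unique()
        raise ValueError(f"inverted LOQ bounds for analytes: {list(bad)}")
    value = t["concentration"].astype(float).copy()
    value[t["flag"] == "below_lloq"] = t.loc[t["flag"] == "below_lloq",
                                             "lloq"] / 2.0
    value[t["flag"] == "above_uloq"] = t.loc[t["flag"] == "above_uloq",
                                             "uloq"]
    t["log10"] = np.log10(value)
    log10 = t.pivot(index="sample", columns="analyte", values="log10")
    flags = t.pivot(index="sample", columns="analyte", values="flag")
    loq = t.groupby("analyte")[["lloq", "uloq"]].first()
    return CytokinePanel(log10=log10, flags=flags, loq=loq)


def exclude_analytes(panel: CytokinePanel,
                     lloq_frac: float = 0.6,
                     uloq_frac: float = 0.3) -> pd.Series:
    """Flag analytes too censored to analyze.

    An analyte is excluded when the fraction of samples below the LLOQ is
    >= ``lloq_frac`` or the fraction above the ULOQ is >= ``uloq_frac``
    (both thresholds inclusive).  Returns the inclusion indicator and
    stores it on the panel.
    """
    below = (panel.flags == "below_lloq").mean(axis=0)
    above = (panel.flags == "above_uloq").mean(axis=0)
    included = ~((below >= lloq_frac) | (above >= uloq_frac))
    panel.included = included
    n_out = int((~included).sum())
    if n_out:
        logger.info("excluding %d analytes: %s", n_out,
                    list(included.index[~included]))
    return included


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant analyte column; exclude it before PCA")
    return (X - mu) / sd, mu, sd


def pc1_subtract(log_matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove the size effect by annihilating the first principal component.

    Columns are standardized, the first right-singular direction is removed
    by setting its scores to zero (equivalently subtracting the rank-1 term
    t1 p1'), and the result is mapped back to the log10 scale with the
    original column means and standard deviations.  The adjusted matrix has
    numerically zero projection onto the removed axis.
    """
    if log_matrix.shape[1] < 2 or log_matrix.shape[0] < 3:
        raise ValueError("PC1 subtraction needs >= 3 samples and >= 2 "
                         "analytes")
    if log_matrix.isna().any().any():
        raise ValueError("missing values in the PCA input")
    Z, mu, sd = _standardize(log_matrix.values.astype(float))
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    Z_adj = Z - np.outer(U[:, 0] * s[0], Vt[0])
    X_adj = Z_adj * sd + mu
    return pd.DataFrame(X_adj, index=log_matrix.index,
                        columns=log_matrix.columns)


def variance_explained(log_matrix: pd.DataFrame) -> np.ndarray:
    """Per-component variance fractions of the standardized log matrix."""
    Z, _, _ = _standardize(log_matrix.values.astype(float))
    s = np.linalg.svd(Z, compute_uv=False)
    frac = s**2 / (s**2).sum()
    return frac


def adjust_panel(panel: CytokinePanel,
                 subtract_pc1: bool = True) -> CytokinePanel:
    """Run exclusion and (optionally) PC1 subtraction on a panel.

    With ``subtract_pc1=False`` the adjusted matrix is the unadjusted
    included-analyte log matrix — the sensitivity mode in which downstream
    contrasts are recomputed without size-effect removal.
    """
    if panel.included is None:
        exclude_analytes(panel)
    X = panel.log10.loc[:, panel.included[panel.included].index]
    panel.variance_fractions = variance_explained(X)
    panel.adjusted = pc1_subtract(X) if subtract_pc1 else X.copy()
    return panel


def baseline_delta(
    adjusted: pd.DataFrame,
    metadata: pd.DataFrame,
    baseline_visit: str = "preMTZ",
    participant_col: str = "participant",
    visit_col: str = "visit",
) -> pd.DataFrame:
    """Within-participant change from the baseline visit.

    Returns a long table (participant, visit, analyte, delta) where
    delta(v) = adjusted(v) - adjusted(baseline).  Participants without a
    baseline measurement are dropped and counted in the log.
    """
    meta = metadata.loc[adjusted.index]
    rows = []
    dropped = 0
    for pid, grp in meta.groupby(participant_col, sort=False):
        base_rows = grp.index[grp[visit_col] == baseline_visit]
        if len(base_rows) == 0:
            dropped += 1
            continue
        base = adjusted.loc[base_rows[0]]
        for s in grp.index:
            visit = grp.loc[s, visit_col]
            delta = adjusted.loc[s] - base
            for analyte, d in delta.items():
                rows.append({"participant": pid, "visit": visit,
                             "analyte": analyte, "delta": d})
    if dropped:
        logger.info("dropped %d participants without a %s visit",
                    dropped, baseline_visit)
    return pd.DataFrame(rows)
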