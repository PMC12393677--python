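"""Multiblock PLS discriminant analysis with block importance.

Explanatory variables are grouped into thematic blocks (demographics,
baseline vaginal environment, previous-visit environment, behavior, ...).
A super-block NIPALS algorithm extracts latent components maximizing
covariance between a weighted combination of block scores and the one-hot
encoded response; squared super-level block weights, accumulated over
components and weighted by the response variance each component explains,
give the cumulative block importance (BIPC).  Dividing by each block's
share of the variables yields a relative importance index whose
variable-share-weighted mean is 1 by construction — the "all variables
equally important" null line.

Component count is chosen by repeated random calibration/validation splits
scored by macro-averaged F1, and block-importance uncertainty by a
participant-level bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import f1_score

logger = logging.getLogger(__name__)


# --- encoding helpers -------------------------------------------------------

def one_hot_jitter(categorical: pd.DataFrame, seed: int = 0,
                   sparse_min: int = 5,
                   noise_var_ratio: float = 1e-3) -> pd.DataFrame:
    """One-hot encode categorical variables, jittering sparse columns.

    Each category level becomes a 0/1 column.  Columns with fewer than
    ``sparse_min`` positive entries receive Gaussian noise with variance
    ``noise_var_ratio`` times the column's empirical variance, which keeps
    near-constant indicators from destabilizing refits under resampling.
    Single-level variables are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    pieces = []
    for col in categorical.columns:
        levels = categorical[col].astype("category")
        if len(levels.cat.categories) < 2:
            logger.warning("dropping single-level variable %r", col)
            continue
        enc = pd.get_dummies(levels, prefix=col).astype(float)
        pieces.append(enc)
    if not pieces:
        return pd.DataFrame(index=categorical.index)
    out = pd.concat(pieces, axis=1)
    for col in out.columns:
        x = out[col].values
        if x.sum() < sparse_min:
            var = x.var(ddof=1)
            if var > 0:
                out[col] = x + rng.normal(
                    0.0, np.sqrt(noise_var_ratio * var), size=len(x))
    return out


def residualize_block(target: pd.DataFrame, predictor: pd.DataFrame,
                      n_components: int = 2) -> pd.DataFrame:
    """Replace a block by its residuals after PLS regression on another.

    The residual block carries the part of ``target`` not linearly
    predicted from ``predictor`` through ``n_components`` PLS components —
    used for, e.g., cytokine blocks whose raw values partly restate
    microbiota composition.
    """
    rank = min(predictor.shape[1], predictor.shape[0] - 1)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds predictor "
                         f"rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(predictor.values, target.values)
    pred = pls.predict(predictor.values)
    return pd.DataFrame(target.values - pred, index=target.index,
                        columns=target.columns)


# --- the multiblock engine --------------------------------------------------

@dataclass
class MbplsdaFit:
    classes: list
    block_names: list[str]
    block_columns: dict[str, list[str]]
    n_components: int
    # preprocessing (training means/sds per column, per-block scale)
    col_mean: dict[str, np.ndarray]
    col_sd: dict[str, np.ndarray]
    block_scale: dict[str, float]
    y_mean: np.ndarray
    # per component: block weights, super weights, score norms, y loadings
    block_weights: list[dict[str, np.ndarray]]
    super_weights: list[np.ndarray]
    score_norms: list[float]
    y_loadings: list[np.ndarray]
    block_loadings: list[dict[str, np.ndarray]]
    super_scores: np.ndarray        # n x n_components, unit columns
    ssy_per_component: np.ndarray
    block_importance: pd.Series     # BIPC, sums to 1
    relative_importance: pd.Series  # BIPC / variable share
    variable_importance: pd.Series = field(default=None)


def _prepare(blocks: dict[str, pd.DataFrame]):
    names = list(blocks)
    index = blocks[names[0]].index
    mats, mean, sd, scale, cols = {}, {}, {}, {}, {}
    for b in names:
        if not blocks[b].index.equals(index):
            raise ValueError(f"block {b!r} is not sample-aligned")
        X = blocks[b].values.astype(float)
        mu = X.mean(axis=0)
        s = X.std(axis=0, ddof=1)
        if (s == 0).any():
            bad = [c for c, v in zip(blocks[b].columns, s) if v == 0]
            raise ValueError(f"constant variables in block {b!r}: {bad}")
        Z = (X - mu) / s
        sc = np.sqrt(Z.shape[1])  # unit total variance per block
        mats[b] = Z / sc
        mean[b], sd[b], scale[b] = mu, s, sc
        cols[b] = list(blocks[b].columns)
    return names, index, mats, mean, sd, scale, cols


def fit_mbplsda(blocks: dict[str, pd.DataFrame], response: pd.Series,
                n_components: int = 2, max_iter: int = 500,
                tol: float = 1e-10) -> MbplsdaFit:
    """Fit the super-block NIPALS MB-PLS-DA model.

    Variables are standardized and each block scaled to unit total
    variance; the response is one-hot encoded and centered.  Per component,
    block weights and scores are combined through super weights into a
    unit-norm super score maximizing covariance with the response scores;
    both the blocks and the response are deflated on the super score.
    """
    if not blocks:
        raise ValueError("need at least one block")
    names, index, mats, mean, sd, scale, cols = _prepare(blocks)
    classes = sorted(pd.unique(response.loc[index]))
    Y = pd.get_dummies(response.loc[index]).reindex(
        columns=classes).values.astype(float)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    n = len(index)
    p_total = sum(m.shape[1] for m in mats.values())
    max_rank = min(n - 1, p_total)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds rank "
                         f"{max_rank}")

    block_weights, super_weights, score_norms = [], [], []
    y_loadings, block_loadings = [], []
    T_super = np.zeros((n, n_components))
    ssy = np.zeros(n_components)

    X = {b: mats[b].copy() for b in names}
    Ydef = Yc.copy()
    for h in range(n_components):
        u = Ydef[:, np.argmax(Ydef.var(axis=0))].copy()
        if np.allclose(u, 0):
            u = np.ones(n)
        t = np.zeros(n)
        for _ in range(max_iter):
            w_b, t_cols = {}, []
            for b in names:
                w = X[b].T @ u
                nw = np.linalg.norm(w)
                w = w / nw if nw > 0 else w
                w_b[b] = w
                t_cols.append(X[b] @ w)
            Tmat = np.column_stack(t_cols)
            a = Tmat.T @ u
            na = np.linalg.norm(a)
            a = a / na if na > 0 else a
            t_raw = Tmat @ a
            c = np.linalg.norm(t_raw)
            t_new = t_raw / c if c > 0 else t_raw
            q = Ydef.T @ t_new
            u_new = Ydef @ q
            nu = np.linalg.norm(u_new)
            u_new = u_new / nu if nu > 0 else u_new
            if np.linalg.norm(t_new - t) < tol:
                t = t_new
                break
            t, u = t_new, u_new
        p_b = {b: X[b].T @ t for b in names}
        q = Ydef.T @ t
        for b in names:
            X[b] = X[b] - np.outer(t, p_b[b])
        Ydef = Ydef - np.outer(t, q)
        block_weights.append(w_b)
        super_weights.append(a)
        score_norms.append(float(c))
        y_loadings.append(q)
        block_loadings.append(p_b)
        T_super[:, h] = t
        ssy[h] = float(q @ q)

    bip = np.zeros(len(names))
    w_ssy = ssy / ssy.sum() if ssy.sum() > 0 else np.full_like(ssy, 1 / len(ssy))
    for h in range(n_components):
        bip += (super_weights[h] ** 2) * w_ssy[h]
    bipc = pd.Series(bip, index=names, name="BIPC")
    share = pd.Series({b: len(cols[b]) / p_total for b in names})
    rel = (bipc / share).rename("relative_importance")

    var_imp = {}
    for b in names:
        for j, cname in enumerate(cols[b]):
            v = 0.0
            for h in range(n_components):
                v += (block_weights[h][b][j] ** 2
                      * super_weights[h][list(names).index(b)] ** 2
                      * w_ssy[h])
            var_imp[cname] = v
    return MbplsdaFit(
        classes=classes, block_names=names, block_columns=cols,
        n_components=n_components, col_mean=mean, col_sd=sd,
        block_scale=scale, y_mean=y_mean,
        block_weights=block_weights, super_weights=super_weights,
        score_norms=score_norms, y_loadings=y_loadings,
        block_loadings=block_loadings, super_scores=T_super,
        ssy_per_component=ssy, block_importance=bipc,
        relative_importance=rel,
        variable_importance=pd.Series(var_imp).sort_values(ascending=False))


def predict_scores(fit: MbplsdaFit,
                   blocks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Predicted (centered-scale) response scores for new samples."""
    index = blocks[fit.block_names[0]].index
    X = {}
    for b in fit.block_names:
        Z = (blocks[b].values.astype(float) - fit.col_mean[b]) / fit.col_sd[b]
        X[b] = Z / fit.block_scale[b]
    n = len(index)
    Yhat = np.tile(fit.y_mean, (n, 1))
    for h in range(fit.n_components):
        t_cols = [X[b] @ fit.block_weights[h][b] for b in fit.block_names]
        t = (np.column_stack(t_cols) @ fit.super_weights[h]
             / fit.score_norms[h])
        for b in fit.block_names:
            X[b] = X[b] - np.outer(t, fit.block_loadings[h][b])
        Yhat = Yhat + np.outer(t, fit.y_loadings[h])
    return pd.DataFrame(Yhat, index=index, columns=fit.classes)


def predict_classes(fit: MbplsdaFit,
                    blocks: dict[str, pd.DataFrame]) -> pd.Series:
    """Class prediction: argmax of the predicted one-hot response."""
    scores = predict_scores(fit, blocks)
    return scores.idxmax(axis=1)


def relative_block_importance(fit: MbplsdaFit) -> pd.Series:
    """BIPC divided by each block's variable share.

    1 means importance proportional to block size; informative blocks
    exceed 1 and noise blocks fall below it.
    """
    return fit.relative_importance


# --- model selection and uncertainty ---------------------------------------

@dataclass
class CvResult:
    n_splits: int
    calib_frac: float
    f1_by_components: pd.DataFrame  # splits x component grid
    mean_f1: pd.Series
    selected_components: int


def _stratified_split(response: pd.Series, calib_frac: float,
                      rng: np.random.Generator):
    calib_idx = []
    for _, grp in response.groupby(response, sort=False):
        idx = np.array(grp.index)
        rng.shuffle(idx)
        n_cal = max(1, int(round(calib_frac * len(idx))))
        n_cal = min(n_cal, len(idx) - 1) if len(idx) > 1 else n_cal
        calib_idx.extend(idx[:n_cal])
    calib = pd.Index(calib_idx)
    valid = response.index.difference(calib)
    return calib, valid


def cross_validate(blocks: dict[str, pd.DataFrame], response: pd.Series,
                   component_grid=(1, 2, 3, 4), n_splits: int = 40,
                   calib_frac: float = 0.75, seed: int = 0) -> CvResult:
    """Select the component count by repeated random-split validation.

    For each of ``n_splits`` stratified calibration/validation splits
    (default 75/25) and each candidate component count, the model is fitted
    on the calibration set and validation classes predicted by the argmax
    rule.  Selection maximizes the mean macro-averaged F1 with a
    one-standard-error parsimony rule: the smallest component count whose
    mean F1 is within one standard error of the best is chosen, so extra
    components must earn a real (not split-noise) gain.  Splits in which a
    class is absent from the calibration set are redrawn (and logged).
    """
    rng = np.random.default_rng(seed)
    grid = list(component_grid)
    rows = []
    classes = set(response.unique())
    for split in range(n_splits):
        for _ in range(100):
            calib, valid = _stratified_split(response, calib_frac, rng)
            if set(response.loc[calib].unique()) == classes and len(valid):
                break
            logger.info("redrawing split %d: class missing from "
                        "calibration", split)
        row = {}
        for nc in grid:
            fit = fit_mbplsda({b: X.loc[calib] for b, X in blocks.items()},
                              response.loc[calib], n_components=nc)
            pred = predict_classes(
                fit, {b: X.loc[valid] for b, X in blocks.items()})
            row[nc] = f1_score(response.loc[valid], pred,
                               labels=sorted(classes), average="macro",
                               zero_division=0)
        rows.append(row)
    f1 = pd.DataFrame(rows)
    mean_f1 = f1.mean(axis=0)
    best = mean_f1.idxmax()
    se = f1[best].std(ddof=1) / np.sqrt(len(f1))
    selected = int(min(nc for nc in grid
                       if mean_f1[nc] >= mean_f1[best] - se))
    return CvResult(n_splits=n_splits, calib_frac=calib_frac,
                    f1_by_components=f1, mean_f1=mean_f1,
                    selected_components=selected)


def bootstrap_block_importance(
    blocks: dict[str, pd.DataFrame], response: pd.Series,
    n_components: int = 2, n_boot: int = 200, seed: int = 0,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for the relative block importance.

    Samples (participants) are resampled with replacement; resamples in
    which a response class vanishes are redrawn with a log entry.
    """
    if n_boot < 200:
        raise ValueError("use at least 200 bootstrap resamples")
    rng = np.random.default_rng(seed)
    index = np.array(response.index)
    classes = set(response.unique())
    draws = []
    for b in range(n_boot):
        for _ in range(100):
            take = rng.choice(len(index), size=len(index), replace=True)
            resp = response.iloc[take]
            if set(resp.unique()) == classes:
                break
            logger.info("redrawing bootstrap %d: class vanished", b)
        resampled = {name: X.iloc[take].reset_index(drop=True)
                     for name, X in blocks.items()}
        resp = resp.reset_index(drop=True)
        try:
            fit = fit_mbplsda(resampled, resp, n_components=n_components)
        except ValueError:
            continue  # degenerate resample (constant column)
        draws.append(fit.relative_importance)
    boot = pd.DataFrame(draws)
    alpha = 1 - conf
    out = pd.DataFrame({
        "ci_low": boot.quantile(alpha / 2),
        "ci_high": boot.quantile(1 - alpha / 2),
        "median": boot.median(),
    })
    out.index.name = "block"
    return out
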