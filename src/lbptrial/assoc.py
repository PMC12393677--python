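"""Multi-table association: RV coefficient, PERMANOVA, DiSTATIS.

The RV coefficient generalizes the squared Pearson correlation to two
sample-aligned data tables; its null distribution is obtained by permuting
the rows of one table.  PERMANOVA tests whether a grouping explains
variability in a distance matrix via a pseudo-F on the Gower-centered
matrix.  DiSTATIS builds a weighted "compromise" of cross-product matrices
derived from several distance matrices on the same samples and projects
both samples and original variables onto its eigen-axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RVResult:
    rv: float
    p_value: float
    n_permutations: int
    seed: int
    null_rvs: np.ndarray | None = None


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class DistatisResult:
    cross_products: list[np.ndarray]
    congruence: np.ndarray          # RV matrix between tables
    table_weights: np.ndarray       # nonnegative, sums to 1
    compromise: np.ndarray
    eigenvalues: np.ndarray         # nonincreasing
    factor_scores: pd.DataFrame     # samples x dims


def _center_columns(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0, keepdims=True)


def rv_coefficient(X, Y) -> float:
    """RV coefficient between two column-centered configuration matrices.

    RV = tr(Sx Sy) / sqrt(tr(Sx^2) tr(Sy^2)) with Sx = X X' and Sy = Y Y'
    computed after column centering; 1 when the two configurations are
    identical up to rotation/scaling, near 0 for unrelated tables.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same samples in the same "
                         "order")
    if X.shape[0] < 3:
        raise ValueError("RV needs at least 3 samples")
    Xc, Yc = _center_columns(X), _center_columns(Y)
    Sx, Sy = Xc @ Xc.T, Yc @ Yc.T
    num = np.sum(Sx * Sy)
    den = np.sqrt(np.sum(Sx * Sx) * np.sum(Sy * Sy))
    return float(num / den)


def rv_permutation_test(X, Y, n_perm: int = 999,
                        seed: int = 0) -> RVResult:
    """Permutation test of the RV coefficient (rows of Y permuted).

    p = (1 + #{RV_perm >= RV_obs}) / (1 + n_perm): the add-one estimator,
    which never returns zero.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    obs = rv_coefficient(X, Y)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = rv_coefficient(X, Y[rng.permutation(Y.shape[0])])
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return RVResult(rv=obs, p_value=float(p), n_permutations=n_perm,
                    seed=seed, null_rvs=null)


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def permanova(distance, grouping, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F on a distance matrix, permutation p.

    The total and within-group sums of squares come from the diagonal-free
    identity SS = sum_{i<j} d_ij^2 / n applied overall and within groups;
    group labels are permuted for the p-value.  Cross-checked in the test
    suite against scikit-bio's implementation.
    """
    D = np.asarray(distance, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    groups = np.asarray(grouping)
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2:
        raise ValueError("grouping needs at least 2 levels")
    if (counts < 2).any():
        raise ValueError("singleton group in PERMANOVA grouping")
    n = D.shape[0]
    a = len(levels)
    D2 = D**2

    def pseudo_f(g: np.ndarray) -> float:
        ss_total = D2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for lev in levels:
            idx = np.where(g == lev)[0]
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    obs = pseudo_f(groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if pseudo_f(groups[rng.permutation(n)]) >= obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return PermanovaResult(pseudo_f=float(obs), p_value=float(p),
                           n_permutations=n_perm, seed=seed)


def distatis(distances: list, n_dims: int = 4,
             square_distances: bool = True) -> DistatisResult:
    """DiSTATIS compromise analysis of several distance matrices.

    Each distance matrix is double-centered into a cross-product matrix
    (``square_distances=True`` centers -D^2/2, the metric convention;
    ``False`` centers -D/2 directly, appropriate for semimetrics such as
    Bray-Curtis, with negative compromise eigenvalues truncated at 0) and
    normalized by its first eigenvalue.  Table weights are the first
    eigenvector of the inter-table RV (congruence) matrix, rescaled to be
    nonnegative and sum to 1; the compromise is the weighted sum of the
    normalized cross-products, and factor scores are its scaled
    eigenvectors.
    """
    mats = []
    index = None
    for D in distances:
        if isinstance(D, pd.DataFrame):
            if index is None:
                index = D.index
            elif not D.index.equals(index):
                raise ValueError("distance matrices cover different samples")
            D = D.values
        D = np.asarray(D, dtype=float)
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("each distance matrix must be square symmetric")
        n = D.shape[0]
        A = -0.5 * (D**2 if square_distances else D)
        J = np.eye(n) - np.ones((n, n)) / n
        S = J @ A @ J
        ev = np.linalg.eigvalsh(S)[-1]
        mats.append(S / ev)

    T = len(mats)
    congruence = np.eye(T)
    for i in range(T):
        for j in range(i + 1, T):
            num = np.sum(mats[i] * mats[j])
            den = np.sqrt(np.sum(mats[i] ** 2) * np.sum(mats[j] ** 2))
            congruence[i, j] = congruence[j, i] = num / den
    evals_c, evecs_c = np.linalg.eigh(congruence)
    w = evecs_c[:, -1]
    if w.sum() < 0:
        w = -w
    if (w < -1e-10).any():
        raise ValueError("negative table weights: degenerate congruence "
                         "structure")
    w = np.clip(w, 0.0, None)
    w = w / w.sum()

    compromise = sum(wi * Si for wi, Si in zip(w, mats))
    evals, evecs = np.linalg.eigh(compromise)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals_trunc = np.clip(evals, 0.0, None)
    dims = min(n_dims, len(evals))
    scores = evecs[:, :dims] * np.sqrt(evals_trunc[:dims])
    idx = index if index is not None else pd.RangeIndex(compromise.shape[0])
    factor_scores = pd.DataFrame(
        scores, index=idx, columns=[f"dim{i+1}" for i in range(dims)])
    return DistatisResult(cross_products=mats, congruence=congruence,
                          table_weights=w, compromise=compromise,
                          eigenvalues=evals, factor_scores=factor_scores)


def correlation_circle(variables: pd.DataFrame,
                       factor_scores: pd.DataFrame,
                       dims: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlations of original variables with latent dimensions.

    Constant variables have undefined correlations and are reported as NaN
    with a warning.
    """
    import warnings

    dims = list(factor_scores.columns) if dims is None else dims
    vars_aligned = variables.loc[factor_scores.index]
    out = pd.DataFrame(index=variables.columns, columns=dims, dtype=float)
    for col in variables.columns:
        v = vars_aligned[col].values.astype(float)
        if np.std(v) == 0:
            warnings.warn(f"variable {col!r} is constant; correlation "
                          "undefined", stacklevel=2)
            continue
        for d in dims:
            f = factor_scores[d].values
            if np.std(f) == 0:
                continue
            out.loc[col, d] = float(np.corrcoef(v, f)[0, 1])
    return out
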