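"""Constrained microbiome topic model.

Topics are constrained to be composed entirely of either *Lactobacillus* or
non-*Lactobacillus* species.  The non-*Lactobacillus* side is a latent
Dirichlet allocation (LDA) fit to the non-*Lactobacillus* counts; the
*Lactobacillus* side consists of "pure" single-species topics for species
that dominate enough samples, plus one pooled "Other L." topic.  Per-sample
non-*Lactobacillus* topic proportions (pi_hat, summing to 1 within the
non-*Lactobacillus* fraction) are rescaled by the total non-*Lactobacillus*
proportion (Pi_hat) to whole-community proportions p_hat = pi_hat * Pi_hat,
so that Lactobacillus topic proportions plus rescaled non-*Lactobacillus*
proportions sum to 1 in every sample.

The number of non-*Lactobacillus* topics K is chosen by aligning models
fitted over a grid of resolutions: topics are chained into paths across
consecutive K by a product-weight matching, low-coherence topics flag
spurious resolutions, and a plateau in the path count indicates a stable K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import LatentDirichletAllocation

from lbptrial.composition import relative_abundance, validate_taxonomy

OTHER_L = "Other L."


@dataclass
class LactoTopics:
    """Pure *Lactobacillus* topics plus the pooled "Other L." topic.

    ``compositions`` holds one probability vector over Lactobacillus species
    per topic; ``proportions`` the per-sample whole-community proportion of
    each topic (equal to the species proportion for pure topics, the pooled
    proportion for "Other L.").
    """

    species: list[str]              # qualifying pure-topic species
    compositions: pd.DataFrame      # topic x Lactobacillus-species
    proportions: pd.DataFrame       # sample x topic


@dataclass
class TopicModel:
    K: int
    beta: pd.DataFrame              # K x non-Lacto species, rows sum to 1
    pi_hat: pd.DataFrame            # sample x K, rows sum to 1
    Pi_hat: pd.Series               # total non-Lacto proportion per sample
    p_hat: pd.DataFrame             # sample x K, rescaled (pi_hat * Pi_hat)
    lacto: LactoTopics | None = None
    seed: int | None = None
    log_likelihood: float | None = None


@dataclass
class AlignmentResult:
    models: dict[int, TopicModel]
    #: (K, K+1) -> weight matrix (K x K+1), entries sum to 1
    weights: dict[tuple[int, int], np.ndarray]
    #: (K, topic index) -> path id
    path_of: dict[tuple[int, int], int]
    #: (K, topic index) -> coherence in [0, 1]
    coherence: dict[tuple[int, int], float]
    #: number of distinct paths among topics at each resolution
    path_count: dict[int, int] = field(default_factory=dict)
    selected_K: int | None = None


def define_lactobacillus_topics(
    proportions: pd.DataFrame,
    taxonomy: pd.DataFrame,
    dominance_threshold: float = 0.5,
    min_samples: int = 10,
) -> LactoTopics:
    """Define the *Lactobacillus* topic set from observed proportions.

    A Lactobacillus species gets its own pure topic when it reaches the
    dominance threshold (default 50% of a sample's composition) in at least
    ``min_samples`` samples; both thresholds are inclusive.  All remaining
    Lactobacillus species are pooled into an "Other L." topic whose
    composition is the species' mean relative abundances across the cohort,
    renormalized.  Per-sample topic proportions equal the corresponding
    species proportions (summed for "Other L.").
    """
    validate_taxonomy(taxonomy)
    lacto_species = [s for s in proportions.columns
                     if s in taxonomy.index
                     and bool(taxonomy.loc[s, "is_lactobacillus"])]
    if not lacto_species:
        raise ValueError("taxonomy contains no Lactobacillus species")
    qualifying = [
        s for s in lacto_species
        if int((proportions[s] >= dominance_threshold).sum()) >= min_samples
    ]
    pooled = [s for s in lacto_species if s not in qualifying]

    topics = qualifying + [OTHER_L]
    comp = pd.DataFrame(0.0, index=topics, columns=lacto_species)
    for s in qualifying:
        comp.loc[s, s] = 1.0
    if pooled:
        means = proportions[pooled].mean(axis=0)
        total = means.sum()
        comp.loc[OTHER_L, pooled] = (means / total if total > 0
                                     else 1.0 / len(pooled))
    props = pd.DataFrame(index=proportions.index, columns=topics, dtype=float)
    for s in qualifying:
        props[s] = proportions[s]
    props[OTHER_L] = proportions[pooled].sum(axis=1) if pooled else 0.0
    return LactoTopics(species=qualifying, compositions=comp,
                       proportions=props)


def fit_nonlacto_lda(
    nonlacto_counts: pd.DataFrame,
    K: int,
    alpha_prior: float | None = None,
    beta_prior: float = 0.1,
    seed: int = 0,
    max_iter: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit LDA to non-*Lactobacillus* species counts.

    Samples with zero non-*Lactobacillus* counts are excluded from the fit
    (their within-fraction proportions are undefined).  Returns
    ``(beta, pi_hat)``: topic-species distributions and per-sample topic
    proportions (variational posterior means, rows summing to 1).

    Default priors are symmetric Dirichlet with alpha = 1/K on topic
    proportions and eta = 0.1 on topic compositions.
    """
    if K > nonlacto_counts.shape[1]:
        raise ValueError(
            f"K={K} exceeds the number of non-Lactobacillus species "
            f"({nonlacto_counts.shape[1]})")
    totals = nonlacto_counts.sum(axis=1)
    fitted_samples = nonlacto_counts.index[totals > 0]
    X = nonlacto_counts.loc[fitted_samples].values.astype(float)
    topic_names = [f"NL{k+1}" for k in range(K)]

    if K == 1:
        # degenerate closed form: single topic = pooled empirical distribution
        pooled = X.sum(axis=0)
        beta = pd.DataFrame(pooled[None, :] / pooled.sum(),
                            index=topic_names,
                            columns=nonlacto_counts.columns)
        pi = pd.DataFrame(1.0, index=fitted_samples, columns=topic_names)
        return beta, pi

    lda = LatentDirichletAllocation(
        n_components=K,
        doc_topic_prior=(1.0 / K if alpha_prior is None else alpha_prior),
        topic_word_prior=beta_prior,
        learning_method="batch",
        max_iter=max_iter,
        mean_change_tol=1e-4,
        evaluate_every=5,   # enables early stopping on the ELBO-based bound
        perp_tol=1e-3,      # loose bounds leave profiles under-converged
        random_state=seed,
    )
    gamma = lda.fit_transform(X)
    beta_arr = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    beta = pd.DataFrame(beta_arr, index=topic_names,
                        columns=nonlacto_counts.columns)
    pi = pd.DataFrame(gamma / gamma.sum(axis=1, keepdims=True),
                      index=fitted_samples, columns=topic_names)
    return beta, pi


def scale_topic_proportions(pi_hat: pd.DataFrame,
                            Pi_hat: pd.Series) -> pd.DataFrame:
    """Rescale within-fraction topic proportions to the whole community.

    p_hat[k, i] = pi_hat[k, i] * Pi_hat[i].  Samples present in ``Pi_hat``
    but absent from ``pi_hat`` (no non-Lactobacillus reads, Pi_hat = 0) get
    all-zero rows, consistent with the identity.
    """
    missing = pi_hat.index.difference(Pi_hat.index)
    if len(missing):
        raise ValueError(
            f"samples in pi_hat missing from Pi_hat: {list(missing)}")
    extra = Pi_hat.index.difference(pi_hat.index)
    if (Pi_hat.loc[extra].abs() > 1e-9).any():
        bad = Pi_hat.loc[extra][Pi_hat.loc[extra].abs() > 1e-9]
        raise ValueError(
            f"samples missing from pi_hat with nonzero Pi_hat: "
            f"{list(bad.index)}")
    p_hat = pi_hat.mul(Pi_hat.reindex(pi_hat.index), axis=0)
    if len(extra):
        zeros = pd.DataFrame(0.0, index=extra, columns=pi_hat.columns)
        p_hat = pd.concat([p_hat, zeros]).reindex(Pi_hat.index)
    return p_hat


def fit_topic_model(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    K: int,
    seed: int = 0,
    **lda_kwargs,
) -> TopicModel:
    """Fit the full constrained topic model at a given K."""
    validate_taxonomy(taxonomy)
    props = relative_abundance(counts)
    lacto_cols = [c for c in counts.columns
                  if bool(taxonomy.loc[c, "is_lactobacillus"])]
    nonlacto_cols = [c for c in counts.columns if c not in lacto_cols]
    Pi_hat = props[nonlacto_cols].sum(axis=1).rename("Pi_hat")
    beta, pi_hat = fit_nonlacto_lda(counts[nonlacto_cols], K, seed=seed,
                                    **lda_kwargs)
    p_hat = scale_topic_proportions(pi_hat, Pi_hat)
    lacto = define_lactobacillus_topics(props, taxonomy)
    return TopicModel(K=K, beta=beta, pi_hat=pi_hat, Pi_hat=Pi_hat,
                      p_hat=p_hat, lacto=lacto, seed=seed)


# --- topic alignment across resolutions ------------------------------------

def product_weights(pi_a: pd.DataFrame, pi_b: pd.DataFrame) -> np.ndarray:
    """Product-scheme alignment weights between two models' topics.

    weight[k, l] is proportional to sum_i pi_a[i, k] * pi_b[i, l] over the
    shared samples; entries are normalized to sum to 1 over all pairs.
    """
    if not pi_a.index.equals(pi_b.index):
        if set(pi_a.index) != set(pi_b.index):
            raise ValueError("models were fitted on different sample sets")
        pi_b = pi_b.reindex(pi_a.index)
    w = pi_a.values.T @ pi_b.values
    return w / w.sum()


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def align_topics(
    models: dict[int, TopicModel] | list[TopicModel],
    branch_threshold: float = 0.15,
    link_floor: float = 0.05,
    duplicate_cosine: float = 0.6,
) -> AlignmentResult:
    """Chain topics across a K grid into paths and score their coherence.

    Between each pair of consecutive resolutions the product-scheme weight
    matrix is computed and topics are linked by greedy maximum-weight
    matching (largest raw weights first, each topic used at most once); a
    matched link below ``link_floor`` affinity in both directions is
    severed, so grids of mutually unrelated topics produce max-K paths.

    A higher-K topic left without a link is either a *duplicate* of an
    existing topic — its column-normalized affinity to some parent reaches
    ``branch_threshold`` and its composition is close (cosine >=
    ``duplicate_cosine``) to the sibling topic matched to that parent — in
    which case it joins that parent's path; or a genuinely distinct topic
    emerging as a mixture resolves, in which case it starts a new path.
    The path count therefore grows while real subcommunities are still
    being separated and plateaus once extra resolutions only clone
    existing topics.

    Coherence of a topic is the minimum link similarity (the smaller of
    the row- and column-normalized matched weights) along its path up to
    its own resolution; topics at the lowest resolution start at 1.
    """
    if isinstance(models, list):
        models = {m.K: m for m in models}
    Ks = sorted(models)
    if len(Ks) < 2:
        raise ValueError("alignment needs at least two fitted models")

    weights: dict[tuple[int, int], np.ndarray] = {}
    path_of: dict[tuple[int, int], int] = {}
    coherence: dict[tuple[int, int], float] = {}
    next_path = 0

    K0 = Ks[0]
    for k in range(K0):
        path_of[(K0, k)] = next_path
        coherence[(K0, k)] = 1.0
        next_path += 1

    for Ka, Kb in zip(Ks[:-1], Ks[1:]):
        w = product_weights(models[Ka].pi_hat, models[Kb].pi_hat)
        weights[(Ka, Kb)] = w
        row_norm = w / w.sum(axis=1, keepdims=True)   # parent -> children
        col_norm = w / w.sum(axis=0, keepdims=True)   # child -> parents
        beta_b = models[Kb].beta.values

        order = np.dstack(np.unravel_index(
            np.argsort(w, axis=None)[::-1], w.shape))[0]
        parent_used = set()
        child_link: dict[int, int] = {}
        for pk, ck in order:
            if pk in parent_used or ck in child_link:
                continue
            parent_used.add(int(pk))
            child_link[int(ck)] = int(pk)
        matched_child_of = {pk: ck for ck, pk in child_link.items()}

        for ck in range(w.shape[1]):
            pk = child_link.get(ck)
            sim = None
            if pk is not None:
                sim = min(row_norm[pk, ck], col_norm[pk, ck])
                if sim < link_floor:
                    pk = None  # matched but essentially unrelated
            if pk is None or sim is None:
                # duplicate of an existing topic, or a new one?
                best = int(np.argmax(col_norm[:, ck]))
                sib = matched_child_of.get(best)
                is_dup = (
                    col_norm[best, ck] >= branch_threshold
                    and sib is not None and sib != ck
                    and _cosine(beta_b[ck], beta_b[sib]) >= duplicate_cosine
                )
                if is_dup:
                    pk = best
                    sim = min(row_norm[best, ck], col_norm[best, ck])
            if pk is None:
                path_of[(Kb, ck)] = next_path
                coherence[(Kb, ck)] = float(
                    np.max(np.minimum(row_norm[:, ck], col_norm[:, ck])))
                next_path += 1
            else:
                path_of[(Kb, ck)] = path_of[(Ka, pk)]
                coherence[(Kb, ck)] = float(
                    min(coherence[(Ka, pk)], sim))

    path_count = {
        K: len({path_of[(K, k)] for k in range(K)}) for K in Ks
    }
    return AlignmentResult(models=models, weights=weights, path_of=path_of,
                           coherence=coherence, path_count=path_count)


def select_K(alignment: AlignmentResult,
             coherence_floor: float = 0.25) -> int:
    """Choose the number of non-*Lactobacillus* topics from an alignment.

    Returns the smallest K at which (a) no topic's coherence falls below
    ``coherence_floor`` and (b) the path count at K equals the path count at
    the next resolution (a plateau).  When no K satisfies both, falls back
    to the K minimizing the number of low-coherence (spurious) topics, with
    a warning.
    """
    Ks = sorted(alignment.models)
    if len(Ks) < 3:
        raise ValueError("K selection needs an alignment over >= 3 "
                         "resolutions")
    for K, K_next in zip(Ks[:-1], Ks[1:]):
        coherent = all(alignment.coherence[(K, k)] >= coherence_floor
                       for k in range(K))
        plateau = alignment.path_count[K] == alignment.path_count[K_next]
        if coherent and plateau:
            alignment.selected_K = K
            return K
    spurious = {
        K: sum(alignment.coherence[(K, k)] < coherence_floor
               for k in range(K))
        for K in Ks
    }
    best = min(Ks, key=lambda K: (spurious[K], K))
    warnings.warn(
        "no resolution satisfied the coherence-and-plateau rule; "
        f"falling back to K={best} (fewest spurious topics)",
        stacklevel=2)
    alignment.selected_K = best
    return best


def match_topics(beta_est: pd.DataFrame,
                 beta_true: pd.DataFrame) -> tuple[list[int], np.ndarray]:
    """Optimally match estimated to reference topics by total variation.

    Returns (assignment, tv_distances): ``assignment[j]`` is the estimated
    topic index matched to reference topic j, minimizing the summed
    total-variation distance (Hungarian algorithm).
    """
    from scipy.optimize import linear_sum_assignment

    est = beta_est.reindex(columns=beta_true.columns, fill_value=0.0).values
    true = beta_true.values
    cost = 0.5 * np.abs(est[:, None, :] - true[None, :, :]).sum(axis=2)
    rows, cols = linear_sum_assignment(cost)
    assignment = [int(rows[list(cols).index(j)]) for j in range(len(true))]
    tv = np.array([cost[assignment[j], j] for j in range(len(true))])
    return assignment, tv
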