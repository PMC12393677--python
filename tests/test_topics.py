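import warnings

import numpy as np
import pandas as pd
import pytest

from lbptrial import topics
from lbptrial.topics import OTHER_L, AlignmentResult, TopicModel


def _dominance_cohort(toy_taxonomy, per_species: dict, n_total=80):
    """Proportions where each species dominates in a chosen # of samples."""
    species = list(toy_taxonomy.index)
    rows = []
    for sp, n in per_species.items():
        for _ in range(n):
            row = {s: 0.5 / (len(species) - 1) for s in species}
            row[sp] = 0.5
            rows.append(row)
    while len(rows) < n_total:
        rows.append({s: 1.0 / len(species) for s in species})
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))])


class TestLactobacillusTopics:
    def test_qualifying_species_get_pure_topics(self, toy_taxonomy):
        props = _dominance_cohort(
            toy_taxonomy,
            {"Lactobacillus crispatus": 12, "Lactobacillus iners": 40,
             "Lactobacillus jensenii": 11})
        lt = topics.define_lactobacillus_topics(props, toy_taxonomy)
        assert set(lt.species) == {"Lactobacillus crispatus",
                                   "Lactobacillus iners",
                                   "Lactobacillus jensenii"}
        assert list(lt.compositions.index)[-1] == OTHER_L

    def test_no_dominant_species_gives_single_pooled_topic(
            self, toy_taxonomy):
        props = _dominance_cohort(toy_taxonomy, {}, n_total=30)
        lt = topics.define_lactobacillus_topics(props, toy_taxonomy)
        assert lt.species == []
        assert list(lt.compositions.index) == [OTHER_L]

    def test_thresholds_inclusive_at_exactly_ten_samples(self, toy_taxonomy):
        props = _dominance_cohort(toy_taxonomy,
                                  {"Lactobacillus crispatus": 10})
        lt = topics.define_lactobacillus_topics(props, toy_taxonomy)
        assert "Lactobacillus crispatus" in lt.species

    def test_proportions_equal_species_proportions(self, toy_taxonomy):
        props = _dominance_cohort(toy_taxonomy,
                                  {"Lactobacillus crispatus": 15})
        lt = topics.define_lactobacillus_topics(props, toy_taxonomy)
        pd.testing.assert_series_equal(
            lt.proportions["Lactobacillus crispatus"],
            props["Lactobacillus crispatus"],
            check_names=False)

    def test_no_lactobacillus_in_taxonomy_rejected(self, toy_taxonomy):
        tax = toy_taxonomy.copy()
        tax["is_lactobacillus"] = False
        with pytest.raises(ValueError, match="no Lactobacillus"):
            topics.define_lactobacillus_topics(
                _dominance_cohort(toy_taxonomy, {}), tax)


def _two_topic_counts(rng, n=200, depth=10_000):
    beta = np.array([
        [0.70, 0.20, 0.05, 0.03, 0.02, 0.0],
        [0.02, 0.03, 0.05, 0.20, 0.30, 0.40],
    ])
    z = rng.random(n) < 0.5
    theta = np.where(z[:, None], [0.95, 0.05], [0.05, 0.95])
    X = np.vstack([rng.multinomial(depth, th @ beta) for th in theta])
    cols = [f"sp{i}" for i in range(beta.shape[1])]
    return pd.DataFrame(X, columns=cols), pd.DataFrame(beta, columns=cols)


class TestNonLactoLda:
    def test_two_topic_recovery(self, rng):
        counts, beta_true = _two_topic_counts(rng)
        beta, pi = topics.fit_nonlacto_lda(counts, K=2, seed=0)
        _, tv = topics.match_topics(beta, beta_true)
        assert tv.max() < 0.05

    def test_k1_closed_form(self, rng):
        counts, _ = _two_topic_counts(rng, n=40)
        beta, pi = topics.fit_nonlacto_lda(counts, K=1)
        pooled = counts.sum(axis=0) / counts.values.sum()
        np.testing.assert_allclose(beta.iloc[0].values, pooled.values,
                                   atol=1e-12)
        assert (pi.values == 1.0).all()

    def test_same_seed_identical(self, rng):
        counts, _ = _two_topic_counts(rng, n=60)
        b1, _ = topics.fit_nonlacto_lda(counts, K=2, seed=7)
        b2, _ = topics.fit_nonlacto_lda(counts, K=2, seed=7)
        np.testing.assert_array_equal(b1.values, b2.values)

    def test_k_exceeding_species_rejected(self, rng):
        counts, _ = _two_topic_counts(rng, n=20)
        with pytest.raises(ValueError, match="exceeds"):
            topics.fit_nonlacto_lda(counts, K=10)

    def test_zero_nonlacto_samples_excluded(self, rng):
        counts, _ = _two_topic_counts(rng, n=30)
        counts.iloc[0] = 0
        _, pi = topics.fit_nonlacto_lda(counts, K=2, seed=0)
        assert counts.index[0] not in pi.index

    def test_column_permutation_invariance(self, rng):
        """Permuting species columns changes nothing up to topic matching."""
        counts, _ = _two_topic_counts(rng)
        b1, _ = topics.fit_nonlacto_lda(counts, K=2, seed=0)
        perm = ["sp3", "sp0", "sp5", "sp1", "sp4", "sp2"]
        b2, _ = topics.fit_nonlacto_lda(counts[perm], K=2, seed=0)
        _, tv = topics.match_topics(b2, b1)
        assert tv.max() < 0.05


class TestScaleTopicProportions:
    def test_direct_product(self):
        pi = pd.DataFrame([[0.5, 0.5]], index=["s"], columns=["t1", "t2"])
        Pi = pd.Series([0.4], index=["s"])
        out = topics.scale_topic_proportions(pi, Pi)
        np.testing.assert_allclose(out.values, [[0.2, 0.2]])

    def test_fully_lactobacillus_sample_gets_zeros(self):
        pi = pd.DataFrame([[1.0, 0.0]], index=["a"], columns=["t1", "t2"])
        Pi = pd.Series([0.3, 0.0], index=["a", "b"])
        out = topics.scale_topic_proportions(pi, Pi)
        assert (out.loc["b"] == 0).all()

    def test_row_sums_equal_pi_hat(self, rng):
        pi = pd.DataFrame(rng.dirichlet(np.ones(4), size=20))
        Pi = pd.Series(rng.uniform(0, 1, 20))
        out = topics.scale_topic_proportions(pi, Pi)
        np.testing.assert_allclose(out.sum(axis=1), Pi.values, atol=1e-12)


def _fake_model(K, pi, beta=None):
    pi = pd.DataFrame(pi, columns=[f"t{k}" for k in range(K)])
    pi.index = [f"s{i}" for i in range(len(pi))]
    if beta is None:
        beta = np.eye(K, 6)
    beta = pd.DataFrame(beta, columns=[f"sp{j}" for j in range(6)])
    Pi = pd.Series(1.0, index=pi.index)
    return TopicModel(K=K, beta=beta, pi_hat=pi, Pi_hat=Pi,
                      p_hat=pi.mul(Pi, axis=0))


class TestAlignTopics:
    def test_duplicate_topic_shares_path(self):
        """An extra resolution that only clones a topic must not open a new
        path, and undisturbed topics stay near-perfectly coherent."""
        n = 60
        rng = np.random.default_rng(0)
        z = rng.integers(0, 2, n)
        pi2 = np.column_stack([z == 0, z == 1]).astype(float)
        pi2 = np.clip(pi2, 0.02, 0.98)
        pi2 /= pi2.sum(axis=1, keepdims=True)
        # duplicate topic 1: its usage split between two clone columns
        pi3 = np.column_stack([pi2[:, 0], pi2[:, 1] / 2, pi2[:, 1] / 2])
        beta2 = np.array([[0.9, 0.1, 0, 0, 0, 0],
                          [0, 0, 0, 0, 0.1, 0.9]], dtype=float)
        beta3 = np.vstack([beta2, beta2[1]])
        m2 = _fake_model(2, pi2, beta2)
        m3 = _fake_model(3, pi3, beta3)
        al = topics.align_topics({2: m2, 3: m3})
        assert al.path_count[3] == 2
        assert al.path_of[(3, 1)] == al.path_of[(3, 2)]
        assert al.coherence[(3, 0)] > 0.9

    def test_disjoint_topics_make_max_k_paths(self):
        # two models used on disjoint halves of the cohort: no topic of one
        # resolution shares samples with any topic of the other
        n = 40
        pi2 = np.zeros((n, 2))
        pi2[: n // 2, 0] = 1.0
        pi2[n // 2:, 1] = 1.0
        pi3 = np.zeros((n, 3))
        pi3[: n // 3, 2] = 1.0
        pi3[n // 3: 2 * n // 3, 0] = 1.0
        pi3[2 * n // 3:, 1] = 1.0
        # force near-zero products by swapping sample blocks
        pi3 = np.roll(pi2, n // 2, axis=0)
        pi3 = np.column_stack([pi3, np.zeros(n)])
        pi3[0, 2] = 1.0
        pi3[0, :2] = 0.0
        beta2 = np.eye(2, 6)
        beta3 = np.eye(3, 6)[:, ::-1]  # disjoint compositions
        al = topics.align_topics({2: _fake_model(2, pi2, beta2),
                                  3: _fake_model(3, pi3, beta3)},
                                 link_floor=0.6)
        assert al.path_count[3] == 3

    def test_greedy_matching_agrees_with_exhaustive_on_small_instance(self):
        """With well-separated weights, greedy path assignment equals the
        optimal assignment found by exhaustive enumeration."""
        from itertools import permutations

        rng = np.random.default_rng(1)
        z = rng.integers(0, 3, 90)
        pi3 = np.eye(3)[z] * 0.94 + 0.02
        pi4 = np.column_stack([pi3[:, 0], pi3[:, 1], pi3[:, 2] / 2,
                               pi3[:, 2] / 2])
        pi4 /= pi4.sum(axis=1, keepdims=True)
        beta3 = np.eye(3, 6) * 0.9 + 0.01
        beta4 = np.vstack([beta3, beta3[2]])
        m3, m4 = _fake_model(3, pi3, beta3), _fake_model(4, pi4, beta4)
        al = topics.align_topics({3: m3, 4: m4})

        w = topics.product_weights(m3.pi_hat, m4.pi_hat)
        best, best_val = None, -1
        for cols in permutations(range(4), 3):
            val = sum(w[i, c] for i, c in enumerate(cols))
            if val > best_val:
                best, best_val = cols, val
        for parent, child in enumerate(best):
            assert al.path_of[(4, child)] == al.path_of[(3, parent)]

    def test_different_sample_sets_rejected(self):
        m2 = _fake_model(2, np.full((10, 2), 0.5))
        m3 = _fake_model(3, np.full((12, 3), 1 / 3))
        with pytest.raises(ValueError, match="sample sets"):
            topics.align_topics({2: m2, 3: m3})


class TestSelectK:
    def _fake_alignment(self, path_count, coherence):
        models = {K: None for K in path_count}
        return AlignmentResult(models=models, weights={}, path_of={},
                               coherence=coherence, path_count=path_count)

    def test_plateau_with_clean_coherence(self):
        coh = {(K, k): 0.9 for K in (2, 3, 4, 5) for k in range(K)}
        al = self._fake_alignment({2: 2, 3: 3, 4: 3, 5: 4}, coh)
        assert topics.select_K(al) == 3

    def test_fallback_warns_when_paths_keep_growing(self):
        coh = {(K, k): 1.0 for K in (2, 3, 4) for k in range(K)}
        al = self._fake_alignment({2: 2, 3: 3, 4: 4}, coh)
        with pytest.warns(UserWarning, match="falling back"):
            K = topics.select_K(al)
        assert K == 2

    def test_low_coherence_blocks_selection(self):
        coh = {(K, k): (0.05 if (K, k) == (3, 2) else 0.9)
               for K in (2, 3, 4, 5) for k in range(K)}
        al = self._fake_alignment({2: 2, 3: 3, 4: 3, 5: 3}, coh)
        # K=3 has a spurious topic, so the plateau at 4 wins
        assert topics.select_K(al) == 4

    def test_needs_three_resolutions(self):
        al = self._fake_alignment({2: 2, 3: 3}, {})
        with pytest.raises(ValueError, match="3"):
            topics.select_K(al)


class TestFullModel:
    def test_composition_conservation(self, small_cohort):
        """Lactobacillus topic proportions plus rescaled non-Lactobacillus
        proportions account for every sample's full composition."""
        model = topics.fit_topic_model(small_cohort.counts,
                                       small_cohort.taxonomy, K=3, seed=0)
        total = (model.p_hat.sum(axis=1)
                 + model.lacto.proportions.reindex(
                     model.p_hat.index).sum(axis=1))
        np.testing.assert_allclose(total.values, 1.0, atol=1e-10)
        np.testing.assert_allclose(
            model.p_hat.sum(axis=1).values,
            model.Pi_hat.reindex(model.p_hat.index).values, atol=1e-10)
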