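import numpy as np
import pytest
from scipy.stats import chisquare

from conftest import random_model
from oracles import bpr_reference_updates, finite_difference_check
from mirlnc.io_data import InteractionNetwork
from mirlnc.model import (
    Hyperparams,
    TrainingDiverged,
    TrainingTriple,
    aggregate_score,
    fused_score,
    group_score,
    init_model,
    load_model,
    predict_score,
    rank_candidates,
    sample_triple,
    save_model,
    sgd_step,
    train,
    triple_gradients,
    triple_loss,
)
from mirlnc.io_data import SimilarityMatrix


def _sim(ids, values, kind="expression", valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(len(ids), dtype=bool)
    return SimilarityMatrix(list(ids), values, np.asarray(valid), kind)


class TestScoring:
    def test_predict_is_inner_product_plus_bias(self, rng):
        m = random_model(rng, d=2)
        m.U[0] = [1.0, 0.0]
        m.V[0] = [2.0, 3.0]
        m.b[0] = 0.5
        assert predict_score(m, 0, 0) == 2.5

    def test_zero_model_scores_zero(self, rng):
        m = random_model(rng)
        m.U[:] = 0; m.V[:] = 0; m.b[:] = 0
        assert predict_score(m, 1, 2) == 0.0

    def test_predict_matches_elementwise_sum(self, rng):
        m = random_model(rng, d=4)
        expected = sum(m.U[2, t] * m.V[3, t] for t in range(4)) + m.b[3]
        assert predict_score(m, 2, 3) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_index_errors(self, rng):
        with pytest.raises(IndexError):
            predict_score(random_model(rng), 99, 0)

    def test_group_score_is_mean_of_members(self, rng):
        m = random_model(rng)
        singles = [predict_score(m, i, 2) for i in (0, 1, 4)]
        assert group_score(m, np.array([0, 1, 4]), 2) == pytest.approx(np.mean(singles))
        assert group_score(m, np.array([3]), 2) == pytest.approx(predict_score(m, 3, 2))

    def test_empty_group_errors(self, rng):
        with pytest.raises(ValueError):
            group_score(random_model(rng), np.array([], dtype=int), 0)

    @pytest.mark.parametrize("rho, expected_from", [(0.0, "individual"), (1.0, "group")])
    def test_fused_score_degenerate_tradeoffs(self, rng, rho, expected_from):
        m = random_model(rng, rho=rho)
        G = np.array([0, 1, 2])
        fused = fused_score(m, G, 1, 3)
        ref = predict_score(m, 1, 3) if expected_from == "individual" else group_score(m, G, 3)
        assert fused == pytest.approx(ref)

    def test_fused_score_is_convex_combination(self, rng):
        m = random_model(rng, rho=0.5)
        G = np.array([0, 1])
        expected = 0.5 * group_score(m, G, 2) + 0.5 * predict_score(m, 1, 2)
        assert fused_score(m, G, 1, 2) == pytest.approx(expected)


class TestLossAndGradients:
    def test_zero_model_loss_is_ln2(self, rng):
        m = random_model(rng, alpha_m=0.0, alpha_l=0.0, beta_l=0.0)
        m.U[:] = 0; m.V[:] = 0; m.b[:] = 0
        t = TrainingTriple(i=0, j=1, k=2, G=np.array([0]))
        assert triple_loss(m, t) == pytest.approx(np.log(2))

    def test_loss_vanishes_at_large_margin(self, rng):
        m = random_model(rng, d=1, alpha_m=0.0, alpha_l=0.0, beta_l=0.0)
        m.U[:] = 0; m.V[:] = 0; m.b[:] = 0
        m.b[1] = 50.0; m.b[2] = -50.0
        t = TrainingTriple(i=0, j=1, k=2, G=np.array([0]))
        assert triple_loss(m, t) < 1e-20

    def test_loss_matches_direct_formula(self, rng):
        m = random_model(rng, d=3, rho=0.3, alpha_m=0.02, alpha_l=0.05, beta_l=0.01)
        G = np.array([0, 2])
        t = TrainingTriple(i=2, j=1, k=4, G=G)
        s = (0.3 * np.mean([m.U[g] @ m.V[1] + m.b[1] for g in G])
             + 0.7 * (m.U[2] @ m.V[1] + m.b[1]) - (m.U[2] @ m.V[4] + m.b[4]))
        expected = (np.log1p(np.exp(-s))
                    + 0.01 * sum((m.U[g] ** 2).sum() for g in G)
                    + 0.025 * ((m.V[1] ** 2).sum() + (m.V[4] ** 2).sum())
                    + 0.005 * (m.b[1] ** 2 + m.b[4] ** 2))
        assert triple_loss(m, t) == pytest.approx(expected, rel=1e-12)

    def test_gradients_match_central_differences(self, rng):
        for _ in range(10):
            d = int(rng.integers(1, 5))
            m = random_model(rng, nm=6, nl=7, d=d,
                             rho=float(rng.uniform(0, 1)),
                             alpha_m=0.05, alpha_l=0.02, beta_l=0.03)
            g_size = int(rng.integers(1, 5))
            G = rng.choice(6, size=g_size, replace=False).astype(np.intp)
            t = TrainingTriple(i=int(G[0]), j=0, k=5, G=G)
            assert finite_difference_check(m, t) < 1e-5

    def test_zero_learning_rate_leaves_model_unchanged(self, rng):
        m = random_model(rng)
        # gamma must be positive by contract; emulate gamma->0 via tiny rate
        t = TrainingTriple(i=0, j=1, k=2, G=np.array([0, 1]))
        loss0, grads = triple_gradients(m, t)
        U0 = m.U.copy()
        m.hyper = Hyperparams(d=m.hyper.d, gamma=1e-300, seed=0)
        sgd_step(m, t)
        np.testing.assert_allclose(m.U, U0, atol=1e-290)

    def test_first_step_from_zero_raises_bj_lowers_bk(self, rng):
        m = random_model(rng)
        m.U[:] = 0; m.V[:] = 0; m.b[:] = 0
        t = TrainingTriple(i=0, j=1, k=2, G=np.array([0]))
        sgd_step(m, t)
        assert m.b[1] > 0 and m.b[2] < 0


class TestSampling:
    def test_group_contains_anchor_and_partners_of_j(self, tiny_synthetic, rng):
        net = tiny_synthetic.net
        mir_partners = net.mir_partners()
        for _ in range(200):
            t = sample_triple(net, rng, group_size=3)
            assert t.i in t.G
            assert (t.i, t.j) in net.pairs and (t.i, t.k) not in net.pairs
            assert set(t.G.tolist()) <= set(mir_partners[t.j].tolist())
            assert t.G.size <= 3 and t.G.size == len(set(t.G.tolist()))

    def test_singleton_group_when_j_has_one_partner(self, rng):
        net = InteractionNetwork(["m1", "m2"], ["l1", "l2", "l3"], {(0, 0), (1, 1)})
        for _ in range(50):
            t = sample_triple(net, rng, group_size=3)
            assert t.G.tolist() == [t.i]

    def test_positive_marginal_is_uniform(self):
        # single miRNA with 6 observed of 10 lncRNAs
        net = InteractionNetwork(["m"], [f"l{j}" for j in range(10)],
                                 {(0, j) for j in range(6)})
        rng = np.random.default_rng(42)
        counts = np.zeros(6)
        for _ in range(10_000):
            t = sample_triple(net, rng, group_size=3)
            counts[t.j] += 1
            assert t.k >= 6
        assert chisquare(counts).pvalue > 0.01

    def test_no_eligible_mirna_errors(self):
        net = InteractionNetwork(["m"], ["l1", "l2"], {(0, 0), (0, 1)})  # full row
        with pytest.raises(ValueError, match="no miRNA"):
            sample_triple(net, np.random.default_rng(0), 3)


class TestTraining:
    def test_t0_returns_initialization(self, tiny_synthetic):
        net = tiny_synthetic.net
        h = Hyperparams(d=4, T=0, seed=5)
        model = train(net, hyper=h)
        np.testing.assert_array_equal(model.U, init_model(net, h).U)
        assert model.epoch_losses == []

    def test_same_seed_gives_identical_trajectories(self, tiny_synthetic):
        net = tiny_synthetic.net
        h = Hyperparams(d=4, T=3, seed=5)
        m1, m2 = train(net, hyper=h), train(net, hyper=h)
        np.testing.assert_array_equal(m1.U, m2.U)
        np.testing.assert_array_equal(m1.V, m2.V)
        np.testing.assert_array_equal(m1.b, m2.b)
        assert m1.epoch_losses == m2.epoch_losses

    def test_loss_trend_decreases(self, tiny_synthetic):
        net = tiny_synthetic.net
        model = train(net, hyper=Hyperparams(d=4, T=30, seed=1))
        assert np.mean(model.epoch_losses[-10:]) <= model.epoch_losses[0]

    def test_group_of_one_matches_pairwise_reference(self, tiny_synthetic):
        from mirlnc.model import _partner_arrays

        net = tiny_synthetic.net
        h = Hyperparams(d=4, group_size=1, seed=11, rho=0.5)
        m = init_model(net, h)
        ref_U, ref_V, ref_b = m.U.copy(), m.V.copy(), m.b.copy()
        rng = np.random.default_rng(0)
        lnc_partners, mir_partners, lnc_sets = _partner_arrays(net)
        eligible = np.array([i for i in range(net.nm) if 0 < lnc_partners[i].size < net.nl],
                            dtype=np.intp)
        cache = (lnc_partners, mir_partners, lnc_sets, eligible)
        triples = [sample_triple(net, rng, 1, _cache=cache) for _ in range(1500)]
        for t in triples:
            sgd_step(m, t)
        bpr_reference_updates(ref_U, ref_V, ref_b, [(t.i, t.j, t.k) for t in triples],
                              h.gamma, h.alpha_m, h.alpha_l, h.beta_l)
        assert np.array_equal(m.U, ref_U)
        assert np.array_equal(m.V, ref_V)
        assert np.array_equal(m.b, ref_b)

    def test_training_is_permutation_equivariant(self, rng):
        net = InteractionNetwork(
            [f"m{i}" for i in range(5)], [f"l{j}" for j in range(8)],
            {(0, 0), (0, 3), (1, 3), (2, 5), (3, 1), (4, 6), (1, 0)},
        )
        perm_m = rng.permutation(5)
        perm_l = rng.permutation(8)
        h = Hyperparams(d=3, seed=2, T=0)
        m = init_model(net, h)
        mp = init_model(net, h)
        mp.U = m.U[np.argsort(perm_m)].copy()
        mp.V = m.V[np.argsort(perm_l)].copy()
        rng9 = np.random.default_rng(9)
        triples = [sample_triple(net, rng9, 3) for _ in range(300)]
        for t in triples:
            sgd_step(m, t)
            tp = TrainingTriple(i=int(perm_m[t.i]), j=int(perm_l[t.j]), k=int(perm_l[t.k]),
                                G=perm_m[t.G])
            sgd_step(mp, tp)
        np.testing.assert_allclose(mp.U[perm_m], m.U, atol=1e-12)
        np.testing.assert_allclose(mp.V[perm_l], m.V, atol=1e-12)

    def test_stronger_regularization_shrinks_norms(self, tiny_synthetic):
        net = tiny_synthetic.net
        norms = []
        for reg in (0.01, 0.1, 1.0):
            model = train(net, hyper=Hyperparams(d=4, T=15, seed=3, alpha_m=reg,
                                                 alpha_l=reg, beta_l=reg))
            norms.append(np.linalg.norm(model.U) + np.linalg.norm(model.V))
        assert norms[0] > norms[1] > norms[2]

    def test_divergence_reports_epoch(self, tiny_synthetic):
        net = tiny_synthetic.net
        with pytest.raises(TrainingDiverged, match="epoch"):
            train(net, hyper=Hyperparams(d=4, T=5, seed=1, gamma=1e8, init_scale=10.0))

    def test_similarity_initialization_is_deterministic(self, tiny_synthetic):
        net = tiny_synthetic.net
        n = net.nm
        vals = np.eye(n) * 0.5 + 0.5
        s_m = _sim(net.mirna_ids, (vals + vals.T) / 2, kind="function")
        h = Hyperparams(d=4, T=0, seed=5, init="similarity")
        m1, m2 = init_model(net, h, s_m, None), init_model(net, h, s_m, None)
        np.testing.assert_array_equal(m1.U, m2.U)
        assert np.isfinite(m1.U).all() and m1.U.shape == (net.nm, 4)


class TestAggregationAndRanking:
    def _setup(self, rng):
        net = InteractionNetwork(["m1", "m2", "m3"], ["l1", "l2", "l3"],
                                 {(0, 0), (1, 0), (2, 0), (0, 1)})
        m = random_model(rng, nm=3, nl=3, d=2, delta_m=1.0, delta_l=1.0)
        m.mirna_ids = list(net.mirna_ids)
        m.lncrna_ids = list(net.lncrna_ids)
        return net, m

    def test_zero_deltas_leave_score_unchanged(self, rng):
        net, m = self._setup(rng)
        m.hyper = Hyperparams(d=2, delta_m=0.0, delta_l=0.0, seed=0)
        s_m = _sim(net.mirna_ids, np.full((3, 3), 0.8), kind="function")
        s_l = _sim(net.lncrna_ids, np.full((3, 3), 0.8))
        assert aggregate_score(m, net, s_m, s_l, 1, 2) == pytest.approx(predict_score(m, 1, 2))

    def test_aggregation_adds_mean_positive_similarity(self, rng):
        # Score(1, l2): M_{l2}={m1}, S_m(m2,m1)=0.4; L_{m2}={l1}, S_l(l2,l1)=0.2
        net = InteractionNetwork(["m1", "m2"], ["l1", "l2"], {(0, 1), (1, 0)})
        m = random_model(rng, nm=2, nl=2, d=2)
        m.U[:] = 0; m.V[:] = 0; m.b[:] = 0
        m.b[1] = 1.0
        s_m = _sim(net.mirna_ids, [[1.0, 0.4], [0.4, 1.0]], kind="function")
        s_l = _sim(net.lncrna_ids, [[1.0, 0.2], [0.2, 1.0]])
        assert aggregate_score(m, net, s_m, s_l, 1, 1) == pytest.approx(1.0 + 0.4 + 0.2)

    def test_negative_similarities_clamped_to_zero(self, rng):
        net = InteractionNetwork(["m1", "m2"], ["l1", "l2"], {(0, 1), (1, 0)})
        m = random_model(rng, nm=2, nl=2, d=2)
        m.U[:] = 0; m.V[:] = 0; m.b[:] = 0
        s_m = _sim(net.mirna_ids, [[1.0, -0.4], [-0.4, 1.0]], kind="expression")
        s_l = _sim(net.lncrna_ids, [[1.0, -0.2], [-0.2, 1.0]])
        assert aggregate_score(m, net, s_m, s_l, 1, 1) == pytest.approx(0.0)

    def test_invalid_similarity_row_contributes_nothing(self, rng):
        net = InteractionNetwork(["m1", "m2"], ["l1", "l2"], {(0, 1), (1, 0)})
        m = random_model(rng, nm=2, nl=2, d=2)
        m.U[:] = 0; m.V[:] = 0; m.b[:] = 0
        s_m = _sim(net.mirna_ids, [[1.0, 0.4], [0.4, 1.0]], kind="function")
        s_l = _sim(net.lncrna_ids, [[1.0, 0.0], [0.0, 0.0]], valid=[True, False])
        assert aggregate_score(m, net, s_m, s_l, 1, 1) == pytest.approx(0.4)

    def test_rank_excludes_observed_and_breaks_ties_by_id(self, rng):
        net, m = self._setup(rng)
        m.U[:] = 0; m.V[:] = 0; m.b[:] = 0
        ranked = rank_candidates(m, net, None, None, "m2", k=5)
        ids = [c for c, _ in ranked]
        assert "l1" not in ids  # observed partner of m2
        assert ids == sorted(ids)  # all-zero scores -> lexicographic

    def test_k_larger_than_candidates_returns_all(self, rng):
        net, m = self._setup(rng)
        assert len(rank_candidates(m, net, None, None, "m2", k=99)) == 2

    def test_unknown_query_errors(self, rng):
        net, m = self._setup(rng)
        with pytest.raises(KeyError, match="unknown"):
            rank_candidates(m, net, None, None, "nope", k=5)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_synthetic):
        model = train(tiny_synthetic.net, hyper=Hyperparams(d=4, T=2, seed=5))
        path = tmp_path / "model.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.U, model.U)
        np.testing.assert_array_equal(back.b, model.b)
        assert back.hyper == model.hyper
        assert back.mirna_ids == model.mirna_ids
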