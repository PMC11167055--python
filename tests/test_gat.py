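"""Prior graph, masked attention, forward-pass oracle equivalence,
gradients, loss and training contracts."""

import numpy as np
import pytest

from stitchgat.datamodel import SUBSKILL_ORDER
from stitchgat.gat import (
    DEFAULT_PAIRS,
    JointConfig,
    build_prior_graph,
    extract_attention,
    gat_backward,
    gat_forward,
    init_params,
    isolated_node_forward,
    joint_loss,
    masked_attention,
    predict_joint,
    train_stage2,
)


class TestPriorGraph:
    def test_default_graph(self):
        """Three pairs give six off-diagonal ones plus a full diagonal;
        hold angle touches all three edges."""
        g = build_prior_graph()
        A = g.adjacency
        assert (np.diag(A) == 1).all()
        assert A.sum() == 6 + 6
        np.testing.assert_array_equal(A, A.T)
        ha = SUBSKILL_ORDER.index([s for s in SUBSKILL_ORDER if s.code == "HA"][0])
        assert A[ha].sum() == 4  # self + HR + DS + WR
        rp = 0
        assert A[rp].sum() == 1  # isolated node

    def test_empty_pairs_identity(self):
        g = build_prior_graph(())
        np.testing.assert_array_equal(g.adjacency, np.eye(6, dtype=int))

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            build_prior_graph((("HA", "HA"),))

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            build_prior_graph((("HA", "ZZ"),))

    def test_duplicate_pair_warns_and_dedups(self):
        with pytest.warns(UserWarning, match="duplicate"):
            g = build_prior_graph((("HR", "HA"), ("HA", "HR")))
        assert g.adjacency.sum() == 6 + 2


class TestMaskedAttention:
    def test_equal_scores_uniform_over_allowed(self):
        g = build_prior_graph()
        alpha = masked_attention(np.zeros((6, 6)), g)
        ha = 2
        np.testing.assert_allclose(alpha[ha][g.adjacency[ha] == 1], 0.25, atol=1e-12)

    def test_non_edges_exactly_zero(self, rng):
        g = build_prior_graph()
        alpha = masked_attention(rng.normal(size=(6, 6)) * 10, g)
        assert (alpha[g.adjacency == 0] == 0.0).all()

    def test_closed_form_degree_two_row(self):
        """Allowed scores (0, ln 2) on a two-entry row give (1/3, 2/3)."""
        g = build_prior_graph((("HR", "HA"),))
        scores = np.zeros((6, 6))
        hr, ha = 1, 2
        scores[hr, ha] = np.log(2.0)
        alpha = masked_attention(scores, g)
        assert alpha[hr, hr] == pytest.approx(1 / 3, abs=1e-12)
        assert alpha[hr, ha] == pytest.approx(2 / 3, abs=1e-12)

    def test_rows_sum_to_one_over_allowed(self, rng):
        g = build_prior_graph()
        for _ in range(50):
            alpha = masked_attention(rng.normal(size=(3, 6, 6)) * 5, g)
            np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-9)
            assert (alpha >= 0).all() and (alpha <= 1).all()

    def test_nonfinite_scores_rejected(self):
        g = build_prior_graph()
        scores = np.zeros((6, 6))
        scores[0, 0] = np.nan
        with pytest.raises(ValueError):
            masked_attention(scores, g)


def _tiny_cfg(**kw):
    defaults = dict(feature_dim=5, target_len=0, hidden=4, att_hidden=3,
                    out_dim=3, seed=1)
    defaults.update(kw)
    return JointConfig(**defaults)


def _leaky(x, s):
    return np.where(x > 0, x, s * x)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0)))


def _oracle_forward(params, X, graph):
    """Explicit nested-loop aggregation, independent of the vectorized path."""
    cfg = params.config
    B = X.shape[0]
    logits = np.zeros((B, 6, 2))
    alphas = np.zeros((B, 6, 6))
    for b in range(B):
        h = [params.W.T @ X[b, j] + params.bW for j in range(6)]
        for i in range(6):
            # scores over allowed neighbours
            allowed = [j for j in range(6) if graph.adjacency[i, j]]
            if cfg.use_attention:
                es = []
                for j in allowed:
                    pair = np.concatenate([h[i], h[j]])
                    hid = _leaky(params.A1.T @ pair + params.b1, cfg.leaky_slope)
                    es.append(float(params.a2 @ hid + params.b2))
                es = np.array(es)
                w = np.exp(es - es.max())
                w = w / w.sum()
            else:
                w = np.ones(len(allowed))
            alphas[b, i, allowed] = w
            msg = sum(wj * h[j] for wj, j in zip(w, allowed))
            z = _elu(msg) @ params.Wo + params.bo
            logits[b, i] = z @ params.heads[i] + params.head_b[i]
    return logits, alphas


@pytest.mark.parametrize("use_attention", [True, False])
def test_forward_matches_nested_loop_oracle(rng, use_attention):
    cfg = _tiny_cfg(use_attention=use_attention)
    graph = build_prior_graph()
    params = init_params(cfg, rng)
    params.a2 = rng.normal(size=params.a2.shape)
    params.b2 = 0.3
    X = rng.normal(size=(4, 6, cfg.input_dim))
    logits, alpha, _ = gat_forward(params, X, graph)
    o_logits, o_alpha = _oracle_forward(params, X, graph)
    np.testing.assert_allclose(logits, o_logits, atol=1e-6)
    np.testing.assert_allclose(alpha, o_alpha, atol=1e-6)


def test_forward_attention_rows_sum_to_one(rng):
    cfg = _tiny_cfg()
    graph = build_prior_graph()
    params = init_params(cfg, rng)
    params.a2 = rng.normal(size=params.a2.shape)
    X = rng.normal(size=(3, 6, cfg.input_dim))
    _, alpha, _ = gat_forward(params, X, graph)
    np.testing.assert_allclose(alpha.sum(axis=-1), 1.0, atol=1e-6)


def test_identity_graph_reduces_to_isolated_networks(rng):
    """Identity adjacency + unit weights: the joint model equals six
    isolated per-node networks on their own inputs."""
    cfg = _tiny_cfg(use_attention=False)
    graph = build_prior_graph(())
    params = init_params(cfg, rng)
    X = rng.normal(size=(5, 6, cfg.input_dim))
    logits, _, _ = gat_forward(params, X, graph)
    for k in range(6):
        iso = isolated_node_forward(params, X[:, k, :], k)
        np.testing.assert_allclose(logits[:, k, :], iso, atol=1e-6)


def test_gradients_match_finite_differences(rng):
    cfg = _tiny_cfg()
    graph = build_prior_graph()
    params = init_params(cfg, rng)
    params.a2 = rng.normal(size=params.a2.shape) * 0.5
    X = rng.normal(size=(2, 6, cfg.input_dim))
    Y = rng.integers(0, 2, size=(2, 6))
    logits, _, _, cache = gat_forward(params, X, graph, return_cache=True)
    grads = gat_backward(params, cache, Y, logits)

    def loss_at():
        lg, _, _ = gat_forward(params, X, graph)
        return joint_loss(lg, Y)

    eps = 1e-6
    check = np.random.default_rng(0)
    for name, g in grads.items():
        p = getattr(params, name)
        if np.ndim(p) == 0:
            setattr(params, name, p + eps)
            lp = loss_at()
            setattr(params, name, p - eps)
            lm = loss_at()
            setattr(params, name, p)
            num = (lp - lm) / (2 * eps)
            assert abs(num - g) < 1e-6 * (1 + abs(num))
        else:
            flat_idx = check.choice(p.size, size=min(p.size, 10), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss_at()
                p[idx] = orig - eps
                lm = loss_at()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) < 1e-6 * (1 + abs(num)), name


class TestJointLoss:
    def test_uniform_logits_six_ln_two(self):
        logits = np.zeros((3, 6, 2))
        labels = np.random.default_rng(0).integers(0, 2, size=(3, 6))
        assert joint_loss(logits, labels) == pytest.approx(6 * np.log(2), abs=1e-12)

    def test_decreases_with_margin(self):
        labels = np.ones((1, 6), dtype=int)
        prev = np.inf
        for margin in (0.5, 1.0, 2.0, 5.0):
            logits = np.zeros((1, 6, 2))
            logits[..., 1] = margin
            cur = joint_loss(logits, labels)
            assert cur < prev
            prev = cur
        assert prev < 0.05

    def test_additivity_over_nodes(self, rng):
        """Equals the sum of six independently computed cross-entropies."""
        logits = rng.normal(size=(4, 6, 2))
        labels = rng.integers(0, 2, size=(4, 6))
        total = 0.0
        for k in range(6):
            z = logits[:, k, :]
            p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
            total += -np.log(p[np.arange(4), labels[:, k]]).mean()
        assert joint_loss(logits, labels) == pytest.approx(total, abs=1e-9)

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            joint_loss(np.zeros((1, 6, 2)), np.full((1, 6), 2))


class TestTraining:
    def _data(self, rng, n=64):
        cfg = _tiny_cfg(feature_dim=8, hidden=8, att_hidden=4, out_dim=4,
                        epochs=15, seed=5)
        X = rng.normal(size=(n, 6, cfg.input_dim))
        w = rng.normal(size=cfg.input_dim)
        Y = (X @ w > 0).astype(int)
        return cfg, X, Y

    def test_same_seed_identical_final_loss(self, rng):
        cfg, X, Y = self._data(rng)
        graph = build_prior_graph()
        log_a, log_b = [], []
        train_stage2(X, Y, graph, cfg, log=log_a)
        train_stage2(X, Y, graph, cfg, log=log_b)
        assert log_a[-1]["loss"] == log_b[-1]["loss"]

    def test_loss_decreases(self, rng):
        cfg, X, Y = self._data(rng)
        graph = build_prior_graph()
        log = []
        train_stage2(X, Y, graph, cfg, log=log)
        assert log[-1]["loss"] < log[0]["loss"]

    def test_single_class_split_rejected(self, rng):
        cfg, X, Y = self._data(rng)
        Y[:, 2] = 1
        with pytest.raises(ValueError, match="HA"):
            train_stage2(X, Y, build_prior_graph(), cfg)

    def test_predictions_in_unit_interval(self, rng):
        cfg, X, Y = self._data(rng)
        graph = build_prior_graph()
        params = train_stage2(X, Y, graph, cfg)
        probs = predict_joint(params, X, graph)
        assert probs.shape == (X.shape[0], 6)
        assert (probs >= 0).all() and (probs <= 1).all()


class TestExtractAttention:
    def test_zero_scorer_gives_uniform_attention(self, rng):
        cfg = _tiny_cfg()
        graph = build_prior_graph()
        params = init_params(cfg, rng)  # a2 = 0 at init
        X = rng.normal(size=(10, 6, cfg.input_dim))
        amap = extract_attention(params, X, graph)
        deg = graph.adjacency.sum(axis=1)
        for i in range(6):
            np.testing.assert_allclose(
                amap[i][graph.adjacency[i] == 1], 1.0 / deg[i], atol=1e-9
            )

    def test_zeros_on_non_edges_and_range(self, rng):
        cfg = _tiny_cfg()
        graph = build_prior_graph()
        params = init_params(cfg, rng)
        params.a2 = rng.normal(size=params.a2.shape)
        X = rng.normal(size=(10, 6, cfg.input_dim))
        amap = extract_attention(params, X, graph)
        assert (amap[graph.adjacency == 0] == 0).all()
        assert (amap >= 0).all() and (amap <= 1).all()
        np.testing.assert_allclose(amap.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_dataset_errors(self, rng):
        cfg = _tiny_cfg()
        params = init_params(cfg, rng)
        with pytest.raises(ValueError):
            extract_attention(params, np.zeros((0, 6, cfg.input_dim)),
                              build_prior_graph())


def test_node_input_dimension_contract():
    """Default fused node input: 128 video dims + 70 x 24 kinematic dims."""
    cfg = JointConfig()
    assert cfg.input_dim == 128 + 70 * 24 == 1808
    assert JointConfig(feature_dim=32, target_len=4).input_dim == 32 + 280
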