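"""Tests for network construction, the training loop, backprop and
checkpointing."""

import numpy as np
import pytest

from ipnet.data import TrainingBatch
from ipnet.network import (
    LayerParams,
    NetworkModel,
    TrainConfig,
    forward_pass,
    init_network,
    intrinsic_step,
    load_checkpoint,
    loss_and_grads,
    save_checkpoint,
    train,
    weight_step,
)
from ipnet.rules import IntrinsicLearningRates, IPState

RULES = ["ip", "infomax", "bn_incremental", "standard"]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def test_init_network_shapes_and_state_count():
    model = init_network([784, 50, 10], "ip", seed=0)
    assert [l.W.shape for l in model.layers] == [(50, 784), (10, 50)]
    n_states = sum(len(np.atleast_1d(l.rule_state.a)) for l in model.layers)
    assert n_states == 834  # input + hidden neurons carry intrinsic state
    model = init_network([3072, 150, 10], "ip", seed=0)
    assert [l.W.shape for l in model.layers] == [(150, 3072), (10, 150)]


def test_init_network_seeded_determinism():
    m1 = init_network([10, 8, 3], "standard", seed=42)
    m2 = init_network([10, 8, 3], "standard", seed=42)
    for l1, l2 in zip(m1.layers, m2.layers):
        assert np.array_equal(l1.W, l2.W)


def test_init_network_matched_weights_across_rules():
    """Every rule variant built from one seed starts from identical weights."""
    models = {r: init_network([6, 5, 4, 3], r, seed=9) for r in RULES}
    ref = models["standard"]
    for model in models.values():
        for l1, l2 in zip(model.layers, ref.layers):
            assert np.array_equal(l1.W, l2.W)
            assert np.array_equal(l1.B_add, l2.B_add)


def test_init_network_fresh_states():
    for rule, fields in [("ip", ("a", "b")), ("infomax", ("alpha", "beta")),
                         ("bn_incremental", ("a_bn", "b_bn"))]:
        model = init_network([4, 3, 2, 2], rule, seed=0)
        for layer in model.layers:
            gain, bias = fields
            assert np.all(getattr(layer.rule_state, gain) == 1.0)
            assert np.all(getattr(layer.rule_state, bias) == 0.0)
    assert all(l.rule_state is None for l in init_network([4, 3, 2], "standard", 0).layers)


def test_init_network_invalid_inputs():
    with pytest.raises(ValueError):
        init_network([4, 2], "ip", seed=0)  # no hidden layer
    with pytest.raises(ValueError):
        init_network([4, 0, 2], "ip", seed=0)
    with pytest.raises(ValueError):
        init_network([4, 3, 2], "dropout", seed=0)


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def _identity_net(rule_state=None):
    layers = [
        LayerParams(W=np.eye(2), B_add=np.zeros(2), rule_state=rule_state),
        LayerParams(W=np.eye(2), B_add=np.zeros(2), rule_state=None
                    if rule_state is None else IPState.initial(2)),
    ]
    return NetworkModel(layers=layers, layer_sizes=[2, 2, 2], rule_kind="standard"
                        if rule_state is None else "ip")


def test_forward_identity_weights_composition():
    """With identity weights the network computes relu(tanh(tanh(x)))."""
    x = np.array([[0.3, -1.2], [2.0, 0.0]])
    cache = forward_pass(_identity_net(), x)
    assert np.allclose(cache.y_out, np.maximum(np.tanh(np.tanh(x)), 0.0))


def test_forward_ip_identity_init_matches_standard():
    x = np.array([[0.5, -0.5], [1.5, 2.5]])
    c_std = forward_pass(_identity_net(), x)
    c_ip = forward_pass(_identity_net(rule_state=IPState.initial(2)), x)
    for a, b in zip(c_std.y, c_ip.y):
        assert np.array_equal(a, b)
    assert np.array_equal(c_std.y_out, c_ip.y_out)


def test_forward_zero_input_gives_zero_everywhere():
    cache = forward_pass(_identity_net(), np.zeros((3, 2)))
    assert all(np.all(u == 0) for u in cache.u)
    assert np.all(cache.y_out == 0)


def test_forward_errors():
    model = init_network([4, 3, 2], "ip", seed=0)
    with pytest.raises(ValueError):
        forward_pass(model, np.zeros((2, 5)))
    with pytest.raises(FloatingPointError):
        forward_pass(model, np.full((2, 4), np.inf))


# ---------------------------------------------------------------------------
# intrinsic step
# ---------------------------------------------------------------------------

def test_intrinsic_step_standard_is_noop(tiny_task):
    model = init_network([5, 4, 3], "standard", seed=0)
    W_before = [l.W.copy() for l in model.layers]
    cache = forward_pass(model, tiny_task[0].inputs[:8])
    intrinsic_step(model, cache, IntrinsicLearningRates(eta=0.5))
    for layer, W in zip(model.layers, W_before):
        assert np.array_equal(layer.W, W)
        assert layer.rule_state is None


def test_intrinsic_step_delegates_to_rule_update():
    """A single input neuron fed x=[1,-1] reproduces the one-step oracle."""
    model = init_network([1, 2, 2], "ip", seed=0)
    x = np.array([[1.0], [-1.0]])
    cache = forward_pass(model, x)
    intrinsic_step(model, cache, IntrinsicLearningRates(eta=0.1))
    a0 = float(model.layers[0].rule_state.a[0])
    assert a0 == pytest.approx(0.9 + 0.2 * np.tanh(1.0), rel=1e-9)
    assert float(model.layers[0].rule_state.b[0]) == 0.0


def test_intrinsic_step_output_layer_untouched():
    model = init_network([3, 4, 2], "ip", seed=1)
    cache = forward_pass(model, np.ones((4, 3)))
    intrinsic_step(model, cache, IntrinsicLearningRates(eta=0.2))
    # only non-output layers hold state; count equals weight-matrix count
    assert len(model.layers) == 2
    assert all(l.rule_state is not None for l in model.layers)


# ---------------------------------------------------------------------------
# weight step and gradients
# ---------------------------------------------------------------------------

def _fd_check(model, batch, rtol=1e-4, eps=1e-5):
    cache = forward_pass(model, batch)
    _, grads = loss_and_grads(model, cache, batch)

    def loss_at():
        c = forward_pass(model, batch)
        l, _ = loss_and_grads(model, c, batch)
        return l

    rng = np.random.default_rng(0)
    for l, layer in enumerate(model.layers):
        W = layer.W
        for _ in range(4):
            i, j = rng.integers(W.shape[0]), rng.integers(W.shape[1])
            orig = W[i, j]
            W[i, j] = orig + eps
            lp = loss_at()
            W[i, j] = orig - eps
            lm = loss_at()
            W[i, j] = orig
            fd = (lp - lm) / (2 * eps)
            an = grads[l][0][i, j]
            assert an == pytest.approx(fd, rel=rtol, abs=1e-8)
        k = int(rng.integers(len(layer.B_add)))
        orig = layer.B_add[k]
        layer.B_add[k] = orig + eps
        lp = loss_at()
        layer.B_add[k] = orig - eps
        lm = loss_at()
        layer.B_add[k] = orig
        assert grads[l][1][k] == pytest.approx((lp - lm) / (2 * eps), rel=rtol, abs=1e-8)


@pytest.mark.parametrize("rule", RULES)
def test_finite_difference_gradients(rule, rng):
    model = init_network([3, 5, 4, 3], rule, seed=3)
    batch = TrainingBatch(inputs=rng.normal(1.0, 1.0, size=(12, 3)),
                          targets=rng.integers(0, 3, size=12))
    _fd_check(model, batch)


def test_finite_difference_gradients_with_adapted_gains(rng):
    """Backprop scales with the cached 1/a: still exact after gains move."""
    model = init_network([3, 5, 4, 3], "ip", seed=3)
    for layer in model.layers:
        layer.rule_state = IPState(a=2.0 * layer.rule_state.a,
                                   b=layer.rule_state.b + 0.3)
    batch = TrainingBatch(inputs=rng.normal(1.0, 1.0, size=(12, 3)),
                          targets=rng.integers(0, 3, size=12))
    _fd_check(model, batch)


def test_softmax_cross_entropy_single_neuron_closed_form():
    """One linear path: gradient equals softmax(p) - onehot through ReLU."""
    layers = [LayerParams(W=np.eye(2), B_add=np.zeros(2), rule_state=None),
              LayerParams(W=np.eye(2), B_add=np.array([0.5, 0.1]), rule_state=None)]
    model = NetworkModel(layers=layers, layer_sizes=[2, 2, 2], rule_kind="standard")
    batch = TrainingBatch(inputs=np.array([[0.4, -0.2]]), targets=np.array([0]))
    cache = forward_pass(model, batch)
    loss, grads = loss_and_grads(model, cache, batch)
    z = cache.z_out[0]
    r = np.maximum(z, 0)
    p = np.exp(r - r.max())
    p /= p.sum()
    assert loss == pytest.approx(-np.log(p[0]), rel=1e-12)
    expected_gB = (p - np.array([1.0, 0.0])) * (z > 0)
    assert np.allclose(grads[1][1], expected_gB, rtol=1e-12)


def test_weight_step_zero_lr_leaves_weights(tiny_task):
    model = init_network([5, 4, 3], "standard", seed=0)
    W_before = [l.W.copy() for l in model.layers]
    batch = TrainingBatch(tiny_task[0].inputs[:16], tiny_task[0].targets[:16])
    cache = forward_pass(model, batch)
    _, loss = weight_step(model, cache, batch, TrainConfig(synaptic_lr=0.0))
    assert loss > 0
    for layer, W in zip(model.layers, W_before):
        assert np.array_equal(layer.W, W)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def test_train_zero_epochs_is_noop(tiny_task):
    model = init_network([5, 4, 3], "ip", seed=0)
    W_before = [l.W.copy() for l in model.layers]
    record = train(model, tiny_task[0], TrainConfig(epochs=0, seed=0))
    assert record.train_loss == [] and not record.diverged
    for layer, W in zip(model.layers, W_before):
        assert np.array_equal(layer.W, W)


def test_train_reduces_loss_on_separable_task(tiny_task):
    trainset, _ = tiny_task
    model = init_network([5, 16, 3], "standard", seed=0)
    record = train(model, trainset, TrainConfig(synaptic_lr=0.01, epochs=15, seed=0))
    assert record.train_loss[-1] < 0.5 * record.train_loss[0]
    assert record.train_loss[-1] < 0.2


def test_train_deterministic_trace(tiny_task):
    cfg = TrainConfig(synaptic_lr=0.01, intrinsic_eta=1e-3, epochs=3, seed=5)
    traces = []
    for _ in range(2):
        model = init_network([5, 8, 3], "ip", seed=5)
        traces.append(train(model, tiny_task[0], cfg).train_loss)
    assert traces[0] == traces[1]


def test_train_records_validation_loss(tiny_task):
    trainset, testset = tiny_task
    model = init_network([5, 8, 3], "ip", seed=0)
    record = train(model, trainset, TrainConfig(epochs=2, synaptic_lr=0.01, seed=0),
                   val_dataset=testset)
    assert len(record.val_loss) == len(record.train_loss) == 2
    frame = record.to_frame(run_id="r", seed=0)
    assert set(frame.columns) == {"run_id", "seed", "epoch", "split", "loss"}
    assert len(frame) == 4


def test_train_marks_divergence(tiny_task):
    """Non-finite activations must be caught and flagged, not propagated."""
    trainset, _ = tiny_task
    model = init_network([5, 8, 3], "standard", seed=0)
    model.layers[0].W *= np.inf  # corrupt the weights: NaN on the first batch
    record = train(model, trainset, TrainConfig(synaptic_lr=1.0, epochs=2, seed=0))
    assert record.diverged
    assert record.train_loss == []


def test_train_empty_dataset_errors():
    model = init_network([5, 8, 3], "standard", seed=0)
    empty = TrainingBatch(np.empty((0, 5)), np.empty(0, dtype=int))
    with pytest.raises(ValueError):
        train(model, empty, TrainConfig(epochs=1))


def test_ip_frozen_rates_reproduces_standard_bitwise(tiny_task):
    """IP with eta=0 (gains pinned at 1, biases at 0) is exactly a standard
    network: identical seeds give bitwise-identical loss traces."""
    trainset, _ = tiny_task
    m_std = init_network([5, 8, 3], "standard", seed=11)
    m_ip = init_network([5, 8, 3], "ip", seed=11)
    r_std = train(m_std, trainset, TrainConfig(synaptic_lr=0.02, epochs=3, seed=11))
    r_ip = train(m_ip, trainset,
                 TrainConfig(synaptic_lr=0.02, intrinsic_eta=0.0, epochs=3, seed=11))
    assert r_std.train_loss == r_ip.train_loss
    for l_std, l_ip in zip(m_std.layers, m_ip.layers):
        assert np.array_equal(l_std.W, l_ip.W)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rule", RULES)
def test_checkpoint_round_trip_bit_exact(rule, tmp_path, tiny_task):
    model = init_network([5, 6, 4, 3], rule, seed=2)
    train(model, tiny_task[0], TrainConfig(synaptic_lr=0.01, intrinsic_eta=1e-3,
                                           epochs=1, seed=2))
    path = tmp_path / "model.h5"
    save_checkpoint(model, path, metadata={"seed": 2})
    loaded = load_checkpoint(path)
    assert loaded.rule_kind == model.rule_kind
    assert loaded.layer_sizes == model.layer_sizes
    for l1, l2 in zip(model.layers, loaded.layers):
        assert np.array_equal(l1.W, l2.W)
        assert np.array_equal(l1.B_add, l2.B_add)
        if rule != "standard":
            for f in vars(l1.rule_state):
                assert np.array_equal(np.atleast_1d(getattr(l1.rule_state, f)),
                                      np.atleast_1d(getattr(l2.rule_state, f)))
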