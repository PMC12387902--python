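"""Auto Contractive Map: forward pass, updates, training, normalization.

The single-step oracle below is an independent scalar re-derivation of
the contractive dynamics (plain Python floats, explicit loops); the
vectorized implementation must agree with it to 1e-12.
"""

import warnings

import numpy as np
import pytest

import inkmap as im
from inkmap.autocm import initial_state
from conftest import make_scaled


def scalar_step(s, v, w, C, lam):
    """One forward+update pass in pure scalar arithmetic."""
    N = len(s)
    h = [s[i] * (1 - v[i] / C) for i in range(N)]
    net = [sum(h[j] * (1 - w[i][j] / C) for j in range(N)) for i in range(N)]
    o = [h[i] * (1 - net[i] / C) for i in range(N)]
    v2 = [min(C, max(0.0, v[i] + lam * (s[i] - h[i]) * (1 - v[i] / C)))
          for i in range(N)]
    w2 = [
        [
            min(C, max(0.0, w[i][j] + lam * (h[i] - o[i]) * (1 - w[i][j] / C) * h[j]))
            for j in range(N)
        ]
        for i in range(N)
    ]
    return h, net, o, v2, w2


def state_with(v, w, C=1.0, lam=0.1):
    cfg = im.AutoCMConfig(contraction=C, learning_rate=lam)
    st = initial_state(len(v), cfg)
    st.v = np.array(v, float)
    st.w = np.array(w, float)
    return st


def test_zero_record_annihilates_signals():
    st = state_with([0.3, 0.4], [[0.1, 0.2], [0.2, 0.1]])
    h, net, o = im.autocm_forward(np.zeros(2), st)
    assert np.all(h == 0) and np.all(net == 0) and np.all(o == 0)


def test_full_contraction_kills_hidden_layer():
    st = state_with([1.0, 1.0], [[0.1, 0.2], [0.2, 0.1]])
    h, _, _ = im.autocm_forward(np.array([0.7, 0.9]), st)
    assert np.all(h == 0)


def test_hand_computed_forward_pass():
    """N=2, C=1, v=0, w=0, s=(1,1): h=(1,1), net=(2,2), o=(-1,-1)."""
    st = state_with([0.0, 0.0], [[0.0, 0.0], [0.0, 0.0]])
    h, net, o = im.autocm_forward(np.ones(2), st)
    assert np.allclose(h, [1, 1]) and np.allclose(net, [2, 2])
    assert np.allclose(o, [-1, -1])


def test_zero_record_update_is_identity():
    st = state_with([0.3, 0.4], [[0.1, 0.2], [0.2, 0.1]])
    v0, w0 = st.v.copy(), st.w.copy()
    im.autocm_update(np.zeros(2), st)
    assert np.array_equal(st.v, v0) and np.array_equal(st.w, w0)


def test_saturated_mono_weight_is_fixed_point():
    st = state_with([1.0, 1.0], [[0.1, 0.2], [0.2, 0.1]])
    im.autocm_update(np.array([1.0, 1.0]), st)
    assert np.allclose(st.v, 1.0)


@pytest.mark.parametrize("case", range(5))
def test_single_step_matches_scalar_oracle(case):
    rng = np.random.default_rng(100 + case)
    N = rng.integers(2, 6)
    C, lam = 1.0, 0.1
    s = rng.random(N)
    v = list(rng.uniform(0, 0.9, N))
    w = [[float(x) for x in row] for row in rng.uniform(0, 0.9, (N, N))]
    st = state_with(v, [list(r) for r in w], C=C, lam=lam)

    h, net, o = im.autocm_forward(s, st)
    im.autocm_update(s, st)
    h_o, net_o, o_o, v_o, w_o = scalar_step(list(s), v, w, C, lam)
    assert np.allclose(h, h_o, atol=1e-12)
    assert np.allclose(net, net_o, atol=1e-12)
    assert np.allclose(o, o_o, atol=1e-12)
    assert np.allclose(st.v, v_o, atol=1e-12)
    assert np.allclose(st.w, w_o, atol=1e-12)


def test_hand_case_from_initial_weights():
    """N=2, s=(1,1), lambda=0.1, v=w=0.01: matches the scalar oracle."""
    st = state_with([0.01, 0.01], [[0.01, 0.01], [0.01, 0.01]], lam=0.1)
    im.autocm_update(np.ones(2), st)
    _, _, _, v_o, w_o = scalar_step(
        [1.0, 1.0], [0.01, 0.01], [[0.01, 0.01], [0.01, 0.01]], 1.0, 0.1
    )
    assert np.allclose(st.v, v_o, atol=1e-12)
    assert np.allclose(st.w, w_o, atol=1e-12)


def test_dimension_mismatch_rejected():
    st = state_with([0.1, 0.1], [[0.1, 0.1], [0.1, 0.1]])
    with pytest.raises(ValueError):
        im.autocm_forward(np.zeros(3), st)


def test_nonfinite_record_rejected():
    st = state_with([0.1, 0.1], [[0.1, 0.1], [0.1, 0.1]])
    with pytest.raises(ValueError):
        im.autocm_forward(np.array([np.nan, 0.0]), st)


# ---------------------------------------------------------------------------
# training dynamics


def toy_scaled(seed=0, n=10, p=5):
    rng = np.random.default_rng(seed)
    return make_scaled(rng.random((n, p)))


def test_mono_weights_saturate_and_are_monotone():
    scaled = toy_scaled()
    cfg = im.AutoCMConfig()
    st = initial_state(scaled.values.shape[1], cfg)
    rng = np.random.default_rng(cfg.seed)
    prev = st.v.copy()
    for _ in range(50):
        for i in rng.permutation(len(scaled.values)):
            im.autocm_update(scaled.values[i], st)
        assert np.all(st.v >= prev - 1e-15)
        prev = st.v.copy()


def test_training_reaches_saturation():
    st = im.train_autocm(toy_scaled(), im.AutoCMConfig())
    assert st.converged
    assert st.saturation_gap <= 1e-6


def test_duplicate_columns_attain_maximal_association():
    # columns share one marginal (permutations of a common grid), so the
    # duplicated pair is the only perfectly co-varying one
    rng = np.random.default_rng(77)
    grid = np.linspace(0.0, 1.0, 15)
    cols = [rng.permutation(grid) for _ in range(4)]
    X = np.column_stack(cols + [cols[0]])  # v4 duplicates v0
    st = im.train_autocm(make_scaled(X), im.AutoCMConfig())
    a = im.normalized_associations(st).values
    off = a - np.eye(5)
    assert off[0, 4] == off.max()


def test_all_zero_dataset_never_converges():
    scaled = make_scaled(np.zeros((4, 3)))
    cfg = im.AutoCMConfig(max_epochs=20)
    with pytest.warns(UserWarning, match="did not reach saturation"):
        st = im.train_autocm(scaled, cfg)
    assert not st.converged
    assert np.allclose(st.v, cfg.init_weight)
    assert np.allclose(st.w, cfg.init_weight)


def test_record_order_changes_little_at_convergence():
    scaled = toy_scaled(seed=5, n=12, p=8)
    a1 = im.normalized_associations(
        im.train_autocm(scaled, im.AutoCMConfig(seed=1))).values
    a2 = im.normalized_associations(
        im.train_autocm(scaled, im.AutoCMConfig(seed=2))).values
    assert np.abs(a1 - a2).max() <= 0.01


def test_variable_permutation_equivariance():
    scaled = toy_scaled(seed=3, n=8, p=5)
    perm = np.array([2, 0, 4, 1, 3])
    permuted = make_scaled(scaled.values[:, perm],
                           names=[scaled.variable_names[j] for j in perm])
    a = im.normalized_associations(im.train_autocm(scaled, im.AutoCMConfig())).values
    b = im.normalized_associations(im.train_autocm(permuted, im.AutoCMConfig())).values
    assert np.allclose(b, a[np.ix_(perm, perm)], atol=1e-9)


# ---------------------------------------------------------------------------
# normalization


def test_normalized_matrix_is_symmetric_unit_diagonal(associations):
    a = associations.values
    assert np.allclose(a, a.T)
    assert np.allclose(np.diag(a), 1.0)
    assert a.min() >= 0.0 and a.max() <= 1.0


def test_saturated_weight_normalizes_to_one():
    st = state_with([1.0, 1.0], [[0.0, 1.0], [1.0, 0.0]])
    a = im.normalized_associations(st, ["x", "y"])
    assert a.entry("x", "y") == 1.0


def test_config_validation():
    with pytest.raises(ValueError):
        im.AutoCMConfig(contraction=0)
    with pytest.raises(ValueError):
        im.AutoCMConfig(init_weight=2.0)
    with pytest.raises(ValueError):
        im.AutoCMConfig(learning_rate=-1)


def test_fixture_training_converges(autocm_state):
    assert autocm_state.converged
    assert autocm_state.epochs < 10_000
    assert len(autocm_state.variable_names) == 47
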