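import numpy as np
import pytest
from scipy.linalg import expm

from s4clm.s4_core import (
    DiscretizationError, StateSpaceParams, compute_kernel, convolve_sequence,
    discretize, hippo_legs_dplr, hippo_legs_matrix, init_state_space,
    init_state_space_bank, recurrent_step, run_recurrence, spectral_radius,
)


def test_dplr_materializes_hippo_matrix():
    # structured factors must reproduce the dense operator
    for N in (4, 8, 16):
        Lam, p, q, V = hippo_legs_dplr(N)
        A = V @ (np.diag(Lam) - np.outer(p, q.conj())) @ V.conj().T
        assert np.abs(A.imag).max() < 1e-10
        np.testing.assert_allclose(A.real, hippo_legs_matrix(N), atol=1e-10)


def test_init_deterministic_and_stable():
    a = init_state_space(8, rng=42)
    b = init_state_space(8, rng=42)
    np.testing.assert_array_equal(a.B, b.B)
    np.testing.assert_array_equal(a.C, b.C)
    assert a.delta == b.delta
    # decaying continuous spectrum and contractive discrete operator
    assert np.all(init_state_space(4, rng=0).Lambda.real <= 0)
    assert spectral_radius(discretize(a)) <= 1.0 + 1e-12


@pytest.mark.parametrize("A,delta,expected_Abar,expected_Bbar", [
    ([[0.0]], 0.1, 1.0, 0.1),   # integrator
    ([[-1.0]], 2.0, 0.0, None),  # pole mapped to the origin
])
def test_bilinear_scalar_closed_forms(A, delta, expected_Abar, expected_Bbar):
    p = discretize(StateSpaceParams.from_continuous(A, [1.0], [1.0], delta))
    assert p.A_bar[0, 0] == pytest.approx(expected_Abar)
    if expected_Bbar is not None:
        assert p.B_bar[0] == pytest.approx(expected_Bbar)


def test_bilinear_matches_exponential_as_delta_shrinks():
    rng = np.random.default_rng(0)
    A = rng.standard_normal((6, 6))
    A = A - 3.5 * np.eye(6)  # push the spectrum left for stability
    errs = []
    for dt in (1e-2, 1e-3):
        p = discretize(StateSpaceParams.from_continuous(A, np.ones(6),
                                                        np.ones(6), dt))
        exact = expm(dt * A)
        errs.append(np.abs(p.A_bar - exact).max() / np.abs(exact).max())
    assert errs[0] < 1e-3 and errs[1] < 1e-5
    assert errs[1] < errs[0] / 10  # vanishing discretization error


def test_discretize_singular_raises():
    p = StateSpaceParams.from_continuous([[2.0]], [1.0], [1.0], 1.0)
    with pytest.raises(DiscretizationError):
        discretize(p)


def test_kernel_scalar_geometric_series():
    p = StateSpaceParams.from_discrete([[0.5]], [1.0], [1.0], 0.0)
    np.testing.assert_allclose(compute_kernel(p, 3).taps, [1.0, 0.5, 0.25])


def test_kernel_first_tap_is_cb():
    p = discretize(init_state_space(8, rng=3))
    k = compute_kernel(p, 5)
    assert k.taps[0] == pytest.approx(float(p.C_bar @ p.B_bar))


@pytest.mark.parametrize("N,L", [(8, 32), (8, 33), (16, 64)])
def test_structured_kernel_matches_matrix_powers(N, L):
    p = discretize(init_state_space(N, rng=N + L))
    naive = compute_kernel(p, L, method="naive").taps
    structured = compute_kernel(p, L, method="structured").taps
    rel = np.abs(naive - structured).max() / np.abs(naive).max()
    assert rel < 1e-6


def test_recurrence_hand_example():
    p = StateSpaceParams.from_discrete([[0.5]], [1.0], [1.0], 0.0)
    x = np.zeros(1)
    ys = []
    for u in (1.0, 0.0, 0.0):
        x, y = recurrent_step(p, x, u)
        ys.append(y)
    np.testing.assert_allclose(ys, [1.0, 0.5, 0.25])


def test_impulse_response_equals_kernel():
    p = discretize(init_state_space(6, rng=1))
    p.D_bar = 0.0
    L = 20
    u = np.zeros(L)
    u[0] = 1.0
    np.testing.assert_allclose(run_recurrence(p, u),
                               compute_kernel(p, L).taps, atol=1e-10)


def test_zero_input_zero_output():
    p = discretize(init_state_space(4, rng=2))
    assert np.all(run_recurrence(p, np.zeros(10)) == 0)


def test_convolution_examples():
    from s4clm.s4_core import ConvKernel
    y = convolve_sequence(np.array([1.0, 0, 0]),
                          ConvKernel(np.array([1.0, 0.5, 0.25]), 3), 0.0)
    np.testing.assert_allclose(y, [1.0, 0.5, 0.25])
    u = np.arange(5.0)
    ident = np.zeros(5)
    ident[0] = 1.0
    np.testing.assert_allclose(
        convolve_sequence(u, ConvKernel(ident, 5), 0.0), u, atol=1e-12)


def test_convolution_equals_recurrence_long():
    # the dual formulation: global convolution == unrolled recurrence
    rng = np.random.default_rng(7)
    for seed in range(5):
        p = discretize(init_state_space(12, rng=seed))
        u = rng.standard_normal(128)
        y_conv = convolve_sequence(u, compute_kernel(p, 128), p.D_bar)
        y_rec = run_recurrence(p, u)
        rel = np.abs(y_conv - y_rec).max() / np.abs(y_rec).max()
        assert rel < 1e-4


def test_bounded_output_on_bounded_input():
    for N in (8, 32):
        p = discretize(init_state_space(N, rng=N))
        u = np.ones(10 * N)
        y = convolve_sequence(u, compute_kernel(p, 10 * N), p.D_bar)
        assert np.all(np.isfinite(y)) and np.abs(y).max() < 1e3


def test_bank_gives_independent_channels():
    bank = init_state_space_bank(4, model_width=3, rng=0)
    deltas = {p.delta for p in bank}
    assert len(bank) == 3 and len(deltas) == 3
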