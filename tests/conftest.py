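"""Shared fixtures and independent oracle helpers.

The oracle helpers recompute GLLA filter responses and biased oscillator
coefficients from first principles (pseudo-inverse of the quadratic
basis, eigenmodes of the one-step propagator) so that tests never reuse
the implementation they are checking.
"""

from __future__ import annotations

import numpy as np
import pytest


def glla_basis_weights(tau: int, embed: int, delta: float = 1.0) -> np.ndarray:
    """Independent route to the GLLA weights: pseudo-inverse of the
    centered quadratic basis (no shared code with the implementation)."""
    t = (np.arange(embed) - (embed - 1) / 2.0) * tau * delta
    basis = np.column_stack([np.ones(embed), t, t**2 / 2.0])
    return np.linalg.pinv(basis).T  # embed x 3


def glla_filter_response(lam: complex, tau: int, embed: int, delta: float = 1.0) -> np.ndarray:
    """Complex response G_k(lambda) of each GLLA output to exp(lambda*t):
    summing the lagged exponentials against the weight columns."""
    w = glla_basis_weights(tau, embed, delta)
    t = (np.arange(embed) - (embed - 1) / 2.0) * tau * delta
    modes = np.exp(lam * t)
    return modes @ w  # (G0, G1, G2)


def sinusoid_ratio_oracle(omega: float, tau: int, embed: int) -> float:
    """Closed-form x2/x0 GLLA response on a pure cosine, via the
    lagged-cosine sum."""
    g = glla_filter_response(1j * omega, tau, embed)
    return float(np.real(g[2]) / np.real(g[0]))


def rk4_eigenmode(eta: float, zeta: float) -> complex:
    """Exact continuous-rate eigenvalue of the discrete RK4 propagator of
    x'' = eta*x + zeta*x' (the mode the simulated data actually follow)."""
    m = np.array([[0.0, 1.0], [eta, zeta]])
    phi = np.eye(2)
    term = np.eye(2)
    for k in range(1, 5):
        term = term @ m / k
        phi = phi + term
    eig = np.linalg.eigvals(phi)
    lam = np.log(eig)
    # the mode with positive imaginary part (its conjugate is the other)
    return lam[np.argmax(lam.imag)]


def biased_self_coefficients(eta: float, zeta: float, tau: int, embed: int) -> tuple[float, float]:
    """GLLA-bias-corrected oracle for an uncoupled damped oscillator:
    the (eta_hat, zeta_hat) the regression of x2 on (x0, x1) must return,
    solving a*G0 + b*G1 = G2 over the real and imaginary parts."""
    lam = rk4_eigenmode(eta, zeta)
    g0, g1, g2 = glla_filter_response(lam, tau, embed)
    a_mat = np.array([[g0.real, g1.real], [g0.imag, g1.imag]])
    rhs = np.array([g2.real, g2.imag])
    a, b = np.linalg.solve(a_mat, rhs)
    return float(a), float(b)


def dominant_period(x: np.ndarray) -> float:
    """Periodogram oracle: period (in samples) of the largest spectral peak."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x)))) ** 2
    freqs = np.fft.rfftfreq(len(x))
    i = int(np.argmax(spec[1:])) + 1
    return 1.0 / freqs[i]


@pytest.fixture(scope="session")
def slow_dyad_noise_free():
    """A noise-free slow archetype dyad, reused by several tests."""
    from dyadosc import synth

    return synth.make_archetype("slow_inphase_damping", n_steps=150, seed=0, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study with short series (cheap, label-focused)."""
    from dyadosc import synth

    return synth.simulate_study(n_dyads=20, seed=42, n_steps=30, noise_sd=5.0)
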