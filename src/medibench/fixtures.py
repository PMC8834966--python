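"""Small synthetic generators with known ground truth.

These are the test bench for the inference methods: a discrete
generalized Lotka--Volterra map (sparse-regression recovery), a pair of
unidirectionally coupled logistic maps (cross-mapping direction), and a
correlated Gaussian pair (correlation calibration).  Output matches the
sampled-series format so inference operations consume it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .mediator_sim import SampledSeries

__all__ = [
    "FixtureSpec",
    "gen_discrete_glv",
    "gen_coupled_logistic",
    "gen_correlated_pair",
    "as_series",
]


@dataclass
class FixtureSpec:
    generator: str
    parameters: dict
    length: int
    noise_sd: float
    seed: Optional[int]


def as_series(values: np.ndarray, tau: int = 1, dt: float = 0.025) -> SampledSeries:
    values = np.asarray(values, dtype=float)
    steps = np.arange(values.shape[0]) * tau
    return SampledSeries(values=values, tau=tau, source_steps=steps, dt=dt)


def gen_discrete_glv(
    A: np.ndarray,
    b: np.ndarray,
    n_steps: int,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    x0: Optional[np.ndarray] = None,
    dt: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Iterate ``x(t+1) = x(t) * exp(dt * (b + A x(t)) + noise)``.

    Returns the ``(n_steps + 1, n)`` series and the off-diagonal nonzero
    pattern of ``A`` as ground truth.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    n = A.shape[0]
    rng = rng or np.random.default_rng()
    x = np.full(n, 0.1) if x0 is None else np.array(x0, dtype=float)
    if np.any(x <= 0):
        raise ValueError("initial abundances must be positive")
    out = np.empty((n_steps + 1, n))
    out[0] = x
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(n_steps):
            growth = dt * (b + A @ x)
            if noise_sd > 0:
                growth = growth + noise_sd * rng.standard_normal(n)
            x = x * np.exp(growth)
            if not np.all(np.isfinite(x)) or np.any(x > 1e12):
                raise RuntimeError(f"gLV map diverged at step {t + 1}")
            out[t + 1] = x
    truth = A != 0
    np.fill_diagonal(truth, False)
    return out, truth


def gen_coupled_logistic(
    coupling: float,
    n_steps: int,
    rng: Optional[np.random.Generator] = None,
    x0: float = 0.4,
    y0: float = 0.2,
) -> Tuple[np.ndarray, bool]:
    """Unidirectionally coupled logistic maps.

    ``x(t+1) = x (3.8 - 3.8 x)`` drives ``y(t+1) = y (3.5 - 3.5 y -
    coupling * x)``; the true direction is x -> y iff ``coupling > 0``.
    Initial values may be jittered through ``rng`` for replicate draws.
    """
    if coupling < 0:
        raise ValueError("coupling must be non-negative")
    if rng is not None:
        x0 = float(np.clip(x0 + 0.1 * (rng.random() - 0.5), 0.05, 0.95))
        y0 = float(np.clip(y0 + 0.1 * (rng.random() - 0.5), 0.05, 0.95))
    x, y = x0, y0
    out = np.empty((n_steps + 1, 2))
    out[0] = (x, y)
    for t in range(n_steps):
        x, y = x * (3.8 - 3.8 * x), y * (3.5 - 3.5 * y - coupling * x)
        out[t + 1] = (x, y)
    return out, coupling > 0


def gen_correlated_pair(
    rho: float, n: int, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Bivariate normal sample with correlation ``rho``, shape ``(n, 2)``."""
    if abs(rho) > 1:
        raise ValueError("|rho| must be <= 1")
    rng = rng or np.random.default_rng()
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return rng.multivariate_normal([0.0, 0.0], cov, size=n)
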