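"""Stochastic community simulators.

Four model variants are supported, identified by a string ``model_id``:

``"M"``
    Chemically mediated interactions with per-species logistic growth.
``"Mprime"``
    Same chemical coupling but a shared (competitive) logistic term.
``"D"``
    Direct pairwise interactions, per-species logistic growth.
``"Dprime"``
    Direct pairwise interactions, shared logistic term.

Species abundances and chemical amounts evolve in continuous time; an
explicit Euler--Maruyama scheme integrates the stochastic dynamics on a
fixed grid.  Abundances are in units of the carrying capacity ``K`` and
time is in days (``dt = 1`` corresponds to one day).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MODEL_IDS",
    "MEDIATOR_MODELS",
    "DIRECT_MODELS",
    "NOISE_FORMS",
    "MediatorParams",
    "DirectParams",
    "SystemState",
    "SimConfig",
    "Trajectory",
    "SampledSeries",
    "IntegrationError",
    "sample_mediator_params",
    "derive_direct_matrix",
    "drift",
    "integrate",
    "resample_tail",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
    "write_series_tsv",
    "read_series_tsv",
]

MEDIATOR_MODELS = ("M", "Mprime")
DIRECT_MODELS = ("D", "Dprime")
MODEL_IDS = MEDIATOR_MODELS + DIRECT_MODELS

NOISE_FORMS = ("additive_sqrt_dt", "additive_dt", "multiplicative")


class IntegrationError(RuntimeError):
    """Raised when an integration step produces a non-finite state."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class MediatorParams:
    """Rate and affinity parameters of the chemically mediated models.

    Attributes
    ----------
    n, m : int
        Number of species and of mediator chemicals.
    r : (n,) ndarray
        Intrinsic growth rates (1/day).
    K : float
        Carrying capacity (abundance units).
    delta : float
        Dilution rate (1/day).
    kappa : (n, m) ndarray
        Half-saturation amounts of chemical effects; strictly positive.
    rho_plus, rho_minus : (n, m) ndarray
        Maximal positive / negative effect of each chemical on each
        species (1/day).
    alpha : (m, n) ndarray
        Maximal consumption rate of each chemical by each species.
    beta : (m, n) ndarray
        Production rate of each chemical by each species.
    """

    n: int
    m: int
    r: np.ndarray
    K: float
    delta: float
    kappa: np.ndarray
    rho_plus: np.ndarray
    rho_minus: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        for name in ("kappa", "rho_plus", "rho_minus", "alpha", "beta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        n, m = self.n, self.m
        if self.r.shape != (n,):
            raise ValueError(f"r must have shape ({n},), got {self.r.shape}")
        for name, shape in (
            ("kappa", (n, m)),
            ("rho_plus", (n, m)),
            ("rho_minus", (n, m)),
            ("alpha", (m, n)),
            ("beta", (m, n)),
        ):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any(self.kappa <= 0):
            raise ValueError("kappa entries must be strictly positive")
        if np.any(self.r < 0):
            raise ValueError("r must be non-negative")

    def copy(self) -> "MediatorParams":
        return MediatorParams(
            n=self.n,
            m=self.m,
            r=self.r.copy(),
            K=self.K,
            delta=self.delta,
            kappa=self.kappa.copy(),
            rho_plus=self.rho_plus.copy(),
            rho_minus=self.rho_minus.copy(),
            alpha=self.alpha.copy(),
            beta=self.beta.copy(),
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "m": self.m,
            "K": self.K,
            "delta": self.delta,
            "r": self.r.tolist(),
            "kappa": self.kappa.tolist(),
            "rho_plus": self.rho_plus.tolist(),
            "rho_minus": self.rho_minus.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MediatorParams":
        return cls(
            n=int(d["n"]),
            m=int(d["m"]),
            r=np.asarray(d["r"], dtype=float),
            K=float(d["K"]),
            delta=float(d["delta"]),
            kappa=np.asarray(d["kappa"], dtype=float),
            rho_plus=np.asarray(d["rho_plus"], dtype=float),
            rho_minus=np.asarray(d["rho_minus"], dtype=float),
            alpha=np.asarray(d["alpha"], dtype=float),
            beta=np.asarray(d["beta"], dtype=float),
        )


@dataclass
class DirectParams:
    """Parameters of the direct-interaction (pairwise) models.

    ``A[i, j]`` is the per-abundance effect of species ``j`` on the growth
    rate of species ``i`` (1/day); signs are unrestricted.
    """

    A: np.ndarray
    r: np.ndarray
    K: float
    delta: float

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"A must be square, got shape {self.A.shape}")
        if self.r.shape != (self.A.shape[0],):
            raise ValueError("r length must match A")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("A contains non-finite entries")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def to_dict(self) -> dict:
        return {
            "A": self.A.tolist(),
            "r": self.r.tolist(),
            "K": self.K,
            "delta": self.delta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DirectParams":
        return cls(
            A=np.asarray(d["A"], dtype=float),
            r=np.asarray(d["r"], dtype=float),
            K=float(d["K"]),
            delta=float(d["delta"]),
        )


@dataclass
class SystemState:
    """Instantaneous abundances ``x`` (species) and amounts ``c`` (chemicals)."""

    x: np.ndarray
    c: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.c is not None:
            self.c = np.asarray(self.c, dtype=float)
        if np.any(self.x < 0) or (self.c is not None and np.any(self.c < 0)):
            raise ValueError("state entries must be non-negative")


@dataclass
class SimConfig:
    """Integration settings for one stochastic run."""

    dt: float = 0.025
    t_max: int = 10_000
    t0: int = 2_000
    sigma: float = 1.0
    eps: float = 1e-7
    seed: Optional[int] = None
    noise_on_chemicals: bool = True
    noise_form: str = "additive_sqrt_dt"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.t0 < self.t_max):
            raise ValueError("t0 must satisfy 0 <= t0 < t_max")
        if self.sigma < 0 or self.eps < 0:
            raise ValueError("sigma and eps must be non-negative")
        if self.noise_form not in NOISE_FORMS:
            raise ValueError(f"noise_form must be one of {NOISE_FORMS}")

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "t_max": self.t_max,
            "t0": self.t0,
            "sigma": self.sigma,
            "eps": self.eps,
            "seed": self.seed,
            "noise_on_chemicals": self.noise_on_chemicals,
            "noise_form": self.noise_form,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        return cls(**d)


@dataclass
class Trajectory:
    """Result of one stochastic integration.

    ``x`` has shape ``(t_max + 1, n)``; ``c`` has shape ``(t_max + 1, m)``
    for the mediator models and is ``None`` for the direct models.
    """

    times: np.ndarray
    x: np.ndarray
    c: Optional[np.ndarray]
    model_id: str
    params: object
    config: SimConfig

    @property
    def n(self) -> int:
        return self.x.shape[1]

    def post_transient_mean(self) -> np.ndarray:
        """Time-averaged abundances over steps ``t0 + 1 .. t_max``."""
        return self.x[self.config.t0 + 1 :].mean(axis=0)


@dataclass
class SampledSeries:
    """Evenly spaced tail resampling of a trajectory (species only)."""

    values: np.ndarray  # (n_points, n)
    tau: int
    source_steps: np.ndarray
    dt: float = 0.025

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.source_steps = np.asarray(self.source_steps, dtype=int)
        if self.values.shape[0] != self.source_steps.shape[0]:
            raise ValueError("values and source_steps length mismatch")
        d = np.diff(self.source_steps)
        if len(d) and (np.any(d <= 0) or np.any(d != d[0])):
            raise ValueError("source steps must be strictly increasing and even")

    @property
    def n_points(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def span_days(self) -> float:
        """Length of the sampling window in days, counting one sampling
        interval per point (100 points at ``tau = 80`` with ``dt = 0.025``
        cover a 200-day window)."""
        return self.n_points * self.tau * self.dt


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

#: sparse-uniform sampling ranges: (probability nonzero, low, high)
PARAM_DISTRIBUTIONS = {
    "r": (1.0, 0.05, 0.5),
    "kappa": (1.0, 0.5e-3, 1.5e-3),
    "rho_plus": (0.2, 0.05, 0.5),
    "rho_minus": (0.2, 0.05, 0.5),
    "alpha": (0.2, 0.5, 1.5),
    "beta": (0.2, 0.05, 0.15),
}

DEFAULT_N = 10
DEFAULT_M = 5
DEFAULT_K = 1.0
DEFAULT_DELTA = 0.01
DEFAULT_EPS = 1e-7


def _sparse_uniform(rng: np.random.Generator, shape, p: float, lo: float, hi: float) -> np.ndarray:
    vals = rng.uniform(lo, hi, size=shape)
    if p < 1.0:
        mask = rng.random(size=shape) < p
        vals = np.where(mask, vals, 0.0)
    return vals


def sample_mediator_params(
    rng: np.random.Generator,
    n: int = DEFAULT_N,
    m: int = DEFAULT_M,
) -> MediatorParams:
    """Draw one random parameter set.

    Each matrix entry is independently nonzero with the configured
    probability, and nonzero entries are uniform on the configured range
    (growth rates and half-saturations are always nonzero).
    """
    p_r, lo_r, hi_r = PARAM_DISTRIBUTIONS["r"]
    p_k, lo_k, hi_k = PARAM_DISTRIBUTIONS["kappa"]
    p_rp, lo_rp, hi_rp = PARAM_DISTRIBUTIONS["rho_plus"]
    p_rm, lo_rm, hi_rm = PARAM_DISTRIBUTIONS["rho_minus"]
    p_a, lo_a, hi_a = PARAM_DISTRIBUTIONS["alpha"]
    p_b, lo_b, hi_b = PARAM_DISTRIBUTIONS["beta"]
    return MediatorParams(
        n=n,
        m=m,
        r=_sparse_uniform(rng, (n,), p_r, lo_r, hi_r),
        K=DEFAULT_K,
        delta=DEFAULT_DELTA,
        kappa=_sparse_uniform(rng, (n, m), p_k, lo_k, hi_k),
        rho_plus=_sparse_uniform(rng, (n, m), p_rp, lo_rp, hi_rp),
        rho_minus=_sparse_uniform(rng, (n, m), p_rm, lo_rm, hi_rm),
        alpha=_sparse_uniform(rng, (m, n), p_a, lo_a, hi_a),
        beta=_sparse_uniform(rng, (m, n), p_b, lo_b, hi_b),
    )


def derive_direct_matrix(p: MediatorParams) -> DirectParams:
    """Collapse chemical mediation into a pairwise interaction matrix.

    The instantaneous effect of species ``j`` on species ``i`` is
    ``A = (rho_plus - rho_minus) @ beta``; growth, capacity and dilution
    are copied unchanged.
    """
    A = (p.rho_plus - p.rho_minus) @ p.beta
    return DirectParams(A=A, r=p.r.copy(), K=p.K, delta=p.delta)


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------


def _logistic(model_id: str, r: np.ndarray, x: np.ndarray, K: float) -> np.ndarray:
    n = x.shape[-1]
    if model_id in ("M", "D"):
        return r * (1.0 - x / K) * x
    # shared term: growth limited by the community total
    return r * (1.0 - x.sum(axis=-1, keepdims=x.ndim > 1) / (n * K)) * x


def drift(model_id: str, params, state: SystemState):
    """Deterministic time derivative ``(dx/dt, dc/dt)`` of the chosen model.

    ``dc/dt`` is ``None`` for the direct models.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    x = np.asarray(state.x, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative species abundance in state")
    if model_id in MEDIATOR_MODELS:
        if not isinstance(params, MediatorParams):
            raise TypeError("mediator models require MediatorParams")
        c = np.asarray(state.c, dtype=float)
        if np.any(c < 0):
            raise ValueError("negative chemical amount in state")
        h = c[None, :] / (c[None, :] + params.kappa)  # (n, m) saturation
        chem = ((params.rho_plus - params.rho_minus) * h).sum(axis=1)
        dx = _logistic(model_id, params.r, x, params.K) + chem * x - params.delta * x
        production = params.beta @ x
        consumption = (params.alpha * x[None, :] * h.T).sum(axis=1)
        dc = production - consumption - params.delta * c
        return dx, dc
    if not isinstance(params, DirectParams):
        raise TypeError("direct models require DirectParams")
    dx = (
        _logistic(model_id, params.r, x, params.K)
        + (params.A @ x) * x
        - params.delta * x
    )
    return dx, None


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def _noise_scale(noise_form: str, sigma: float, dt: float, value: np.ndarray) -> np.ndarray:
    if noise_form == "additive_sqrt_dt":
        return sigma * np.sqrt(dt)
    if noise_form == "additive_dt":
        return sigma * dt
    # multiplicative
    return sigma * value * np.sqrt(dt)


def integrate(
    model_id: str,
    params,
    x0: np.ndarray,
    config: SimConfig,
    c0: Optional[np.ndarray] = None,
) -> Trajectory:
    """Euler--Maruyama integration for ``t_max`` steps.

    Each step applies drift, additive Gaussian noise scaled per
    ``config.noise_form``, and a constant influx ``eps`` to the species;
    the state is floored at zero afterwards.  Chemicals receive the same
    noise (without influx) when ``noise_on_chemicals`` is set.  Fully
    reproducible from ``config.seed``.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    mediator = model_id in MEDIATOR_MODELS
    x = np.array(x0, dtype=float)
    n = x.shape[0]
    if mediator:
        c = np.zeros(params.m) if c0 is None else np.array(c0, dtype=float)
    else:
        c = None
    rng = np.random.default_rng(config.seed)
    dt, sigma, eps = config.dt, config.sigma, config.eps

    xs = np.empty((config.t_max + 1, n))
    xs[0] = x
    cs = np.empty((config.t_max + 1, params.m)) if mediator else None
    if mediator:
        cs[0] = c

    state = SystemState(x=x, c=c)
    with np.errstate(over="ignore", invalid="ignore"):
        for t in range(config.t_max):
            state.x, state.c = x, c
            dx, dc = drift(model_id, params, state)
            noise_x = rng.standard_normal(n) if sigma > 0 else 0.0
            x_new = (
                x + dx * dt + _noise_scale(config.noise_form, sigma, dt, x) * noise_x + eps
            )
            if mediator:
                if sigma > 0 and config.noise_on_chemicals:
                    noise_c = rng.standard_normal(params.m)
                    c_new = (
                        c + dc * dt
                        + _noise_scale(config.noise_form, sigma, dt, c) * noise_c
                    )
                else:
                    c_new = c + dc * dt
                c = np.maximum(c_new, 0.0)
            x = np.maximum(x_new, 0.0)
            if not np.all(np.isfinite(x)) or (mediator and not np.all(np.isfinite(c))):
                bad_x = np.flatnonzero(~np.isfinite(x))
                which = (
                    f"species {bad_x.tolist()}"
                    if bad_x.size
                    else f"chemicals {np.flatnonzero(~np.isfinite(c)).tolist()}"
                )
                raise IntegrationError(
                    f"non-finite state at step {t + 1} ({which}) in model {model_id}"
                )
            xs[t + 1] = x
            if mediator:
                cs[t + 1] = c

    return Trajectory(
        times=np.arange(config.t_max + 1),
        x=xs,
        c=cs,
        model_id=model_id,
        params=params,
        config=config,
    )


def resample_tail(traj: Trajectory, tau: int, n_points: int = 100) -> SampledSeries:
    """Pick ``n_points`` evenly spaced steps from the end of a trajectory.

    The selected source steps are ``t_max - (n_points - 1 - k) * tau`` for
    ``k = 0 .. n_points - 1``; the final trajectory step is always
    included.  Only species abundances are returned.
    """
    t_last = traj.x.shape[0] - 1
    if (n_points - 1) * tau > t_last:
        raise ValueError(
            f"trajectory too short: need {(n_points - 1) * tau + 1} steps, have {t_last + 1}"
        )
    steps = t_last - (n_points - 1 - np.arange(n_points)) * tau
    return SampledSeries(
        values=traj.x[steps], tau=tau, source_steps=steps, dt=traj.config.dt
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    n = traj.x.shape[1]
    m = traj.c.shape[1] if traj.c is not None else 0
    header = ["step"] + [f"x_{i + 1}" for i in range(n)] + [f"c_{k + 1}" for k in range(m)]
    cols = [traj.times[:, None], traj.x] + ([traj.c] if m else [])
    data = np.hstack(cols)
    np.savetxt(path, data, delimiter="\t", header="\t".join(header), comments="")


def read_trajectory_tsv(path):
    """Read back a trajectory TSV as ``(steps, x, c_or_None)`` arrays."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    n = sum(1 for h in header if h.startswith("x_"))
    m = sum(1 for h in header if h.startswith("c_"))
    steps = data[:, 0].astype(int)
    x = data[:, 1 : 1 + n]
    c = data[:, 1 + n : 1 + n + m] if m else None
    return steps, x, c


def write_series_tsv(series: SampledSeries, path) -> None:
    header = ["step"] + [f"x_{i + 1}" for i in range(series.n_species)]
    data = np.hstack([series.source_steps[:, None].astype(float), series.values])
    np.savetxt(path, data, delimiter="\t", header="\t".join(header), comments="")


def read_series_tsv(path, tau: Optional[int] = None, dt: float = 0.025) -> SampledSeries:
    with open(path) as fh:
        fh.readline()
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    steps = data[:, 0].astype(int)
    inferred_tau = int(steps[1] - steps[0]) if len(steps) > 1 else (tau or 1)
    return SampledSeries(
        values=data[:, 1:], tau=tau if tau is not None else inferred_tau,
        source_steps=steps, dt=dt,
    )


def save_params_json(params, path, seed: Optional[int] = None) -> None:
    d = params.to_dict()
    d["kind"] = "mediator" if isinstance(params, MediatorParams) else "direct"
    if seed is not None:
        d["seed"] = seed
    Path(path).write_text(json.dumps(d, indent=1))


def load_params_json(path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("kind")
    d.pop("seed", None)
    if kind == "mediator":
        return MediatorParams.from_dict(d)
    return DirectParams.from_dict(d)
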