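"""Evolutionary search for diverse, coexisting communities.

Random parameter sets rarely sustain several species at once, so the
benchmark datasets are built from parameter-set / initial-state pairs
selected by a small evolutionary loop: candidates are simulated, scored
by a coexistence-and-connectance objective, the best few are kept as
parents and the rest of the population is refilled with mutants.  A pair
is accepted when its final score exceeds the threshold ``omega``.

The per-generation simulations are vectorized across the whole
population (one fused Euler--Maruyama sweep per generation), which keeps
a full search tractable on a single CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import mediator_sim as msim
from .ground_truth import EffectiveMatrix, direct_truth, structural_presence
from .mediator_sim import (
    DIRECT_MODELS,
    MEDIATOR_MODELS,
    MODEL_IDS,
    MediatorParams,
    SampledSeries,
    SimConfig,
    Trajectory,
    derive_direct_matrix,
    integrate,
    resample_tail,
    sample_mediator_params,
)

__all__ = [
    "MUTABLE_MATRICES",
    "Candidate",
    "ScoreBreakdown",
    "SearchConfig",
    "ConditionGrid",
    "DatasetEntry",
    "BenchmarkDataset",
    "EvolveResult",
    "SearchRejected",
    "score",
    "score_from_xhat",
    "mutate",
    "mutate_single",
    "evolve",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "candidate_truth",
]

#: matrices of theta eligible for swap mutations (sigma is never mutated)
MUTABLE_MATRICES = ("kappa", "rho_plus", "rho_minus", "alpha", "beta")


class SearchRejected(RuntimeError):
    """Raised when repeated searches fail to produce an accepted candidate."""


@dataclass
class Candidate:
    """One parameter-set / initial-state pair under selection.

    ``params`` always holds mediator-style matrices; for the direct
    models the interaction matrix is derived from them at scoring time so
    the two model families stay statistically comparable.  ``sigma`` is
    carried with theta but never mutated.
    """

    params: MediatorParams
    x0: np.ndarray
    sigma: float

    def copy(self) -> "Candidate":
        return Candidate(params=self.params.copy(), x0=self.x0.copy(), sigma=self.sigma)


@dataclass
class ScoreBreakdown:
    """Decomposition of the community evaluation function."""

    z: float
    s_star: int
    diversity: float
    connectance: float
    links: int
    x_hat: np.ndarray
    eta: float


@dataclass
class SearchConfig:
    """Settings of the evolutionary loop and dataset assembly."""

    Mp: int = 32  # population size
    mp: int = 4  # parents kept per generation
    Tmax: int = 60  # generations (120 for the shared-logistic models)
    omega: float = 5.0  # acceptance threshold on the score
    N: int = 288  # accepted communities per dataset
    eta: float = 1e-2  # major-species abundance threshold
    perturb_low: float = 0.8
    perturb_high: float = 1.2
    diversity_form: str = "sqrt"  # or "inv_simpson"
    perturb_x0: bool = True
    rescore_parents: bool = True
    max_restarts: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.mp < self.Mp):
            raise ValueError("must have 0 < mp < Mp")
        if self.Tmax <= 0 or self.N <= 0 or self.eta <= 0:
            raise ValueError("Tmax, N and eta must be positive")
        if self.diversity_form not in ("sqrt", "inv_simpson"):
            raise ValueError("diversity_form must be 'sqrt' or 'inv_simpson'")


def default_tmax(model_id: str) -> int:
    """Generation budget: doubled for the shared-logistic variants."""
    return 120 if model_id in ("Mprime", "Dprime") else 60


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _diversity(p: np.ndarray, form: str) -> float:
    if form == "sqrt":
        return float(np.sqrt(p).sum())
    return float(1.0 / np.square(p).sum())


def score_from_xhat(
    x_hat: np.ndarray,
    truth_presence: np.ndarray,
    eta: float = 1e-2,
    diversity_form: str = "sqrt",
) -> ScoreBreakdown:
    """Community score ``z = S* . D . (4c - 4c^2)`` from mean abundances.

    ``S*`` counts major species (mean abundance above ``eta``); the
    diversity ``D`` and connectance ``c`` are computed on the major
    species only, with ``c = L / (S* (S* - 1))`` from the off-diagonal
    presence pattern restricted to the major-species submatrix.
    """
    x_hat = np.asarray(x_hat, dtype=float)
    major = np.flatnonzero(np.nan_to_num(x_hat, nan=0.0) > eta)
    s_star = int(major.size)
    if s_star <= 1:
        return ScoreBreakdown(
            z=0.0, s_star=s_star, diversity=float(s_star), connectance=0.0,
            links=0, x_hat=x_hat, eta=eta,
        )
    xm = x_hat[major]
    p = xm / xm.sum()
    diversity = _diversity(p, diversity_form)
    sub = np.asarray(truth_presence, dtype=bool)[np.ix_(major, major)]
    links = int(sub.sum()) - int(np.diag(sub).sum())
    connectance = links / (s_star * (s_star - 1))
    z = s_star * diversity * (4.0 * connectance - 4.0 * connectance**2)
    return ScoreBreakdown(
        z=float(z), s_star=s_star, diversity=diversity, connectance=connectance,
        links=links, x_hat=x_hat, eta=eta,
    )


def score(
    traj: Trajectory,
    truth_presence: np.ndarray,
    eta: float = 1e-2,
    diversity_form: str = "sqrt",
) -> ScoreBreakdown:
    """Score a trajectory by its post-transient time-averaged abundances."""
    return score_from_xhat(
        traj.post_transient_mean(), truth_presence, eta=eta,
        diversity_form=diversity_form,
    )


def candidate_truth(model_id: str, params: MediatorParams) -> EffectiveMatrix:
    """Ground-truth network used for scoring and evaluation of a candidate."""
    if model_id in MEDIATOR_MODELS:
        presence = structural_presence(params)
        return EffectiveMatrix(
            values=presence.astype(float), presence=presence, model_id=model_id
        )
    return direct_truth(derive_direct_matrix(params), model_id=model_id)


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------


def mutate_single(
    params: MediatorParams,
    rng: np.random.Generator,
    matrix: Optional[str] = None,
) -> MediatorParams:
    """One swap mutation: pick a matrix with a nonzero entry (uniformly,
    unless ``matrix`` names one), a uniformly random nonzero entry of it
    and a uniformly random other position, and exchange the two values."""
    out = params.copy()
    if matrix is None:
        eligible = [
            name for name in MUTABLE_MATRICES if np.any(getattr(out, name) != 0)
        ]
        if not eligible:
            raise ValueError("cannot mutate: all matrices are zero")
        matrix = eligible[int(rng.integers(len(eligible)))]
    flat = getattr(out, matrix).ravel()
    nonzero = np.flatnonzero(flat)
    if nonzero.size == 0:
        raise ValueError(f"cannot mutate: matrix {matrix} is all-zero")
    i1 = int(nonzero[int(rng.integers(nonzero.size))])
    i2 = int(rng.integers(flat.size - 1))
    if i2 >= i1:
        i2 += 1
    flat[i1], flat[i2] = flat[i2], flat[i1]
    return out


def mutate(params: MediatorParams, rng: np.random.Generator) -> MediatorParams:
    """Swap-mutate theta: 1--4 swaps (uniform count), each within one
    matrix; the multiset of values of every matrix is invariant."""
    out = params
    n_swaps = int(rng.integers(1, 5))
    for _ in range(n_swaps):
        out = mutate_single(out, rng)
    return out


# ---------------------------------------------------------------------------
# vectorized population simulation
# ---------------------------------------------------------------------------


def _stack_params(cands: Sequence[Candidate]):
    ps = [c.params for c in cands]
    return {
        "r": np.stack([p.r for p in ps]),
        "kappa": np.stack([p.kappa for p in ps]),
        "rho": np.stack([p.rho_plus - p.rho_minus for p in ps]),
        "alpha": np.stack([p.alpha for p in ps]),
        "beta": np.stack([p.beta for p in ps]),
        "K": ps[0].K,
        "delta": ps[0].delta,
    }


def _simulate_population(
    model_id: str,
    cands: Sequence[Candidate],
    x0: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Integrate all candidates at once; return post-transient means and an
    all-finite mask.  Same update rule as :func:`medibench.mediator_sim.integrate`
    but with one shared noise stream for the whole population."""
    P = len(cands)
    n = x0.shape[1]
    mediator = model_id in MEDIATOR_MODELS
    shared = model_id in ("Mprime", "Dprime")
    sp = _stack_params(cands)
    K, delta = sp["K"], sp["delta"]
    r = sp["r"]
    if mediator:
        kappa, rho, alpha, beta = sp["kappa"], sp["rho"], sp["alpha"], sp["beta"]
        m = kappa.shape[2]
        c = np.zeros((P, m))
    else:
        A = np.stack([derive_direct_matrix(cand.params).A for cand in cands])
        c = None

    dt, sigma, eps = cfg.dt, cfg.sigma, cfg.eps
    sqdt = np.sqrt(dt)
    x = x0.copy()
    x_sum = np.zeros_like(x)
    n_avg = cfg.t_max - cfg.t0

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for t in range(cfg.t_max):
            if shared:
                logistic = r * (1.0 - x.sum(axis=1, keepdims=True) / (n * K)) * x
            else:
                logistic = r * (1.0 - x / K) * x
            if mediator:
                h = c[:, None, :] / (c[:, None, :] + kappa)  # (P, n, m)
                chem = (rho * h).sum(axis=2)
                dx = logistic + chem * x - delta * x
                production = np.einsum("pmn,pn->pm", beta, x)
                consumption = np.einsum(
                    "pmn,pn,pnm->pm", alpha, x, h
                )
                dc = production - consumption - delta * c
            else:
                dx = logistic + np.einsum("pij,pj->pi", A, x) * x - delta * x

            if sigma > 0:
                noise_x = rng.standard_normal((P, n))
                if cfg.noise_form == "additive_sqrt_dt":
                    nx = sigma * sqdt * noise_x
                elif cfg.noise_form == "additive_dt":
                    nx = sigma * dt * noise_x
                else:
                    nx = sigma * x * sqdt * noise_x
            else:
                nx = 0.0
            x = np.maximum(x + dx * dt + nx + eps, 0.0)
            if mediator:
                if sigma > 0 and cfg.noise_on_chemicals:
                    noise_c = rng.standard_normal((P, m))
                    if cfg.noise_form == "additive_sqrt_dt":
                        nc = sigma * sqdt * noise_c
                    elif cfg.noise_form == "additive_dt":
                        nc = sigma * dt * noise_c
                    else:
                        nc = sigma * c * sqdt * noise_c
                    c = np.maximum(c + dc * dt + nc, 0.0)
                else:
                    c = np.maximum(c + dc * dt, 0.0)
            if t >= cfg.t0:
                x_sum += x

    x_hat = x_sum / n_avg
    ok = np.all(np.isfinite(x_hat), axis=1)
    if mediator:
        ok &= np.all(np.isfinite(c), axis=1)
    return x_hat, ok


# ---------------------------------------------------------------------------
# evolutionary loop
# ---------------------------------------------------------------------------


@dataclass
class EvolveResult:
    candidate: Candidate
    trajectory: Trajectory
    breakdown: ScoreBreakdown
    x0_perturbed: np.ndarray
    seed: int
    generations: int


def _init_candidates(
    n_cands: int, rng: np.random.Generator, sigma: float, eps: float,
    n: int = msim.DEFAULT_N, m: int = msim.DEFAULT_M,
) -> List[Candidate]:
    out = []
    for _ in range(n_cands):
        params = sample_mediator_params(rng, n=n, m=m)
        x0 = rng.uniform(10 * eps, 100 * eps, size=n)
        out.append(Candidate(params=params, x0=x0, sigma=sigma))
    return out


def evolve(
    model_id: str,
    search_cfg: SearchConfig,
    sim_cfg: SimConfig,
    rng: np.random.Generator,
) -> Optional[EvolveResult]:
    """Run one evolutionary search; return the accepted pair or ``None``.

    Each generation perturbs every candidate's initial microbe abundances
    by independent uniform factors, simulates the whole population,
    scores it and keeps the top ``mp`` candidates as parents; the rest of
    the next population are single-parent mutants.  After ``Tmax``
    generations the best candidate of the final generation is re-run
    through the reference integrator (same perturbed initial state, fresh
    noise seed drawn from ``rng``) and accepted iff its score exceeds
    ``omega``.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    cfg = search_cfg
    sim = sim_cfg
    cands = _init_candidates(cfg.Mp, rng, sigma=sim.sigma, eps=max(sim.eps, 1e-12))
    scores = np.full(cfg.Mp, -np.inf)
    breakdowns: List[Optional[ScoreBreakdown]] = [None] * cfg.Mp
    x0_used = np.stack([c.x0 for c in cands])

    best_final = None
    for gen in range(cfg.Tmax):
        if cfg.rescore_parents or gen == 0:
            todo = np.arange(len(cands))
        else:
            todo = np.arange(cfg.mp, len(cands))
        sub = [cands[i] for i in todo]
        x0 = np.stack([c.x0 for c in sub])
        if cfg.perturb_x0:
            x0 = x0 * rng.uniform(cfg.perturb_low, cfg.perturb_high, size=x0.shape)
        x_hat, ok = _simulate_population(model_id, sub, x0, sim, rng)
        for pos, i in enumerate(todo):
            if not ok[pos]:
                breakdowns[i] = None
                scores[i] = 0.0
                continue
            truth = candidate_truth(model_id, cands[i].params)
            bd = score_from_xhat(
                x_hat[pos], truth.presence, eta=cfg.eta,
                diversity_form=cfg.diversity_form,
            )
            breakdowns[i] = bd
            scores[i] = bd.z
            x0_used[i] = x0[pos]

        order = np.argsort(-scores, kind="stable")
        if gen == cfg.Tmax - 1:
            best = int(order[0])
            best_final = (cands[best].copy(), x0_used[best].copy())
            break
        parents = [cands[i] for i in order[: cfg.mp]]
        parent_scores = scores[order[: cfg.mp]].copy()
        parent_bds = [breakdowns[i] for i in order[: cfg.mp]]
        parent_x0 = x0_used[order[: cfg.mp]].copy()
        children = []
        for _ in range(cfg.Mp - cfg.mp):
            parent = parents[int(rng.integers(cfg.mp))]
            children.append(
                Candidate(
                    params=mutate(parent.params, rng),
                    x0=parent.x0.copy(),
                    sigma=parent.sigma,
                )
            )
        cands = [c.copy() for c in parents] + children
        scores = np.concatenate([parent_scores, np.full(len(children), -np.inf)])
        breakdowns = parent_bds + [None] * len(children)
        x0_used = np.concatenate([parent_x0, np.stack([c.x0 for c in children])])

    cand, x0p = best_final
    seed = int(rng.integers(2**31 - 1))
    final_sim = SimConfig(**{**sim.to_dict(), "seed": seed})
    params = (
        cand.params if model_id in MEDIATOR_MODELS else derive_direct_matrix(cand.params)
    )
    try:
        traj = integrate(model_id, params, x0p, final_sim)
    except msim.IntegrationError:
        return None
    truth = candidate_truth(model_id, cand.params)
    bd = score(traj, truth.presence, eta=cfg.eta, diversity_form=cfg.diversity_form)
    if bd.z > cfg.omega:
        return EvolveResult(
            candidate=cand, trajectory=traj, breakdown=bd,
            x0_perturbed=x0p, seed=seed, generations=cfg.Tmax,
        )
    return None


def evolve_until_accepted(
    model_id: str,
    search_cfg: SearchConfig,
    sim_cfg: SimConfig,
    rng: np.random.Generator,
) -> EvolveResult:
    """Repeat :func:`evolve` with fresh initializations until acceptance."""
    for _ in range(search_cfg.max_restarts + 1):
        res = evolve(model_id, search_cfg, sim_cfg, rng)
        if res is not None:
            return res
    raise SearchRejected(
        f"no accepted candidate for model {model_id} after "
        f"{search_cfg.max_restarts + 1} searches"
    )


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class ConditionGrid:
    """The benchmark's sampling-interval and noise-magnitude sweeps."""

    taus: Tuple[int, ...] = (10, 20, 40, 80)
    sigmas: Tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    tau_ref: int = 40
    sigma_ref: float = 1.0


@dataclass
class DatasetEntry:
    series: SampledSeries
    truth: EffectiveMatrix
    candidate: Candidate
    seed: int


@dataclass
class BenchmarkDataset:
    model_id: str
    tau: int
    sigma: float
    entries: List[DatasetEntry] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(self.entries)


def generate_dataset(
    model_id: str,
    condition_grid: ConditionGrid,
    N: int,
    rng: np.random.Generator,
    search_cfg: Optional[SearchConfig] = None,
    sim_cfg: Optional[SimConfig] = None,
    n_points: int = 100,
) -> List[BenchmarkDataset]:
    """Assemble the full per-model benchmark: the tau sweep at the
    reference noise level plus the sigma sweep at the reference interval.

    Communities are searched once per distinct noise magnitude; the tau
    sweep resamples the reference-noise trajectories at each interval.
    The default grid yields eight datasets (the reference condition
    appears in both sweeps, backed by the same communities).
    """
    grid = condition_grid
    search_cfg = search_cfg or SearchConfig(Tmax=default_tmax(model_id), N=N)
    base_sim = sim_cfg or SimConfig()

    sigma_levels = [grid.sigma_ref] + [s for s in grid.sigmas if s != grid.sigma_ref]
    accepted = {}
    for sig in sigma_levels:
        sim = SimConfig(**{**base_sim.to_dict(), "sigma": sig})
        group = []
        for _ in range(N):
            res = evolve_until_accepted(model_id, search_cfg, sim, rng)
            group.append(res)
        accepted[sig] = group

    def build(group, tau, sigma):
        ds = BenchmarkDataset(model_id=model_id, tau=tau, sigma=sigma)
        for res in group:
            series = resample_tail(res.trajectory, tau, n_points=n_points)
            truth = candidate_truth(model_id, res.candidate.params)
            ds.entries.append(
                DatasetEntry(
                    series=series, truth=truth, candidate=res.candidate,
                    seed=res.seed,
                )
            )
        return ds

    datasets = [build(accepted[grid.sigma_ref], tau, grid.sigma_ref) for tau in grid.taus]
    datasets += [build(accepted[s], grid.tau_ref, s) for s in grid.sigmas]
    return datasets


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_dataset(ds: BenchmarkDataset, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "model_id": ds.model_id,
        "tau": ds.tau,
        "sigma": ds.sigma,
        "n_communities": ds.n_communities,
        "communities": [],
    }
    for k, entry in enumerate(ds.entries):
        sub = out / f"community_{k}"
        sub.mkdir(exist_ok=True)
        msim.write_series_tsv(entry.series, sub / "series.tsv")
        (sub / "truth.json").write_text(json.dumps(entry.truth.to_dict(), indent=1))
        pd = entry.candidate.params.to_dict()
        pd.update({"kind": "mediator", "sigma": entry.candidate.sigma,
                   "x0": entry.candidate.x0.tolist(), "seed": entry.seed})
        (sub / "params.json").write_text(json.dumps(pd, indent=1))
        manifest["communities"].append(f"community_{k}")
    (out / "dataset.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(in_dir) -> BenchmarkDataset:
    src = Path(in_dir)
    manifest = json.loads((src / "dataset.json").read_text())
    ds = BenchmarkDataset(
        model_id=manifest["model_id"], tau=manifest["tau"], sigma=manifest["sigma"]
    )
    for name in manifest["communities"]:
        sub = src / name
        series = msim.read_series_tsv(sub / "series.tsv", tau=manifest["tau"])
        truth = EffectiveMatrix.from_dict(json.loads((sub / "truth.json").read_text()))
        pd = json.loads((sub / "params.json").read_text())
        cand = Candidate(
            params=MediatorParams.from_dict(
                {k: pd[k] for k in
                 ("n", "m", "K", "delta", "r", "kappa", "rho_plus", "rho_minus",
                  "alpha", "beta")}
            ),
            x0=np.asarray(pd["x0"], dtype=float),
            sigma=float(pd["sigma"]),
        )
        ds.entries.append(
            DatasetEntry(series=series, truth=truth, candidate=cand,
                         seed=int(pd.get("seed", 0)))
        )
    return ds
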