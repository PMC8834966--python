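"""End-to-end orchestration: generate communities, infer, evaluate.

This thin layer wires the simulator, the community search, the inference
methods and the evaluation metrics into one reproducible run driven by a
plain dictionary config (loadable from YAML/JSON through the CLI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .community_search import (
    BenchmarkDataset,
    SearchConfig,
    default_tmax,
    evolve_until_accepted,
    candidate_truth,
)
from .evaluation import BenchmarkRecord, evaluate_result, records_to_frame
from .inference import infer
from .mediator_sim import SimConfig, resample_tail

__all__ = ["BenchmarkConfig", "generate_communities", "run_benchmark"]

DEFAULT_METHOD_KWARGS = {
    "lsa": {"n_boot": 2000},
    "ccm": {"n_surrogates": 100},
    "limits": {"n_bags": 500},
}


@dataclass
class BenchmarkConfig:
    models: Sequence[str] = ("Mprime", "Dprime")
    methods: Sequence[str] = ("pearson", "spearman", "lsa", "ccm", "limits")
    n_communities: int = 10
    tau: int = 40
    sigma: float = 1.0
    seed: int = 0
    search: Dict = field(default_factory=dict)  # SearchConfig overrides
    sim: Dict = field(default_factory=dict)  # SimConfig overrides
    method_kwargs: Dict[str, Dict] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        return cls(**d)


def generate_communities(
    model_id: str,
    n_communities: int,
    rng: np.random.Generator,
    tau: int = 40,
    sigma: float = 1.0,
    search_overrides: Optional[dict] = None,
    sim_overrides: Optional[dict] = None,
    n_points: int = 100,
) -> BenchmarkDataset:
    """Search ``n_communities`` accepted communities at one condition and
    resample each accepted trajectory into a benchmark dataset."""
    from .community_search import DatasetEntry

    search_kwargs = {"Tmax": default_tmax(model_id), "N": n_communities}
    search_kwargs.update(search_overrides or {})
    search_cfg = SearchConfig(**search_kwargs)
    sim_kwargs = {"sigma": sigma}
    sim_kwargs.update(sim_overrides or {})
    sim_cfg = SimConfig(**sim_kwargs)

    ds = BenchmarkDataset(model_id=model_id, tau=tau, sigma=sigma)
    for _ in range(n_communities):
        res = evolve_until_accepted(model_id, search_cfg, sim_cfg, rng)
        series = resample_tail(res.trajectory, tau, n_points=n_points)
        truth = candidate_truth(model_id, res.candidate.params)
        ds.entries.append(
            DatasetEntry(series=series, truth=truth, candidate=res.candidate,
                         seed=res.seed)
        )
    return ds


def evaluate_dataset(
    ds: BenchmarkDataset,
    methods: Sequence[str],
    seed: int = 0,
    method_kwargs: Optional[Dict[str, Dict]] = None,
    k: int = 5,
) -> List[BenchmarkRecord]:
    """Run every method on every community of a dataset and score it."""
    method_kwargs = method_kwargs or {}
    records: List[BenchmarkRecord] = []
    ss = np.random.SeedSequence(seed)
    for ci, entry in enumerate(ds.entries):
        dt_eff = ds.tau * entry.series.dt
        for method in methods:
            kwargs = dict(DEFAULT_METHOD_KWARGS.get(method, {}))
            kwargs.update(method_kwargs.get(method, {}))
            if method == "limits":
                kwargs.setdefault("dt_effective", dt_eff)
            child_seed = int(ss.spawn(1)[0].generate_state(1)[0])
            result = infer(entry.series, method, seed=child_seed, **kwargs)
            for classifier, auc, prec, n_pos in evaluate_result(
                entry.truth, result, entry.series, k=k
            ):
                records.append(
                    BenchmarkRecord(
                        model_id=ds.model_id, tau=ds.tau, sigma=ds.sigma,
                        community=ci, method=method, classifier=classifier,
                        auc=auc, precision_half=prec, positives=n_pos,
                    )
                )
    return records


def evaluate_results_dir(ds: BenchmarkDataset, results_dir, k: int = 5):
    """Score precomputed inference results stored as
    ``<results_dir>/community_<i>/<method>.json`` against a dataset."""
    from pathlib import Path

    from .inference import InferenceResult

    records: List[BenchmarkRecord] = []
    root = Path(results_dir)
    for ci, entry in enumerate(ds.entries):
        sub = root / f"community_{ci}"
        if not sub.is_dir():
            continue
        for path in sorted(sub.glob("*.json")):
            result = InferenceResult.load(path)
            for classifier, auc, prec, n_pos in evaluate_result(
                entry.truth, result, entry.series, k=k
            ):
                records.append(
                    BenchmarkRecord(
                        model_id=ds.model_id, tau=ds.tau, sigma=ds.sigma,
                        community=ci, method=result.method, classifier=classifier,
                        auc=auc, precision_half=prec, positives=n_pos,
                    )
                )
    return records


def run_benchmark(cfg: BenchmarkConfig) -> pd.DataFrame:
    """Full generate -> infer -> evaluate loop for every configured model."""
    records: List[BenchmarkRecord] = []
    for mi, model_id in enumerate(cfg.models):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, mi)))
        ds = generate_communities(
            model_id, cfg.n_communities, rng, tau=cfg.tau, sigma=cfg.sigma,
            search_overrides=cfg.search, sim_overrides=cfg.sim,
        )
        records.extend(
            evaluate_dataset(
                ds, cfg.methods, seed=cfg.seed + 1000 * mi,
                method_kwargs=cfg.method_kwargs,
            )
        )
    return records_to_frame(records)
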