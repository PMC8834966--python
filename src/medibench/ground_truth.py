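"""Ground-truth interaction networks.

For the direct models the truth is the interaction matrix ``A`` itself.
For the mediator models the chemical coupling is collapsed into an
effective species-by-species matrix: the product of the Jacobian block of
chemical effects on species with the block of species effects on
chemicals.  Entry ``(i, j)`` always means "effect of species j on
species i".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .mediator_sim import (
    DIRECT_MODELS,
    MEDIATOR_MODELS,
    MODEL_IDS,
    DirectParams,
    MediatorParams,
    SystemState,
)

__all__ = [
    "ZERO_TOL",
    "JacobianBlocks",
    "EffectiveMatrix",
    "jacobian_blocks",
    "effective_interaction_matrix",
    "structural_presence",
    "direct_truth",
    "save_effective_matrix",
    "load_effective_matrix",
]

#: magnitudes below this count as zero when deriving presence patterns
ZERO_TOL = 1e-12


@dataclass
class JacobianBlocks:
    """Partial derivatives of the drift, split into state blocks."""

    JF_x: np.ndarray  # (n, n) species wrt species
    JF_c: np.ndarray  # (n, m) species wrt chemicals
    JG_x: np.ndarray  # (m, n) chemicals wrt species
    JG_c: np.ndarray  # (m, m) chemicals wrt chemicals
    eval_state: SystemState


@dataclass
class EffectiveMatrix:
    """Signed interaction matrix plus its off-diagonal presence pattern."""

    values: np.ndarray
    presence: np.ndarray
    model_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.values.shape != self.presence.shape:
            raise ValueError("values/presence shape mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_dict(self) -> dict:
        return {
            "values": self.values.tolist(),
            "presence": self.presence.astype(int).tolist(),
            "model_id": self.model_id,
            "convention": "entry (i, j) is the effect of species j on species i",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectiveMatrix":
        return cls(
            values=np.asarray(d["values"], dtype=float),
            presence=np.asarray(d["presence"], dtype=bool),
            model_id=d["model_id"],
        )


def _offdiag_presence(values: np.ndarray) -> np.ndarray:
    presence = np.abs(values) > ZERO_TOL
    np.fill_diagonal(presence, False)
    return presence


def jacobian_blocks(model_id: str, params, state: SystemState) -> JacobianBlocks:
    """Analytic Jacobian of the drift at ``state``, split into blocks.

    Direct models have no chemical variables; their chemical blocks are
    returned with zero-width shape.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    x = np.asarray(state.x, dtype=float)
    n = x.shape[0]

    if model_id in MEDIATOR_MODELS:
        if not isinstance(params, MediatorParams):
            raise TypeError("mediator models require MediatorParams")
        c = np.asarray(state.c, dtype=float)
        m = params.m
        rho = params.rho_plus - params.rho_minus  # (n, m)
        h = c[None, :] / (c[None, :] + params.kappa)  # (n, m)
        dh = params.kappa / (c[None, :] + params.kappa) ** 2  # (n, m) dh/dc

        chem = (rho * h).sum(axis=1)
        if model_id == "M":
            JF_x = np.diag(params.r * (1.0 - 2.0 * x / params.K) + chem - params.delta)
        else:
            total = x.sum()
            JF_x = np.diag(
                params.r * (1.0 - total / (n * params.K)) + chem - params.delta
            ) - np.outer(params.r * x, np.ones(n)) / (n * params.K)
        JF_c = rho * dh * x[:, None]
        JG_x = params.beta - params.alpha * h.T
        # dG_k/dc_l is diagonal: chemicals interact only through shared species
        JG_c = np.diag(-(params.alpha * x[None, :] * dh.T).sum(axis=1) - params.delta)
        return JacobianBlocks(JF_x=JF_x, JF_c=JF_c, JG_x=JG_x, JG_c=JG_c,
                              eval_state=state)

    if not isinstance(params, DirectParams):
        raise TypeError("direct models require DirectParams")
    inter = params.A @ x
    if model_id == "D":
        diag = params.r * (1.0 - 2.0 * x / params.K) + inter - params.delta
        JF_x = np.diag(diag) + params.A * x[:, None]
    else:
        total = x.sum()
        diag = params.r * (1.0 - total / (n * params.K)) + inter - params.delta
        JF_x = (
            np.diag(diag)
            + params.A * x[:, None]
            - np.outer(params.r * x, np.ones(n)) / (n * params.K)
        )
    empty_nm = np.zeros((n, 0))
    return JacobianBlocks(
        JF_x=JF_x, JF_c=empty_nm, JG_x=empty_nm.T, JG_c=np.zeros((0, 0)),
        eval_state=state,
    )


def effective_interaction_matrix(
    params: MediatorParams, state: SystemState, model_id: str = "M"
) -> EffectiveMatrix:
    """Effective species-by-species matrix ``JF_c @ JG_x`` at ``state``."""
    if not isinstance(params, MediatorParams):
        raise TypeError(
            "effective_interaction_matrix requires MediatorParams; "
            "use direct_truth for the direct models"
        )
    if model_id not in MEDIATOR_MODELS:
        raise ValueError("model_id must be a mediator model (M or Mprime)")
    blocks = jacobian_blocks(model_id, params, state)
    values = blocks.JF_c @ blocks.JG_x
    return EffectiveMatrix(
        values=values, presence=_offdiag_presence(values), model_id=model_id
    )


def structural_presence(params: MediatorParams) -> np.ndarray:
    """State-free directed presence pattern of chemical-mediated effects.

    ``presence[i, j]`` is true iff some chemical both affects species
    ``i`` (through a nonzero positive or negative effect) and is produced
    or consumed by species ``j``.  Diagonal entries are always false.
    """
    if not isinstance(params, MediatorParams):
        raise TypeError("structural_presence requires MediatorParams")
    senses = (params.rho_plus != 0) | (params.rho_minus != 0)  # (n, m)
    emits = (params.beta != 0) | (params.alpha != 0)  # (m, n)
    presence = senses.astype(int) @ emits.astype(int) > 0
    np.fill_diagonal(presence, False)
    return presence


def direct_truth(dparams: DirectParams, model_id: str = "D") -> EffectiveMatrix:
    """Truth network of a direct model: ``A`` and its off-diagonal pattern."""
    if not isinstance(dparams, DirectParams):
        raise TypeError("direct_truth requires DirectParams")
    if model_id not in DIRECT_MODELS:
        raise ValueError("model_id must be a direct model (D or Dprime)")
    return EffectiveMatrix(
        values=dparams.A.copy(),
        presence=_offdiag_presence(dparams.A),
        model_id=model_id,
    )


def save_effective_matrix(em: EffectiveMatrix, path) -> None:
    Path(path).write_text(json.dumps(em.to_dict(), indent=1))


def load_effective_matrix(path) -> EffectiveMatrix:
    return EffectiveMatrix.from_dict(json.loads(Path(path).read_text()))
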