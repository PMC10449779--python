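"""Linear dynamical network models of the intervention experiment.

The state ``x(k)`` is the vector of questionnaire responses and evolves as

    x(k+1) = A x(k) + B u(k)

where ``A`` couples the items and ``B`` maps the intervention input onto the
items.  Two model families are supported:

- *self-constructed*: ``A`` is the participant-drawn perceived causal network
  (convention ``A[target, source]``), ``B`` the identity; scenario ``s`` is an
  input of magnitude ±1 (the intended direction) at entry ``s``.
- *dmdc*: ``A`` and ``B`` jointly estimated by Dynamic Mode Decomposition with
  Control from snapshot pairs, ``[A B] = X2 [X1; U]^+`` (Moore-Penrose
  pseudoinverse); scenario inputs have magnitude +1 during fitting.

With the study design every "before" snapshot is the common baseline, so
``X1`` has rank one and the fit is under-determined; the pseudoinverse then
returns the minimum-Frobenius-norm model, which still reproduces the training
snapshots exactly whenever the stacked linear system is consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .study_data import StudyData

SELF_CONSTRUCTED = "self_constructed"
DMDC = "dmdc"

#: Relative singular-value cutoff for the DMDc pseudoinverse.
DEFAULT_RCOND = 1e-10


class ModelError(ValueError):
    """Missing inputs or contract violations while building a model."""


@dataclass
class DynamicalModel:
    """A fitted or constructed linear model ``x(k+1) = A x(k) + B u(k)``."""

    A: np.ndarray
    B: np.ndarray
    provenance: str
    stabilization: Optional[dict] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.B.shape != (n, n):
            raise ModelError(f"A and B must be square and equal-sized, got {self.A.shape}, {self.B.shape}")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise ModelError("A and B must be finite")

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass
class SnapshotSet:
    """Paired before/after states with the inputs applied between them."""

    X1: np.ndarray  # (n, m) before states
    X2: np.ndarray  # (n, m) after states
    U: np.ndarray  # (n, m) inputs

    def __post_init__(self) -> None:
        self.X1 = np.asarray(self.X1, dtype=float)
        self.X2 = np.asarray(self.X2, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if not (self.X1.shape == self.X2.shape == self.U.shape):
            raise ModelError("X1, X2, U must share a shape")
        if self.X1.shape[1] < 1:
            raise ModelError("need at least one snapshot column")

    @property
    def m(self) -> int:
        return self.X1.shape[1]


def input_vector(n: int, active_index: int, magnitude: float = 1.0) -> np.ndarray:
    """Canonical intervention input: all zeros except ``magnitude`` at the target."""
    if not 0 <= active_index < n:
        raise ModelError(f"active_index {active_index} out of range for {n} items")
    u = np.zeros(n)
    u[active_index] = magnitude
    return u


def build_self_constructed(study: StudyData, participant: str) -> DynamicalModel:
    """Model from the participant's drawn network; B is the identity pattern.

    Raises :class:`ModelError` if the participant drew no network — callers
    must handle absence explicitly rather than fall back silently.
    """
    net = study.drawn_network(participant)
    if net is None:
        raise ModelError(f"participant {participant!r} has no drawn network")
    n = study.n_items
    return DynamicalModel(
        A=np.array(net, dtype=float),
        B=np.eye(n),
        provenance=SELF_CONSTRUCTED,
        metadata={"participant": participant},
    )


def assemble_snapshots(study: StudyData, participant: str) -> SnapshotSet:
    """Study-design snapshots for one participant.

    Every X1 column is the common baseline; X2 column ``s`` is the response
    vector after scenario ``s``; U column ``s`` is the unit input at ``s``.
    """
    i = study.participant_index(participant)
    n = study.n_items
    x0 = study.baseline[i].astype(float)
    X1 = np.tile(x0[:, None], (1, n))
    X2 = study.post[i].T.astype(float)  # column s = post[i, s, :]
    U = np.eye(n)
    return SnapshotSet(X1=X1, X2=X2, U=U)


def dmdc_fit(snapshots: SnapshotSet, rcond: float = DEFAULT_RCOND) -> DynamicalModel:
    """Joint least-squares fit ``[A B] = X2 [X1; U]^+``.

    The pseudoinverse is computed by SVD with relative cutoff ``rcond``; when
    the stacked regressor is rank deficient the result is the
    minimum-Frobenius-norm solution among all least-squares minimizers.
    """
    if not (
        np.all(np.isfinite(snapshots.X1))
        and np.all(np.isfinite(snapshots.X2))
        and np.all(np.isfinite(snapshots.U))
    ):
        raise ModelError("snapshots must be finite")
    n = snapshots.X1.shape[0]
    Z = np.vstack([snapshots.X1, snapshots.U])
    AB = snapshots.X2 @ np.linalg.pinv(Z, rcond=rcond)
    return DynamicalModel(
        A=AB[:, :n],
        B=AB[:, n:],
        provenance=DMDC,
        metadata={"rcond": rcond, "m": snapshots.m},
    )


def predict_post(model: DynamicalModel, baseline: np.ndarray, u: np.ndarray) -> np.ndarray:
    """One-step prediction ``A @ baseline + B @ u``; real-valued, not re-gridded."""
    baseline = np.asarray(baseline, dtype=float)
    u = np.asarray(u, dtype=float)
    if baseline.shape != (model.n,) or u.shape != (model.n,):
        raise ModelError(f"state/input must have shape ({model.n},)")
    return model.A @ baseline + model.B @ u


def cohort_models(
    study: StudyData, provenance: str, rcond: float = DEFAULT_RCOND
) -> tuple[dict[str, DynamicalModel], list[str]]:
    """Build one model per participant; returns (models, skipped participants)."""
    models: dict[str, DynamicalModel] = {}
    skipped: list[str] = []
    for pid in study.participants:
        if provenance == SELF_CONSTRUCTED:
            try:
                models[pid] = build_self_constructed(study, pid)
            except ModelError:
                skipped.append(pid)
        elif provenance == DMDC:
            models[pid] = dmdc_fit(assemble_snapshots(study, pid), rcond=rcond)
        else:
            raise ModelError(f"unknown provenance {provenance!r}")
    return models, skipped


def predict_cohort(
    study: StudyData,
    provenance: str,
    rcond: float = DEFAULT_RCOND,
    models: Optional[dict[str, DynamicalModel]] = None,
) -> tuple[np.ndarray, list[str]]:
    """One-step predictions for all scenarios of every participant.

    Returns ``(predictions, skipped)`` where predictions is ``(P, n, n)``
    (NaN rows for skipped participants).  Input magnitude follows the family
    convention: the intended direction ±1 for self-constructed models, +1 for
    dmdc models (matching how they were fitted).
    """
    P, n = study.n_participants, study.n_items
    if models is None:
        models, skipped = cohort_models(study, provenance, rcond=rcond)
    else:
        skipped = [p for p in study.participants if p not in models]
    pred = np.full((P, n, n), np.nan)
    for i, pid in enumerate(study.participants):
        model = models.get(pid)
        if model is None:
            continue
        x0 = study.baseline[i].astype(float)
        for s in range(n):
            mag = float(study.direction[i, s]) if provenance == SELF_CONSTRUCTED else 1.0
            pred[i, s] = predict_post(model, x0, input_vector(n, s, mag))
    return pred, skipped
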