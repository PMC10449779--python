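"""Network controllability and minimum control energy for discrete-time LTI models.

Average controllability of node ``j`` is the trace of the infinite-horizon
controllability Gramian driven through the canonical input ``e_j``:

    AC_j = trace( sum_{i>=0} A^i e_j e_j^T (A^T)^i ) = sum_{i>=0} ||A^i e_j||^2,

obtained here from the discrete Lyapunov equation ``M = A^T M A + I`` (then
``AC_j = M[j, j]``), which requires Schur stability (spectral radius < 1).

Modal controllability of node ``j`` weights its eigenvector loadings by how
fast each mode decays:

    MC_j = sum_i (1 - |xi_i|^2) |v_ji|^2,

with unit-norm eigenvector columns; complex eigenpairs enter through their
squared moduli.

Control energy quantifies the effort of steering the state from ``x0`` to
``xT`` in ``K`` steps using a restricted set of input columns, with the
quadratic cost  sum_k [ (xT - x(k))^T (xT - x(k)) + rho * u(k)^T u(k) ].
When the terminal state is exactly reachable the terminal equality is
enforced (for K=1 this reduces to the least-norm input); otherwise the
equality is relaxed into the quadratic terminal-tracking penalty and the
result is flagged infeasible.  The energy reported is ``E = sum_k u(k)^T u(k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .models import DynamicalModel
from .study_data import StudyData

#: Condition-number threshold above which an eigenbasis is reported near-defective.
DEFECTIVE_COND = 1e8

#: Relative residual below which a terminal constraint counts as reachable.
FEASIBILITY_RTOL = 1e-8


class InstabilityError(ValueError):
    """A computation that needs Schur stability received an unstable matrix."""


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(np.asarray(A, dtype=float)))))


def stabilize_matrix(A: np.ndarray) -> tuple[np.ndarray, dict]:
    """Rescale ``A -> A / (1 + |lambda_max|)`` and record what was done."""
    A = np.asarray(A, dtype=float)
    rho = spectral_radius(A)
    factor = 1.0 + rho
    return A / factor, {"original_spectral_radius": rho, "factor": factor}


def _ensure_stable(A: np.ndarray, stabilize: bool) -> tuple[np.ndarray, Optional[dict]]:
    A = np.asarray(A, dtype=float)
    rho = spectral_radius(A)
    if rho < 1.0 - 1e-12:
        return A, None
    if not stabilize:
        raise InstabilityError(f"spectral radius {rho:.6g} >= 1; enable stabilization or rescale A")
    return stabilize_matrix(A)


def average_controllability(A: np.ndarray, stabilize: bool = False) -> np.ndarray:
    """Per-node trace of the infinite-horizon controllability Gramian.

    Solves ``M = A^T M A + I`` (so ``M = sum_i (A^i)^T A^i``) once and reads
    ``AC_j = M[j, j]``, which equals ``trace(W_j)`` of the Gramian driven by
    the canonical input at node ``j``.
    """
    A, _ = _ensure_stable(A, stabilize)
    M = solve_discrete_lyapunov(A.T, np.eye(A.shape[0]))
    return np.diag(M).copy()


def node_gramian(A: np.ndarray, j: int, stabilize: bool = False) -> np.ndarray:
    """Infinite-horizon controllability Gramian for the single input ``e_j``."""
    A, _ = _ensure_stable(A, stabilize)
    n = A.shape[0]
    Q = np.zeros((n, n))
    Q[j, j] = 1.0
    return solve_discrete_lyapunov(A, Q)


def modal_controllability(A: np.ndarray, return_info: bool = False):
    """Eigenmode-weighted controllability ``MC_j = sum_i (1 - |xi_i|^2) |v_ji|^2``.

    Eigenvector columns are normalized to unit Euclidean norm (MC is not
    invariant to this scaling, so the convention is fixed here).  A
    near-defective eigenbasis is flagged in the info dict, values are still
    returned.
    """
    A = np.asarray(A, dtype=float)
    eigvals, V = np.linalg.eig(A)
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    weights = 1.0 - np.abs(eigvals) ** 2
    mc = (np.abs(V) ** 2) @ weights
    if not return_info:
        return mc
    cond = float(np.linalg.cond(V))
    info = {
        "eigenbasis_condition": cond,
        "near_defective": bool(cond > DEFECTIVE_COND),
        "complex_eigenpairs": int(np.sum(np.abs(eigvals.imag) > 0) // 2),
    }
    return mc, info


@dataclass
class EnergyResult:
    """Outcome of one minimum-energy transition."""

    energy: float
    u: np.ndarray  # (K, n_inputs) input sequence
    feasible: bool
    residual: float  # terminal miss ||xT - x(K)||


def _propagation_operators(
    A: np.ndarray, B_r: np.ndarray, K: int
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Maps from the stacked input ``[u(0); ...; u(K-1)]`` to x(K) and to x(1..K-1).

    Returns ``C`` with x(K) = A^K x0 + C u, and the list of partial maps for
    the intermediate states.
    """
    n, m = B_r.shape
    powers = [np.eye(n)]
    for _ in range(K):
        powers.append(A @ powers[-1])
    C = np.hstack([powers[K - 1 - j] @ B_r for j in range(K)])
    partial = []
    for k in range(1, K):
        Ck = np.zeros((n, K * m))
        for j in range(k):
            Ck[:, j * m : (j + 1) * m] = powers[k - 1 - j] @ B_r
        partial.append(Ck)
    return C, partial


def control_energy(
    model: DynamicalModel | np.ndarray,
    x0: np.ndarray,
    xT: np.ndarray,
    input_columns: Sequence[int],
    K: int = 1,
    rho: float = 1.0,
    B: Optional[np.ndarray] = None,
    feasibility_rtol: float = FEASIBILITY_RTOL,
) -> EnergyResult:
    """Minimum-effort input driving ``x0`` to ``xT`` in ``K`` steps.

    ``model`` may be a :class:`DynamicalModel` or a bare ``A`` matrix with
    ``B`` given separately.  The controller only uses the columns of ``B``
    listed in ``input_columns``.

    If ``xT - A^K x0`` lies in the K-step reachable space of the restricted
    input (relative residual below ``feasibility_rtol``), the terminal
    equality is enforced and the quadratic state/input cost is minimized over
    the remaining freedom; the result is exact for K=1 where it is the
    least-norm input.  Otherwise the relaxed problem with the terminal
    tracking penalty replaces the equality and ``feasible=False`` is returned.
    """
    if isinstance(model, DynamicalModel):
        A, Bfull = model.A, model.B
    else:
        A = np.asarray(model, dtype=float)
        if B is None:
            raise ValueError("bare A requires an explicit B")
        Bfull = np.asarray(B, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if rho <= 0:
        raise ValueError("rho must be > 0")
    x0 = np.asarray(x0, dtype=float)
    xT = np.asarray(xT, dtype=float)
    n = A.shape[0]
    if x0.shape != (n,) or xT.shape != (n,):
        raise ValueError(f"states must have shape ({n},)")
    input_columns = list(input_columns)
    B_r = Bfull[:, input_columns]
    m = B_r.shape[1]

    C, partial = _propagation_operators(A, B_r, K)
    powers_x0 = [x0]
    for _ in range(K):
        powers_x0.append(A @ powers_x0[-1])
    d = xT - powers_x0[K]

    # reachability test via least-norm solution of C u = d
    z, *_ = np.linalg.lstsq(C, d, rcond=None)
    resid = float(np.linalg.norm(C @ z - d))
    feasible = resid <= feasibility_rtol * (1.0 + float(np.linalg.norm(d)))

    # intermediate-state tracking blocks (empty for K=1)
    G_rows = [Ck for Ck in partial]
    h_rows = [xT - powers_x0[k] for k in range(1, K)]

    if feasible:
        if G_rows:
            G = np.vstack(G_rows)
            h = np.concatenate(h_rows)
            H = 2.0 * (G.T @ G + rho * np.eye(K * m))
            g = 2.0 * (G.T @ h)
        else:
            H = 2.0 * rho * np.eye(K * m)
            g = np.zeros(K * m)
        KKT = np.block([[H, C.T], [C, np.zeros((n, n))]])
        rhs = np.concatenate([g, d])
        sol, *_ = np.linalg.lstsq(KKT, rhs, rcond=None)
        u = sol[: K * m]
    else:
        G = np.vstack(G_rows + [C])
        h = np.concatenate(h_rows + [d])
        u = np.linalg.solve(G.T @ G + rho * np.eye(K * m), G.T @ h)

    u_seq = u.reshape(K, m)
    energy = float(u @ u)
    terminal_miss = float(np.linalg.norm(C @ u - d))
    return EnergyResult(energy=energy, u=u_seq, feasible=feasible, residual=terminal_miss)


@dataclass
class ControlProfile:
    """Per-participant controllability and per-scenario energy profile."""

    participant: str
    ac: np.ndarray  # (n,) average controllability per node
    mc: np.ndarray  # (n,) modal controllability per node
    energy: np.ndarray  # (n,) per-scenario transition energy
    feasible: np.ndarray  # (n,) bool
    optimal_u: list  # per-scenario (K, m) input sequences
    horizon: int = 1
    rho: float = 1.0
    stabilization: Optional[dict] = None
    metadata: dict = field(default_factory=dict)


def cohort_control_profiles(
    study: StudyData,
    models: dict[str, DynamicalModel],
    K: int = 1,
    rho: float = 1.0,
    energy_input: str = "fitted",
) -> dict[str, ControlProfile]:
    """Controllability and transition energies for every modeled participant.

    AC and MC are computed on a spectrally rescaled copy of each model's A
    when needed (recorded in ``stabilization``); the energy uses the model
    exactly as given.  Per scenario ``s`` the transition is the participant's
    baseline to the observed post-scenario responses, driven through input
    column ``s``.

    ``energy_input`` selects the B column the controller may use:
    ``"fitted"`` takes column ``s`` of the model's own B (canonical identity
    for self-constructed models); ``"canonical"`` always uses the unit vector
    ``e_s``.  For a model whose fitted B reproduces the training transitions
    exactly, the fitted column makes the in-sample energy identically the
    squared input magnitude used during fitting, so the canonical option is
    the informative one for in-sample association analyses.
    """
    if energy_input not in ("fitted", "canonical"):
        raise ValueError(f"unknown energy_input {energy_input!r}")
    n = study.n_items
    profiles: dict[str, ControlProfile] = {}
    for pid, model in models.items():
        i = study.participant_index(pid)
        A_stab, record = model.A, None
        if spectral_radius(model.A) >= 1.0 - 1e-12:
            A_stab, record = stabilize_matrix(model.A)
        ac = average_controllability(A_stab)
        mc, mc_info = modal_controllability(A_stab, return_info=True)
        B_energy = np.eye(n) if energy_input == "canonical" else model.B
        x0 = study.baseline[i].astype(float)
        energy = np.zeros(n)
        feasible = np.zeros(n, dtype=bool)
        inputs = []
        for s in range(n):
            res = control_energy(model.A, x0, study.post[i, s].astype(float), [s], K=K, rho=rho, B=B_energy)
            energy[s] = res.energy
            feasible[s] = res.feasible
            inputs.append(res.u)
        profiles[pid] = ControlProfile(
            participant=pid,
            ac=ac,
            mc=mc,
            energy=energy,
            feasible=feasible,
            optimal_u=inputs,
            horizon=K,
            rho=rho,
            stabilization=record,
            metadata={"modal_info": mc_info, "provenance": model.provenance, "energy_input": energy_input},
        )
    return profiles
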