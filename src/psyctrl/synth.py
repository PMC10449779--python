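"""Synthetic cohorts with the intervention study's exact structure.

Each generated participant has a ground-truth stable interaction matrix A
(random dense, rescaled to a prescribed spectral radius), input matrix
``B = gain * I``, a uniform random Likert baseline, directions from the
push-away-from-baseline rule, and post-intervention responses produced by one
step of ``x(1) = A x0 + B u`` plus Gaussian noise, optionally discretized back
onto the 1..6 grid (round half away from zero, then clip).  The participant's
"drawn" network is the true A with the diagonal removed and each remaining
entry retained with probability ``draw_network_fidelity``.

The ``energy_sensitivity_negative`` plant builds a ground-truth negative
association between the minimum control energy of a scenario and its
sensitivity.  Energy heterogeneity comes from the network's free drift
``A x0 - x0``: a scenario whose intended unit change opposes a large drift at
its target has a high one-step control energy.  Scenarios are ranked by that
theoretical energy and their achieved intended change is attenuated in rank
proportion (the hardest scenario slightly backfires), so high-energy scenarios
under-shoot their targets while the drift keeps their measured transition
energy high.  In planted mode the off-target items stay at baseline (plus
noise) so the plant, not free drift, governs the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .control import control_energy
from .study_data import StudyData, derive_direction, LIKERT_MAX, LIKERT_MIN

PLANT_NONE = "none"
PLANT_ENERGY_SENSITIVITY = "energy_sensitivity_negative"

STUDY_DESIGN = "study_design"
FULL_RANK = "full_rank"


@dataclass
class GeneratorConfig:
    """Study conditions for synthetic cohorts (defaults match the target design)."""

    n_participants: int = 30
    n_items: int = 11
    seed: int = 0
    spectral_radius: float = 0.6
    intervention_gain: float = 1.0
    noise_sd: float = 0.25
    discretize: bool = True
    draw_network_fidelity: float = 0.9
    planted_association: str = PLANT_NONE
    plant_attenuation: float = 1.1  # rank-proportional shrink; >1 lets the hardest scenario backfire
    trajectory_mode: str = STUDY_DESIGN
    baseline_threshold: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.spectral_radius < 1):
            raise ValueError("spectral_radius must lie in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.draw_network_fidelity <= 1):
            raise ValueError("draw_network_fidelity must lie in [0, 1]")
        if self.planted_association not in (PLANT_NONE, PLANT_ENERGY_SENSITIVITY):
            raise ValueError(f"unknown planted_association {self.planted_association!r}")
        if self.trajectory_mode not in (STUDY_DESIGN, FULL_RANK):
            raise ValueError(f"unknown trajectory_mode {self.trajectory_mode!r}")


@dataclass
class SyntheticStudy:
    """A generated cohort together with its ground truth."""

    study: StudyData
    true_A: dict[str, np.ndarray]
    true_B: dict[str, np.ndarray]
    true_energy: np.ndarray  # (P, n) per-scenario minimum energies under the truth
    config: GeneratorConfig = field(repr=False, default=None)


def generate_network(n: int, spectral_radius: float, rng) -> np.ndarray:
    """Random dense matrix rescaled so its spectral radius is exact.

    ``rng`` may be a seed or a :class:`numpy.random.Generator`.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0 < spectral_radius < 1):
        raise ValueError("spectral_radius must lie in (0, 1)")
    rng = np.random.default_rng(rng)
    A = rng.normal(size=(n, n))
    return A * (spectral_radius / np.max(np.abs(np.linalg.eigvals(A))))


def discretize_likert(x: np.ndarray) -> np.ndarray:
    """Round half away from zero, then clip onto the Likert grid."""
    x = np.asarray(x, dtype=float)
    rounded = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return np.clip(rounded, LIKERT_MIN, LIKERT_MAX).astype(int)


def _thin_network(A: np.ndarray, fidelity: float, rng: np.random.Generator) -> np.ndarray:
    drawn = A.copy()
    np.fill_diagonal(drawn, 0.0)
    keep = rng.random(A.shape) < fidelity
    return np.where(keep, drawn, 0.0)


def generate_cohort(config: GeneratorConfig) -> SyntheticStudy:
    """Generate a full cohort; deterministic per config (seed included)."""
    rng = np.random.default_rng(config.seed)
    n, P = config.n_items, config.n_participants
    gain = config.intervention_gain
    participants = [f"P{idx + 1:02d}" for idx in range(P)]
    items = [f"item{idx + 1:02d}" for idx in range(n)]

    baseline = np.zeros((P, n), dtype=int)
    post = np.zeros((P, n, n))
    direction = np.zeros((P, n), dtype=int)
    drawn_networks: dict[str, np.ndarray] = {}
    true_A: dict[str, np.ndarray] = {}
    true_B: dict[str, np.ndarray] = {}

    for i, pid in enumerate(participants):
        A = generate_network(n, config.spectral_radius, rng)
        B = gain * np.eye(n)
        x0 = rng.integers(LIKERT_MIN, LIKERT_MAX + 1, size=n)
        g = derive_direction(x0, config.baseline_threshold)
        noise = rng.normal(scale=config.noise_sd, size=(n, n)) if config.noise_sd > 0 else np.zeros((n, n))

        if config.planted_association == PLANT_ENERGY_SENSITIVITY:
            drift = A @ x0 - x0
            # one-step relaxed energy (rho=1, canonical input) of the full intended unit change
            theo = ((gain * g - drift) / 2.0) ** 2
            ranks = np.argsort(np.argsort(theo))
            lam = 1.0 - config.plant_attenuation * ranks / (n - 1)
            latent = np.tile(x0.astype(float), (n, 1))
            latent[np.arange(n), np.arange(n)] += lam * gain * g
            latent += noise
        else:
            latent = np.tile((A @ x0), (n, 1)) + gain * np.diag(g.astype(float)) + noise

        baseline[i] = x0
        direction[i] = g
        post[i] = discretize_likert(latent) if config.discretize else latent
        true_A[pid] = A
        true_B[pid] = B
        if config.draw_network_fidelity > 0:
            drawn_networks[pid] = _thin_network(A, config.draw_network_fidelity, rng)

    study = StudyData(
        participants=participants,
        items=items,
        baseline=baseline,
        post=post if not config.discretize else post.astype(int),
        direction=direction,
        drawn_networks=drawn_networks or None,
    )

    true_energy = np.zeros((P, n))
    for i, pid in enumerate(participants):
        x0 = baseline[i].astype(float)
        for s in range(n):
            res = control_energy(true_A[pid], x0, np.asarray(post[i, s], dtype=float), [s], K=1, rho=1.0, B=true_B[pid])
            true_energy[i, s] = res.energy

    return SyntheticStudy(study=study, true_A=true_A, true_B=true_B, true_energy=true_energy, config=config)


def generate_full_rank_trajectory(true_A: np.ndarray, true_B: np.ndarray, m: int, seed: int):
    """Noise-free snapshots with full stacked rank, for identifiability checks.

    Draws random states and inputs until ``[X1; U]`` has rank ``2n`` (at most
    10 attempts), then sets ``X2 = A X1 + B U`` exactly.
    """
    from .models import SnapshotSet

    true_A = np.asarray(true_A, dtype=float)
    true_B = np.asarray(true_B, dtype=float)
    n = true_A.shape[0]
    if m < 2 * n:
        raise ValueError(f"need m >= {2 * n} snapshot columns for full stacked rank")
    root = np.random.default_rng(seed)
    for stream in root.spawn(10):
        X1 = stream.normal(size=(n, m))
        U = stream.normal(size=(n, m))
        if np.linalg.matrix_rank(np.vstack([X1, U])) == 2 * n:
            return SnapshotSet(X1=X1, X2=true_A @ X1 + true_B @ U, U=U)
    raise RuntimeError("could not generate a full-rank snapshot set in 10 attempts")


def write_synthetic(sim: SyntheticStudy, directory: str | Path) -> None:
    """Write the study files plus ground truth and a config manifest."""
    from dataclasses import asdict

    from .study_data import write_study

    directory = Path(directory)
    write_study(sim.study, directory)
    for pid in sim.study.participants:
        truth = {
            "A": sim.true_A[pid].tolist(),
            "B": sim.true_B[pid].tolist(),
            "energy": sim.true_energy[sim.study.participant_index(pid)].tolist(),
        }
        (directory / f"truth_{pid}.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    (directory / "synth_manifest.json").write_text(
        json.dumps(asdict(sim.config), indent=2, sort_keys=True) + "\n"
    )
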