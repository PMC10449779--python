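"""Perturbation effect, sensitivity and specificity of item-targeted interventions.

For participant ``i`` with baseline response ``r_k0`` to item ``k`` and
response ``r_sk`` to item ``k`` after the scenario targeting item ``s``:

- effect        ``e[i, s, k] = (r_sk - r_k0) / r_k0``  (normalized change),
- sensitivity   ``se[i, s] = e[i, s, s] * g[i, s]``   (signed by the intended
  direction ``g``; positive = the target moved the intended way),
- specificity   ``sp[i, s] = |e[i, s, s]| / mean_{k != s} |e[i, s, k]|``
  (>1 = the targeted item moved more than the others on average).

A specificity denominator of zero (no off-target movement at all) is either
masked out or replaced by a configurable epsilon guard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .study_data import StudyData


@dataclass
class EffectTensor:
    """Per-cohort effect metrics; axes ordered (participant, scenario[, item])."""

    effect: np.ndarray  # (P, n, n)
    sensitivity: np.ndarray  # (P, n)
    specificity: np.ndarray  # (P, n), NaN where invalid
    valid_mask: np.ndarray  # (P, n) bool, True where specificity is defined
    metadata: Optional[dict] = None


def compute_effect(baseline: np.ndarray, post: np.ndarray) -> np.ndarray:
    """Normalized response change ``(post - baseline) / baseline`` per item.

    ``baseline`` is ``(P, n)``, ``post`` is ``(P, n, n)``; the baseline of item
    ``k`` normalizes every scenario's change of item ``k``.
    """
    baseline = np.asarray(baseline, dtype=float)
    post = np.asarray(post, dtype=float)
    if post.shape != baseline.shape[:1] + (baseline.shape[1],) * 2:
        raise ValueError(f"shape mismatch: baseline {baseline.shape}, post {post.shape}")
    if np.any(baseline == 0):
        raise ValueError("baseline contains zeros; normalized change undefined")
    return (post - baseline[:, None, :]) / baseline[:, None, :]


def compute_sensitivity(effect: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Signed on-target effect: diagonal of the effect tensor times direction."""
    effect = np.asarray(effect, dtype=float)
    direction = np.asarray(direction)
    if effect.shape[:2] != direction.shape or effect.shape[1] != effect.shape[2]:
        raise ValueError(f"shape mismatch: effect {effect.shape}, direction {direction.shape}")
    if not np.all(np.isin(direction, (-1, 1))):
        raise ValueError("direction entries must be -1 or +1")
    on_target = np.diagonal(effect, axis1=1, axis2=2)
    return on_target * direction


def compute_specificity(effect: np.ndarray, epsilon: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """On-target absolute effect relative to the mean off-target absolute effect.

    Returns ``(specificity, valid_mask)``.  Cells whose off-target mean is zero
    are masked (NaN) when ``epsilon == 0``, else computed with denominator
    ``epsilon``.
    """
    effect = np.asarray(effect, dtype=float)
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    P, n, _ = effect.shape
    absval = np.abs(effect)
    target = np.diagonal(absval, axis1=1, axis2=2)
    off_mean = (absval.sum(axis=2) - target) / (n - 1)
    valid = off_mean > 0
    sp = np.full((P, n), np.nan)
    np.divide(target, off_mean, out=sp, where=valid)
    if epsilon > 0:
        sp = np.where(valid, sp, target / epsilon)
        valid = np.ones_like(valid)
    return sp, valid


def effect_tensor(study: StudyData, epsilon: float = 0.0) -> EffectTensor:
    """Compute all effect metrics for a cohort."""
    effect = compute_effect(study.baseline, study.post)
    sensitivity = compute_sensitivity(effect, study.direction)
    specificity, valid = compute_specificity(effect, epsilon)
    return EffectTensor(
        effect=effect,
        sensitivity=sensitivity,
        specificity=specificity,
        valid_mask=valid,
        metadata={"epsilon_specificity": epsilon, "std_convention": "sample (ddof=1)"},
    )


def _unit_summary(values: np.ndarray, axis: str) -> dict:
    """Mean/std over per-unit means; masked (NaN) cells ignored.

    ``values`` is (P, n).  ``axis='participants'`` summarizes one value per
    participant (mean over that participant's scenarios); ``axis='items'``
    one value per item/scenario (mean over participants).
    """
    if axis not in ("participants", "items"):
        raise ValueError(f"unknown axis {axis!r}")
    with warnings.catch_warnings():
        # an all-masked unit legitimately yields NaN; reported as missing below
        warnings.simplefilter("ignore", RuntimeWarning)
        per_unit = np.nanmean(values, axis=1 if axis == "participants" else 0)
    defined = np.isfinite(per_unit)
    summary = {
        "per_unit": per_unit,
        "n_units": int(defined.sum()),
        "missing_units": int((~defined).sum()),
        "mean": float(np.mean(per_unit[defined])) if defined.any() else float("nan"),
        "std": float(np.std(per_unit[defined], ddof=1)) if defined.sum() > 1 else float("nan"),
    }
    return summary


def summarize_effects(eff: EffectTensor, axis: str) -> dict:
    """Fig-2-style marginal summaries of sensitivity and specificity.

    ``axis`` chooses the unit of the distribution: ``'participants'`` (one
    value per participant, averaged over scenarios) or ``'items'`` (one value
    per item, averaged over participants).  Masked specificity cells are
    ignored; a unit with every cell masked is reported missing.
    """
    sp = np.where(eff.valid_mask, eff.specificity, np.nan)
    with np.errstate(invalid="ignore"):
        return {
            "axis": axis,
            "sensitivity": _unit_summary(eff.sensitivity, axis),
            "specificity": _unit_summary(sp, axis),
            "std_convention": "sample (ddof=1)",
            "pooling": "per-unit means, then mean/std over units",
        }
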