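"""Group-level statistics: rank correlations, Fisher combination, accuracy.

Per participant, a control metric (AC, MC, or transition energy — 11 values,
one per node/scenario) is paired with an intervention outcome (sensitivity or
specificity — 11 values, one per scenario) and summarized by Kendall's tau-b.
Likert-derived quantities guarantee ties, hence the tie-corrected variant.
The per-participant p-values are combined across the cohort with Fisher's
method: ``X = -2 sum(ln p_i)`` compared to a chi-square with ``2k`` degrees of
freedom.

Prediction accuracy is the Pearson correlation between model-predicted and
observed post-intervention responses, pooled per participant (all scenario x
item cells) and per item (all participant x scenario cells).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional

import numpy as np
from scipy import stats as sps

from .control import ControlProfile
from .effects import EffectTensor
from .study_data import StudyData

#: Largest sample size for which the exact permutation null of tau is enumerated.
EXACT_N_MAX = 9


@dataclass
class KendallResult:
    tau: float
    p: float
    n: int
    method: str
    reason: Optional[str] = None  # why tau/p are missing, if they are

    def __iter__(self):
        return iter((self.tau, self.p))


def _tau_b_S(x: np.ndarray, y: np.ndarray) -> float:
    """Concordance-minus-discordance count (the numerator of tau before scaling)."""
    i, j = np.triu_indices(len(x), 1)
    return float(np.sum(np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])))


def _exact_permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p for tau-b by enumerating all permutations of y.

    The tie pattern of y is preserved under permutation, so the tau-b
    denominator is constant and tail probabilities of |tau| equal those of the
    concordance count |S|.
    """
    n = len(x)
    i, j = np.triu_indices(n, 1)
    sx = np.sign(x[i] - x[j])
    S_obs = abs(_tau_b_S(x, y))
    total = 0
    hits = 0
    block = []
    for perm in permutations(y):
        block.append(perm)
        if len(block) == 40320:
            arr = np.asarray(block)
            S = np.abs((sx * np.sign(arr[:, i] - arr[:, j])).sum(axis=1))
            hits += int(np.sum(S >= S_obs - 1e-9))
            total += len(block)
            block = []
    if block:
        arr = np.asarray(block)
        S = np.abs((sx * np.sign(arr[:, i] - arr[:, j])).sum(axis=1))
        hits += int(np.sum(S >= S_obs - 1e-9))
        total += len(block)
    return hits / total


def kendall_tau(x, y, method: str = "auto") -> KendallResult:
    """Tie-corrected Kendall rank correlation with a two-sided p-value.

    ``method='auto'`` uses the exact permutation null for n <= 9 and the
    tie-corrected normal approximation otherwise; ``'exact'`` and
    ``'asymptotic'`` force one path.  NaN pairs are dropped pairwise.  An
    all-tied argument leaves tau undefined and is reported as missing with a
    reason rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return KendallResult(math.nan, math.nan, n, "none", reason="fewer than 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return KendallResult(math.nan, math.nan, n, "none", reason="an argument is constant (all tied)")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and n <= EXACT_N_MAX)
    if method == "exact" and n > EXACT_N_MAX:
        raise ValueError(f"exact permutation p limited to n <= {EXACT_N_MAX}")
    tau, p_asym = sps.kendalltau(x, y, variant="b")
    if use_exact:
        return KendallResult(float(tau), _exact_permutation_p(x, y), n, "exact_permutation")
    return KendallResult(float(tau), float(p_asym), n, "normal_approximation")


@dataclass
class FisherResult:
    statistic: float
    group_p: float
    n_used: int
    n_dropped: int


def fisher_combine(pvals) -> FisherResult:
    """Fisher's method: ``-2 sum(ln p)`` against chi-square with 2k df.

    NaN entries are dropped (count recorded).  With a single p-value the
    combination is the identity.  An empty input yields a missing result.
    """
    p = np.asarray(pvals, dtype=float)
    keep = np.isfinite(p)
    dropped = int((~keep).sum())
    p = p[keep]
    if p.size == 0:
        return FisherResult(math.nan, math.nan, 0, dropped)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.sum(np.log(p)))
    group_p = float(sps.chi2.sf(statistic, df=2 * p.size))
    return FisherResult(statistic, group_p, int(p.size), dropped)


@dataclass
class GroupStatResult:
    """Cohort-level association between a control metric and an outcome."""

    pairing: str
    provenance: str
    participants: list[str]
    tau: np.ndarray  # per participant, NaN where undefined
    p: np.ndarray
    mean_tau: float
    std_tau: float
    group_statistic: float
    group_p: float
    n_significant: int
    alpha: float
    n_excluded: int  # participants whose tau was undefined
    metadata: dict = field(default_factory=dict)


METRIC_FIELDS = {"ac": "ac", "mc": "mc", "energy": "energy"}


def metric_effect_association(
    study: StudyData,
    effects: EffectTensor,
    profiles: dict[str, ControlProfile],
    metric: str,
    outcome: str,
    provenance: str = "",
    alpha: float = 0.05,
    tau_method: str = "auto",
) -> GroupStatResult:
    """Per-participant Kendall tau between a control metric and an outcome,
    Fisher-combined across the cohort.

    Node ``j``'s AC/MC is paired with scenario ``j``'s outcome; energies pair
    by scenario directly.  Participants flagged excluded in the study, or
    lacking a profile, are left out; undefined taus are dropped from the
    combination with their count reported.
    """
    if metric not in METRIC_FIELDS:
        raise ValueError(f"unknown metric {metric!r}")
    if outcome not in ("sensitivity", "specificity"):
        raise ValueError(f"unknown outcome {outcome!r}")
    ids = [p for p in study.included_participants() if p in profiles]
    taus, ps = [], []
    for pid in ids:
        i = study.participant_index(pid)
        xvec = np.asarray(getattr(profiles[pid], METRIC_FIELDS[metric]), dtype=float)
        if outcome == "sensitivity":
            yvec = effects.sensitivity[i]
        else:
            yvec = np.where(effects.valid_mask[i], effects.specificity[i], np.nan)
        res = kendall_tau(xvec, yvec, method=tau_method)
        taus.append(res.tau)
        ps.append(res.p)
    tau_arr = np.asarray(taus, dtype=float)
    p_arr = np.asarray(ps, dtype=float)
    defined = np.isfinite(tau_arr)
    fisher = fisher_combine(p_arr[defined]) if defined.any() else FisherResult(math.nan, math.nan, 0, 0)
    mean_tau = float(np.mean(tau_arr[defined])) if defined.any() else math.nan
    std_tau = float(np.std(tau_arr[defined], ddof=1)) if defined.sum() > 1 else math.nan
    n_sig = int(np.sum(p_arr[defined] < alpha)) if defined.any() else 0
    return GroupStatResult(
        pairing=f"{metric}~{outcome}",
        provenance=provenance,
        participants=ids,
        tau=tau_arr,
        p=p_arr,
        mean_tau=mean_tau,
        std_tau=std_tau,
        group_statistic=fisher.statistic,
        group_p=fisher.group_p,
        n_significant=n_sig,
        alpha=alpha,
        n_excluded=int((~defined).sum()),
        metadata={"tau_variant": "b", "tau_method": tau_method},
    )


def _pearson_or_nan(x: np.ndarray, y: np.ndarray) -> tuple[float, Optional[str]]:
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        return math.nan, "fewer than 3 complete pairs"
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, "zero variance"
    return float(sps.pearsonr(x, y).statistic), None


def prediction_accuracy(predicted: np.ndarray, observed: np.ndarray) -> dict:
    """Pearson correlation between predicted and observed responses.

    ``predicted`` and ``observed`` are ``(P, n, n)`` tensors indexed
    (participant, scenario, item).  Correlations are pooled per participant
    and per item; units with undefined correlations are reported with their
    reason, never silently dropped.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("shape mismatch between predicted and observed")
    P, n, _ = predicted.shape
    per_participant = np.full(P, np.nan)
    participant_reasons: dict[int, str] = {}
    for i in range(P):
        r, reason = _pearson_or_nan(predicted[i].ravel(), observed[i].ravel())
        per_participant[i] = r
        if reason:
            participant_reasons[i] = reason
    per_item = np.full(n, np.nan)
    item_reasons: dict[int, str] = {}
    for k in range(n):
        r, reason = _pearson_or_nan(predicted[:, :, k].ravel(), observed[:, :, k].ravel())
        per_item[k] = r
        if reason:
            item_reasons[k] = reason

    def _ms(v: np.ndarray) -> dict:
        d = np.isfinite(v)
        return {
            "mean": float(np.mean(v[d])) if d.any() else math.nan,
            "std": float(np.std(v[d], ddof=1)) if d.sum() > 1 else math.nan,
            "n": int(d.sum()),
        }

    return {
        "per_participant": per_participant,
        "per_item": per_item,
        "participants": _ms(per_participant),
        "items": _ms(per_item),
        "participant_missing": participant_reasons,
        "item_missing": item_reasons,
        "correlation": "pearson",
    }
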