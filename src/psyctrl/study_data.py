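"""Domain containers, validation, and tidy-file I/O for item-targeted intervention studies.

The experimental design: each participant answers ``n_items`` Likert questions
(integers 1..6) at baseline, then works through one targeted scenario per item;
after each scenario the full questionnaire is re-administered.  Scenario ``s``
is constructed to push item ``s`` in a known direction (+1 = agree more,
-1 = agree less).  Participants may additionally draw their perceived causal
network among the items, used downstream as a self-constructed interaction
matrix.

On disk a study is a directory of tidy UTF-8 CSV files plus a JSON manifest:

- ``responses_baseline.csv``  (participant, item, response)
- ``responses_post.csv``      (participant, scenario, item, response)
- ``directions.csv``          (participant, scenario, direction)
- ``networks.csv``            (participant, source, target, weight), optional
- ``manifest.json``           (participant/item ordering, config echo)

Writes are deterministic (fixed row sort and column order, sorted JSON keys),
so writing the same study twice yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

LIKERT_MIN = 1
LIKERT_MAX = 6

BASELINE_FILE = "responses_baseline.csv"
POST_FILE = "responses_post.csv"
DIRECTIONS_FILE = "directions.csv"
NETWORKS_FILE = "networks.csv"
MANIFEST_FILE = "manifest.json"


class StudyError(ValueError):
    """Malformed or inconsistent study data."""


@dataclass(frozen=True)
class Violation:
    """One invariant violation, with the coordinates where it occurred."""

    code: str
    message: str
    participant: Optional[str] = None
    scenario: Optional[str] = None
    item: Optional[str] = None


@dataclass
class StudyConfig:
    """Run-level configuration for reading and interpreting a study.

    direction_rule
        ``"from_file"`` reads intended intervention directions from
        ``directions.csv``; ``"from_baseline_threshold"`` derives them from the
        baseline stance: push away from the current answer, i.e. +1 (increase)
        when baseline <= ``baseline_threshold``, else -1.
    baseline_threshold
        Pivot of the fallback direction rule, in 1..5.
    exclusion_list
        Participants flagged as excluded from group statistics.  They are
        retained in the data, never silently dropped.
    epsilon_specificity
        Zero-denominator guard for the specificity ratio; 0 means "mask the
        undefined cell" rather than substitute a value.
    """

    direction_rule: str = "from_file"
    baseline_threshold: int = 3
    exclusion_list: tuple[str, ...] = ()
    epsilon_specificity: float = 0.0

    def __post_init__(self) -> None:
        if self.direction_rule not in ("from_file", "from_baseline_threshold"):
            raise StudyError(f"unknown direction_rule {self.direction_rule!r}")
        if not (LIKERT_MIN <= self.baseline_threshold <= LIKERT_MAX - 1):
            raise StudyError("baseline_threshold must be in 1..5")
        if self.epsilon_specificity < 0:
            raise StudyError("epsilon_specificity must be >= 0")
        object.__setattr__(self, "exclusion_list", tuple(self.exclusion_list))


@dataclass
class StudyData:
    """One cohort of the intervention experiment.

    Attributes
    ----------
    participants, items
        Ordered identifiers; array axes follow these orders.
    baseline
        ``(P, n)`` int array, responses before any intervention, in 1..6.
    post
        ``(P, n, n)`` int array indexed ``[participant, scenario, item]``:
        responses to every item after the scenario targeting item ``scenario``.
    direction
        ``(P, n)`` int array in {-1, +1}: intended direction of scenario ``s``.
    drawn_networks
        Optional per-participant ``(n, n)`` real matrices of perceived causal
        relations, convention ``A[target, source]``, zero diagonal.  Maps
        participant id -> matrix; participants without a drawing are absent.
    excluded
        Participants flagged for exclusion from group-level statistics.
    """

    participants: list[str]
    items: list[str]
    baseline: np.ndarray
    post: np.ndarray
    direction: np.ndarray
    drawn_networks: Optional[dict[str, np.ndarray]] = None
    excluded: list[str] = field(default_factory=list)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_items(self) -> int:
        return len(self.items)

    def participant_index(self, participant: str) -> int:
        try:
            return self.participants.index(participant)
        except ValueError:
            raise StudyError(f"unknown participant {participant!r}") from None

    def drawn_network(self, participant: str) -> Optional[np.ndarray]:
        if not self.drawn_networks:
            return None
        return self.drawn_networks.get(participant)

    def included_participants(self) -> list[str]:
        return [p for p in self.participants if p not in set(self.excluded)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyData):
            return NotImplemented
        if (
            self.participants != other.participants
            or self.items != other.items
            or self.excluded != other.excluded
        ):
            return False
        if not (
            np.array_equal(self.baseline, other.baseline)
            and np.array_equal(self.post, other.post)
            and np.array_equal(self.direction, other.direction)
        ):
            return False
        a = self.drawn_networks or {}
        b = other.drawn_networks or {}
        if set(a) != set(b):
            return False
        return all(np.array_equal(a[k], b[k]) for k in a)


def derive_direction(baseline: np.ndarray, threshold: int = 3) -> np.ndarray:
    """Intended direction from the baseline stance: push away from it.

    A low baseline answer (<= threshold) means the scenario tries to increase
    agreement (+1); a high answer means it tries to decrease it (-1).
    """
    baseline = np.asarray(baseline)
    return np.where(baseline <= threshold, 1, -1).astype(int)


def validate_study(study: StudyData) -> list[Violation]:
    """Return every invariant violation; empty list iff the study is valid."""
    out: list[Violation] = []
    P, n = study.n_participants, study.n_items

    def _shape(name: str, arr: np.ndarray, shape: tuple[int, ...]) -> bool:
        if arr.shape != shape:
            out.append(Violation("shape", f"{name} has shape {arr.shape}, expected {shape}"))
            return False
        return True

    ok_base = _shape("baseline", study.baseline, (P, n))
    ok_post = _shape("post", study.post, (P, n, n))
    ok_dir = _shape("direction", study.direction, (P, n))

    for name, arr, ok in (("baseline", study.baseline, ok_base), ("post", study.post, ok_post)):
        if ok and not np.issubdtype(arr.dtype, np.integer) and not np.all(arr == np.round(arr)):
            out.append(Violation("integer", f"{name} responses must be integers"))
    if ok_base:
        bad = np.argwhere((study.baseline < LIKERT_MIN) | (study.baseline > LIKERT_MAX))
        for i, k in bad:
            out.append(
                Violation(
                    "range",
                    f"baseline response {study.baseline[i, k]} outside {LIKERT_MIN}..{LIKERT_MAX}",
                    participant=study.participants[i],
                    item=study.items[k],
                )
            )
    if ok_post:
        bad = np.argwhere((study.post < LIKERT_MIN) | (study.post > LIKERT_MAX))
        for i, s, k in bad:
            out.append(
                Violation(
                    "range",
                    f"post response {study.post[i, s, k]} outside {LIKERT_MIN}..{LIKERT_MAX}",
                    participant=study.participants[i],
                    scenario=study.items[s],
                    item=study.items[k],
                )
            )
    if ok_dir:
        bad = np.argwhere(~np.isin(study.direction, (-1, 1)))
        for i, s in bad:
            out.append(
                Violation(
                    "direction",
                    f"direction {study.direction[i, s]} not in {{-1, +1}}",
                    participant=study.participants[i],
                    scenario=study.items[s],
                )
            )
    for pid, net in (study.drawn_networks or {}).items():
        if net.shape != (n, n):
            out.append(
                Violation("shape", f"drawn network has shape {net.shape}, expected {(n, n)}", participant=pid)
            )
            continue
        if not np.all(np.isfinite(net)):
            out.append(Violation("finite", "drawn network has non-finite entries", participant=pid))
        if np.any(np.diag(net) != 0):
            out.append(Violation("diagonal", "drawn network diagonal is not zero", participant=pid))
    for pid in study.excluded:
        if pid not in study.participants:
            out.append(Violation("excluded", f"excluded id {pid!r} is not a participant", participant=pid))
    return out


def _require_valid(study: StudyData) -> None:
    violations = validate_study(study)
    if violations:
        head = "; ".join(v.message for v in violations[:5])
        raise StudyError(f"{len(violations)} study invariant violation(s): {head}")


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise StudyError(f"missing study file {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise StudyError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise StudyError(f"{path} lacks column(s) {missing}")
    return df


def _response_array(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    try:
        df = df.assign(response=df["response"].astype(int))
    except ValueError as exc:
        raise StudyError(f"non-integer response in {path}: {exc}") from exc
    return df


def read_study(directory: str | Path, config: Optional[StudyConfig] = None) -> StudyData:
    """Read a tidy study directory into a validated :class:`StudyData`."""
    config = config or StudyConfig()
    directory = Path(directory)

    manifest_path = directory / MANIFEST_FILE
    if not manifest_path.exists():
        raise StudyError(f"missing study file {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    participants = [str(p) for p in manifest["participants"]]
    items = [str(i) for i in manifest["items"]]
    excluded = [str(p) for p in manifest.get("excluded", [])]
    excluded = sorted(set(excluded) | set(config.exclusion_list))
    P, n = len(participants), len(items)
    p_idx = {p: i for i, p in enumerate(participants)}
    i_idx = {it: k for k, it in enumerate(items)}

    base_df = _response_array(_read_csv(directory / BASELINE_FILE, ["participant", "item", "response"]), directory / BASELINE_FILE)
    baseline = np.zeros((P, n), dtype=int)
    seen = np.zeros((P, n), dtype=bool)
    for row in base_df.itertuples(index=False):
        try:
            i, k = p_idx[row.participant], i_idx[row.item]
        except KeyError as exc:
            raise StudyError(f"{BASELINE_FILE}: unknown identifier {exc}") from None
        baseline[i, k] = row.response
        seen[i, k] = True
    if not seen.all():
        i, k = np.argwhere(~seen)[0]
        raise StudyError(f"{BASELINE_FILE}: missing baseline for {participants[i]}/{items[k]}")

    post_df = _response_array(
        _read_csv(directory / POST_FILE, ["participant", "scenario", "item", "response"]), directory / POST_FILE
    )
    post = np.zeros((P, n, n), dtype=int)
    seen3 = np.zeros((P, n, n), dtype=bool)
    for row in post_df.itertuples(index=False):
        try:
            i, s, k = p_idx[row.participant], i_idx[row.scenario], i_idx[row.item]
        except KeyError as exc:
            raise StudyError(f"{POST_FILE}: unknown identifier {exc}") from None
        post[i, s, k] = row.response
        seen3[i, s, k] = True
    if not seen3.all():
        i, s, k = np.argwhere(~seen3)[0]
        raise StudyError(
            f"{POST_FILE}: missing response for {participants[i]}, scenario {items[s]}, item {items[k]}"
        )

    if config.direction_rule == "from_baseline_threshold":
        # scenario s targets item s, so its direction depends on baseline[:, s]
        direction = derive_direction(baseline, config.baseline_threshold)
    else:
        dir_df = _read_csv(directory / DIRECTIONS_FILE, ["participant", "scenario", "direction"])
        direction = np.zeros((P, n), dtype=int)
        for row in dir_df.itertuples(index=False):
            try:
                i, s = p_idx[row.participant], i_idx[row.scenario]
            except KeyError as exc:
                raise StudyError(f"{DIRECTIONS_FILE}: unknown identifier {exc}") from None
            direction[i, s] = int(row.direction)

    drawn: Optional[dict[str, np.ndarray]] = None
    net_path = directory / NETWORKS_FILE
    if net_path.exists():
        net_df = _read_csv(net_path, ["participant", "source", "target", "weight"])
        drawn = {}
        for row in net_df.itertuples(index=False):
            try:
                i = p_idx[row.participant]
                src, tgt = i_idx[row.source], i_idx[row.target]
            except KeyError as exc:
                raise StudyError(f"{NETWORKS_FILE}: unknown identifier {exc}") from None
            A = drawn.setdefault(participants[i], np.zeros((n, n)))
            A[tgt, src] = float(row.weight)
        drawn = drawn or None

    study = StudyData(
        participants=participants,
        items=items,
        baseline=baseline,
        post=post,
        direction=direction,
        drawn_networks=drawn,
        excluded=excluded,
    )
    _require_valid(study)
    return study


def write_study(study: StudyData, directory: str | Path) -> None:
    """Write a study to the tidy layout :func:`read_study` accepts.

    Deterministic: row order follows the manifest orders, JSON keys are
    sorted, so repeated writes of equal studies are byte-identical.
    """
    _require_valid(study)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    P, n = study.n_participants, study.n_items

    rows = [
        (study.participants[i], study.items[k], study.baseline[i, k])
        for i in range(P)
        for k in range(n)
    ]
    pd.DataFrame(rows, columns=["participant", "item", "response"]).to_csv(
        directory / BASELINE_FILE, index=False
    )

    rows = [
        (study.participants[i], study.items[s], study.items[k], study.post[i, s, k])
        for i in range(P)
        for s in range(n)
        for k in range(n)
    ]
    pd.DataFrame(rows, columns=["participant", "scenario", "item", "response"]).to_csv(
        directory / POST_FILE, index=False
    )

    rows = [
        (study.participants[i], study.items[s], study.direction[i, s])
        for i in range(P)
        for s in range(n)
    ]
    pd.DataFrame(rows, columns=["participant", "scenario", "direction"]).to_csv(
        directory / DIRECTIONS_FILE, index=False
    )

    if study.drawn_networks:
        rows = []
        for pid in study.participants:
            net = study.drawn_networks.get(pid)
            if net is None:
                continue
            for tgt in range(n):
                for src in range(n):
                    if net[tgt, src] != 0:
                        rows.append((pid, study.items[src], study.items[tgt], repr(float(net[tgt, src]))))
        pd.DataFrame(rows, columns=["participant", "source", "target", "weight"]).to_csv(
            directory / NETWORKS_FILE, index=False
        )
    else:
        # absence of the file encodes absence of drawings
        net_path = directory / NETWORKS_FILE
        if net_path.exists():
            net_path.unlink()

    manifest = {
        "participants": study.participants,
        "items": study.items,
        "excluded": list(study.excluded),
        "likert_range": [LIKERT_MIN, LIKERT_MAX],
    }
    (directory / MANIFEST_FILE).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def config_to_dict(config: StudyConfig) -> dict:
    return dataclasses.asdict(config)
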