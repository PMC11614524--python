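"""Event-level dataset container, CSV round-trip, and exclusion rules.

A dataset is a flat collection of trial attempts: (participant, condition,
block, trial, attempt) with the trial's display and the ordered target
selections.  On disk a dataset is two UTF-8 CSV files:

* ``<stem>.csv`` -- one row per item selection, header
  ``participant_id,difficulty,ratio_condition,block,trial,attempt,terminated,
  select_index,item_id,item_class,is_target,x,y,t_sec``
* ``<stem>_display.csv`` -- one row per display item, header
  ``participant_id,trial,item_id,item_class,is_target,x,y``

Coordinates are pixels with the origin bottom-left, x rightward, y upward;
timestamps are seconds from trial onset.  Trial numbers are unique within
a participant (they key the display file).  Sequences contain target
selections only; an attempt that ended by clicking a distractor is marked
``terminated=1`` on its rows and its distractor click is not logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    ConditionKey,
    Item,
    ModelParams,
    SelectionSequence,
    TrialDisplay,
)

__all__ = [
    "TrialRecord",
    "Dataset",
    "ExclusionReport",
    "read_events",
    "write_events",
    "apply_exclusions",
    "filter_half",
    "EVENT_COLUMNS",
    "DISPLAY_COLUMNS",
]

EVENT_COLUMNS = [
    "participant_id",
    "difficulty",
    "ratio_condition",
    "block",
    "trial",
    "attempt",
    "terminated",
    "select_index",
    "item_id",
    "item_class",
    "is_target",
    "x",
    "y",
    "t_sec",
]

DISPLAY_COLUMNS = ["participant_id", "trial", "item_id", "item_class", "is_target", "x", "y"]


@dataclass(frozen=True)
class TrialRecord:
    """One trial attempt of one participant."""

    participant_id: str
    condition: ConditionKey
    block: int
    trial: int
    attempt: int
    terminated: bool
    display: TrialDisplay
    sequence: SelectionSequence

    def __post_init__(self) -> None:
        self.sequence.validate_against(self.display)
        if not self.terminated and len(self.sequence) != len(self.display.targets):
            raise ValueError(
                f"non-terminated attempt {self.participant_id}/{self.trial} has "
                f"{len(self.sequence)} selections for {len(self.display.targets)} targets"
            )


@dataclass
class Dataset:
    """Participants x conditions x trials of displays and selection sequences."""

    trials: List[TrialRecord]
    provenance: str = "real"  # "real" | "simulated"
    generating: Optional[object] = None  # GroupParams when simulated
    true_participant_params: Optional[Dict[Tuple[str, ConditionKey], ModelParams]] = None

    @property
    def participants(self) -> List[str]:
        return sorted({t.participant_id for t in self.trials})

    @property
    def conditions(self) -> List[ConditionKey]:
        return sorted({t.condition for t in self.trials})

    def n_trials(self) -> int:
        return len(self.trials)

    def for_participant(self, pid: str) -> List[TrialRecord]:
        return [t for t in self.trials if t.participant_id == pid]

    def subset(self, keep: Sequence[TrialRecord]) -> "Dataset":
        kept = set(map(id, keep))
        return Dataset(
            trials=[t for t in self.trials if id(t) in kept],
            provenance=self.provenance,
            generating=self.generating,
            true_participant_params=self.true_participant_params,
        )

    def same_events(self, other: "Dataset") -> bool:
        """Content equality of the event-level data (ignores provenance)."""
        if len(self.trials) != len(other.trials):
            return False

        def key(t: TrialRecord):
            return (t.participant_id, t.block, t.trial, t.attempt)

        for a, b in zip(sorted(self.trials, key=key), sorted(other.trials, key=key)):
            if (
                key(a) != key(b)
                or a.condition != b.condition
                or a.terminated != b.terminated
                or a.sequence != b.sequence
                or a.display.items != b.display.items
                or (a.display.width, a.display.height) != (b.display.width, b.display.height)
            ):
                return False
        return True


@dataclass
class ExclusionReport:
    """Bookkeeping of the exclusion pass; counts reconcile in/out sizes."""

    n_terminated_removed: int = 0
    n_trials_removed_by_timing: int = 0
    n_removed_with_dropped_participants: int = 0
    participants_dropped: List[str] = field(default_factory=list)
    valid_trials_per_condition: Dict[str, int] = field(default_factory=dict)

    @property
    def n_removed_total(self) -> int:
        return (
            self.n_terminated_removed
            + self.n_trials_removed_by_timing
            + self.n_removed_with_dropped_participants
        )


def write_events(dataset: Dataset, events_path: str | Path) -> Tuple[Path, Path]:
    """Write a dataset to the two-file CSV schema; returns the paths."""
    events_path = Path(events_path)
    display_path = events_path.with_name(events_path.stem + "_display.csv")

    ev_rows = []
    disp_rows = []
    seen_displays = set()
    for t in sorted(
        dataset.trials, key=lambda t: (t.participant_id, t.block, t.trial, t.attempt)
    ):
        times = t.sequence.times
        for i, item_id in enumerate(t.sequence.selected_ids):
            it = t.display.target_by_id(item_id)
            ev_rows.append(
                {
                    "participant_id": t.participant_id,
                    "difficulty": t.condition.difficulty,
                    "ratio_condition": t.condition.ratio,
                    "block": t.block,
                    "trial": t.trial,
                    "attempt": t.attempt,
                    "terminated": int(t.terminated),
                    "select_index": i,
                    "item_id": it.item_id,
                    "item_class": it.item_class,
                    "is_target": 1,
                    "x": repr(float(it.x)),
                    "y": repr(float(it.y)),
                    "t_sec": "" if times is None else repr(float(times[i])),
                }
            )
        dkey = (t.participant_id, t.trial)
        if dkey not in seen_displays:
            seen_displays.add(dkey)
            for it in t.display.items:
                disp_rows.append(
                    {
                        "participant_id": t.participant_id,
                        "trial": t.trial,
                        "item_id": it.item_id,
                        "item_class": it.item_class,
                        "is_target": int(it.is_target),
                        "x": repr(float(it.x)),
                        "y": repr(float(it.y)),
                    }
                )
    pd.DataFrame(ev_rows, columns=EVENT_COLUMNS).to_csv(
        events_path, index=False, lineterminator="\n"
    )
    pd.DataFrame(disp_rows, columns=DISPLAY_COLUMNS).to_csv(
        display_path, index=False, lineterminator="\n"
    )
    return events_path, display_path


def _fail(path: Path, row: int, msg: str) -> None:
    # +2: 1-based line numbers plus the header line
    raise ValueError(f"{path}:{row + 2}: {msg}")


def read_events(
    events_path: str | Path,
    display_path: Optional[str | Path] = None,
    width: float = 1000.0,
    height: float = 1000.0,
) -> Dataset:
    """Read and validate the two-file CSV schema into a :class:`Dataset`."""
    events_path = Path(events_path)
    if display_path is None:
        display_path = events_path.with_name(events_path.stem + "_display.csv")
    display_path = Path(display_path)

    ev = pd.read_csv(
        events_path, dtype={"participant_id": str}, float_precision="round_trip"
    )
    missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
    if missing:
        raise ValueError(f"{events_path}: missing columns {missing}")
    disp = pd.read_csv(
        display_path, dtype={"participant_id": str}, float_precision="round_trip"
    )
    missing = [c for c in DISPLAY_COLUMNS if c not in disp.columns]
    if missing:
        raise ValueError(f"{display_path}: missing columns {missing}")

    from .model import DIFFICULTIES, RATIOS  # local to avoid polluting namespace

    bad = ev[~ev["difficulty"].isin(DIFFICULTIES)]
    if len(bad):
        _fail(events_path, int(bad.index[0]), f"unknown difficulty {bad['difficulty'].iloc[0]!r}")
    bad = ev[~ev["ratio_condition"].isin(RATIOS)]
    if len(bad):
        _fail(
            events_path, int(bad.index[0]), f"unknown ratio {bad['ratio_condition'].iloc[0]!r}"
        )
    dup = ev.duplicated(["participant_id", "trial", "attempt", "select_index"])
    if dup.any():
        _fail(events_path, int(ev.index[dup][0]), "repeated (participant, trial, select_index)")

    displays: Dict[Tuple[str, int], TrialDisplay] = {}
    for (pid, trial), g in disp.groupby(["participant_id", "trial"], sort=False):
        items = tuple(
            Item(
                item_id=int(r.item_id),
                x=float(r.x),
                y=float(r.y),
                item_class=str(r.item_class),
                is_target=bool(int(r.is_target)),
            )
            for r in g.itertuples()
        )
        displays[(str(pid), int(trial))] = TrialDisplay(items=items, width=width, height=height)

    trials: List[TrialRecord] = []
    group_cols = ["participant_id", "block", "trial", "attempt"]
    for (pid, block, trial, attempt), g in ev.groupby(group_cols, sort=True):
        g = g.sort_values("select_index")
        sel = g["select_index"].to_numpy()
        if not (sel == range(len(sel))).all():
            _fail(events_path, int(g.index[0]), "select_index not consecutive from 0")
        cond = ConditionKey(str(g["difficulty"].iloc[0]), str(g["ratio_condition"].iloc[0]))
        key = (str(pid), int(trial))
        if key not in displays:
            _fail(events_path, int(g.index[0]), f"no display rows for participant/trial {key}")
        display = replace(displays[key], condition=cond)
        has_times = g["t_sec"].notna().all()
        times = tuple(float(v) for v in g["t_sec"]) if has_times else None
        seq = SelectionSequence(
            selected_ids=tuple(int(v) for v in g["item_id"]), times=times
        )
        trials.append(
            TrialRecord(
                participant_id=str(pid),
                condition=cond,
                block=int(block),
                trial=int(trial),
                attempt=int(attempt),
                terminated=bool(int(g["terminated"].iloc[0])),
                display=display,
                sequence=seq,
            )
        )
    return Dataset(trials=trials)


def apply_exclusions(
    dataset: Dataset,
    max_gap_s: float = 5.0,
    min_trials: int = 5,
) -> Tuple[Dataset, ExclusionReport]:
    """Apply the pre-registered exclusion rules.

    1. attempts terminated by a distractor click are removed;
    2. any trial containing an inter-target selection time greater than
       ``max_gap_s`` seconds is removed (the first selection's gap is
       measured from trial onset, i.e. it equals its timestamp);
    3. participants left with fewer than ``min_trials`` valid trials in any
       condition of the dataset are dropped entirely.

    The returned report reconciles every removal; the operation is
    idempotent.
    """
    report = ExclusionReport()
    survivors: List[TrialRecord] = []
    for t in dataset.trials:
        if t.terminated:
            report.n_terminated_removed += 1
            continue
        if math.isfinite(max_gap_s):
            times = t.sequence.times
            if times is None:
                raise ValueError(
                    f"trial {t.participant_id}/{t.trial} has no timestamps; "
                    "timing exclusion requires them (use max_gap_s=inf to skip)"
                )
            gaps = [times[0]] + [b - a for a, b in zip(times, times[1:])]
            if any(g > max_gap_s for g in gaps):
                report.n_trials_removed_by_timing += 1
                continue
        survivors.append(t)

    conditions = dataset.conditions
    counts: Dict[Tuple[str, ConditionKey], int] = {}
    for t in survivors:
        counts[(t.participant_id, t.condition)] = counts.get((t.participant_id, t.condition), 0) + 1
    dropped = sorted(
        pid
        for pid in {t.participant_id for t in survivors}
        if any(counts.get((pid, c), 0) < min_trials for c in conditions)
    )
    report.participants_dropped = dropped
    kept = [t for t in survivors if t.participant_id not in dropped]
    report.n_removed_with_dropped_participants = len(survivors) - len(kept)
    for t in kept:
        key = str(t.condition)
        report.valid_trials_per_condition[key] = (
            report.valid_trials_per_condition.get(key, 0) + 1
        )

    out = Dataset(
        trials=kept,
        provenance=dataset.provenance,
        generating=dataset.generating,
        true_participant_params=dataset.true_participant_params,
    )
    return out, report


def filter_half(dataset: Dataset, half: str) -> Dataset:
    """Keep the first or second half of each participant-condition's trials.

    Trials are ordered by (block, trial); for odd counts the extra trial
    goes to the first half.
    """
    if half not in ("first", "second"):
        raise ValueError("half must be 'first' or 'second'")
    keep: List[TrialRecord] = []
    by_cell: Dict[Tuple[str, ConditionKey], List[TrialRecord]] = {}
    for t in dataset.trials:
        by_cell.setdefault((t.participant_id, t.condition), []).append(t)
    for cell in by_cell.values():
        cell.sort(key=lambda t: (t.block, t.trial, t.attempt))
        cut = (len(cell) + 1) // 2
        keep.extend(cell[:cut] if half == "first" else cell[cut:])
    return dataset.subset(keep)
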