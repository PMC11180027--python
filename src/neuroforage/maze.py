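"""Radial-arm-maze event coding.

A trial is a time-ordered sequence of behavioural events recorded while a
rat forages on an eight-arm radial maze whose arms 1, 2, 4 and 7 are baited
with a sucrose pellet. Every arm entry receives exactly one of five labels:

* ``PE``  — pellet eaten: first visit to a baited arm, pellet consumed.
* ``PO``  — pellet omission: first visit to a baited arm, pellet left.
* ``WME`` — working memory error: re-entry into a baited arm.
* ``RME`` — reference memory error: first entry into an unbaited arm.
* ``HME`` — hybrid memory error: re-entry into an unbaited arm; it counts
  toward both the working and the reference memory tallies.

Affective endpoints (time in the central atrium, time at the end of an arm,
nose pokes, stretch-attend postures, grooming, rearing, climbing) are
aggregated per trial, and every measure is additionally normalised per arm
entry because trial-level activity differs widely between rats.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "MazeConfig",
    "BehaviouralEvent",
    "TrialRecord",
    "EntryLabel",
    "VisitHistory",
    "TrialSummary",
    "EventGrammarError",
    "classify_entry",
    "code_trial",
    "read_event_log",
    "write_event_log",
    "write_summaries",
    "read_summaries",
    "summaries_to_frame",
]

EVENT_TYPES = frozenset(
    {
        "arm_entry",
        "atrium_dwell",
        "nose_poke",
        "stretch_attend",
        "groom",
        "rear",
        "climb",
        "end_of_arm_dwell",
    }
)

#: event types that reference an arm
ARM_EVENTS = frozenset({"arm_entry", "nose_poke", "stretch_attend", "end_of_arm_dwell"})

#: counted (frequency) measures and timed (duration) measures
COUNT_MEASURES = ("pe", "po", "wme_label", "rme_label", "hme_label",
                  "wme_total", "rme_total", "nose_pokes", "saps", "total_entries")
DURATION_MEASURES = ("tica", "tieoa", "groom", "rear", "climb")


class EventGrammarError(ValueError):
    """Raised when an event sequence violates the trial grammar."""


@dataclass(frozen=True)
class MazeConfig:
    """Geometry and timing of the radial-arm maze task."""

    n_arms: int = 8
    baited_arms: frozenset[int] = frozenset({1, 2, 4, 7})
    trial_duration_s: float = 300.0
    #: a re-entry into a baited arm is a WME regardless of whether the pellet
    #: is still present; setting this False lets a revisit that consumes a
    #: previously-omitted pellet count as PE instead.
    revisit_always_wme: bool = True

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("n_arms must be positive")
        object.__setattr__(self, "baited_arms", frozenset(self.baited_arms))
        if not self.baited_arms <= set(range(1, self.n_arms + 1)):
            raise ValueError("baited_arms must be a subset of 1..n_arms")
        if self.trial_duration_s <= 0:
            raise ValueError("trial_duration_s must be positive")


class EntryLabel(str, Enum):
    PE = "PE"
    PO = "PO"
    WME = "WME"
    RME = "RME"
    HME = "HME"


@dataclass(frozen=True)
class BehaviouralEvent:
    event_type: str
    t_start_s: float
    duration_s: float
    arm: int | None = None
    pellet_eaten: bool = False

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise EventGrammarError(f"unknown event type {self.event_type!r}")
        if self.duration_s < 0:
            raise EventGrammarError("duration_s must be >= 0")
        if (self.arm is not None) != (self.event_type in ARM_EVENTS):
            raise EventGrammarError(
                f"event {self.event_type!r} must reference an arm iff it is an arm event"
            )


@dataclass(frozen=True)
class TrialRecord:
    rat_id: str
    group: str
    day: int
    events: tuple[BehaviouralEvent, ...]

    def validate(self, config: MazeConfig) -> None:
        """Check time ordering, non-overlap and arm range; raise listing rows."""
        bad: list[str] = []
        t_prev_end = 0.0
        for i, ev in enumerate(self.events):
            if ev.arm is not None and not (1 <= ev.arm <= config.n_arms):
                bad.append(f"event {i}: arm {ev.arm} outside 1..{config.n_arms}")
            # tolerance absorbs CSV round-trip quantisation (6 decimals)
            if ev.t_start_s + 1e-4 < t_prev_end:
                bad.append(f"event {i}: starts at {ev.t_start_s:.3f}s before "
                           f"previous event ended at {t_prev_end:.3f}s")
            t_prev_end = max(t_prev_end, ev.t_start_s + ev.duration_s)
        if bad:
            raise EventGrammarError(
                f"trial {self.rat_id} day {self.day}: " + "; ".join(bad)
            )


@dataclass
class VisitHistory:
    """Per-arm state accumulated over the entries of one trial."""

    visits: dict[int, int] = field(default_factory=dict)
    pellet_taken: set[int] = field(default_factory=set)

    def record(self, arm: int, ate: bool) -> None:
        self.visits[arm] = self.visits.get(arm, 0) + 1
        if ate:
            self.pellet_taken.add(arm)


def classify_entry(
    arm: int,
    history: VisitHistory,
    config: MazeConfig,
    pellet_eaten: bool = False,
) -> EntryLabel:
    """Label one arm entry and update the visit history.

    Decision order: unbaited & first visit -> RME; unbaited & revisit -> HME;
    baited & revisit -> WME; baited & first visit -> PE if the pellet was
    eaten else PO.
    """
    if not 1 <= arm <= config.n_arms:
        raise ValueError(f"arm {arm} outside 1..{config.n_arms}")
    first_visit = history.visits.get(arm, 0) == 0
    baited = arm in config.baited_arms
    if not baited:
        label = EntryLabel.RME if first_visit else EntryLabel.HME
    elif not first_visit:
        if config.revisit_always_wme or arm in history.pellet_taken:
            label = EntryLabel.WME
        else:
            label = EntryLabel.PE if pellet_eaten else EntryLabel.WME
    else:
        label = EntryLabel.PE if pellet_eaten else EntryLabel.PO
    history.record(arm, pellet_eaten and baited)
    return label


@dataclass(frozen=True)
class TrialSummary:
    """All per-trial endpoints, raw and per-entry-normalised.

    ``normalised`` maps measure name -> value / total_entries and is empty
    (with ``normalised_defined`` False) for trials without any arm entry.
    """

    rat_id: str
    group: str
    day: int
    counts: dict[str, int]
    durations_s: dict[str, float]
    normalised: dict[str, float]
    normalised_defined: bool
    trial_duration_s: float

    @property
    def total_entries(self) -> int:
        return self.counts["total_entries"]


def code_trial(trial: TrialRecord, config: MazeConfig | None = None) -> TrialSummary:
    """Aggregate a trial's events into a :class:`TrialSummary`."""
    config = config or MazeConfig()
    trial.validate(config)

    history = VisitHistory()
    counts = {m: 0 for m in COUNT_MEASURES}
    durations = {m: 0.0 for m in DURATION_MEASURES}
    duration_of = {
        "atrium_dwell": "tica",
        "end_of_arm_dwell": "tieoa",
        "groom": "groom",
        "rear": "rear",
        "climb": "climb",
    }
    t_end = 0.0
    for ev in trial.events:
        t_end = max(t_end, ev.t_start_s + ev.duration_s)
        if ev.event_type == "arm_entry":
            label = classify_entry(ev.arm, history, config, ev.pellet_eaten)
            counts[label.value.lower() + "_label" if label in
                   (EntryLabel.WME, EntryLabel.RME, EntryLabel.HME)
                   else label.value.lower()] += 1
            counts["total_entries"] += 1
        elif ev.event_type == "nose_poke":
            counts["nose_pokes"] += 1
        elif ev.event_type == "stretch_attend":
            counts["saps"] += 1
        elif ev.event_type in duration_of:
            durations[duration_of[ev.event_type]] += ev.duration_s
    counts["wme_total"] = counts["wme_label"] + counts["hme_label"]
    counts["rme_total"] = counts["rme_label"] + counts["hme_label"]

    n = counts["total_entries"]
    if n > 0:
        normalised = {
            **{f"{k}_per_entry": v / n for k, v in durations.items()},
            **{f"{k}_per_entry": v / n for k, v in counts.items()
               if k != "total_entries"},
        }
        defined = True
    else:
        normalised, defined = {}, False
    return TrialSummary(
        rat_id=trial.rat_id,
        group=trial.group,
        day=trial.day,
        counts=counts,
        durations_s=durations,
        normalised=normalised,
        normalised_defined=defined,
        trial_duration_s=t_end,
    )


# ---------------------------------------------------------------------------
# event-log / summary IO (tidy CSV, one row per event)

_LOG_COLUMNS = ["rat_id", "group", "day", "event_type", "arm",
                "t_start_s", "duration_s", "pellet_eaten"]


def write_event_log(trials: Iterable[TrialRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_LOG_COLUMNS)
        for tr in trials:
            for ev in tr.events:
                w.writerow([
                    tr.rat_id, tr.group, tr.day, ev.event_type,
                    "" if ev.arm is None else ev.arm,
                    repr(ev.t_start_s), repr(ev.duration_s),
                    int(ev.pellet_eaten),
                ])


def read_event_log(path, config: MazeConfig | None = None) -> list[TrialRecord]:
    """Parse a tidy event-log CSV into trials, reporting bad rows by number."""
    config = config or MazeConfig()
    trials: dict[tuple[str, int], list] = {}
    meta: dict[tuple[str, int], str] = {}
    errors: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(_LOG_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise EventGrammarError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                arm = row["arm"].strip()
                ev = BehaviouralEvent(
                    event_type=row["event_type"],
                    arm=int(arm) if arm else None,
                    t_start_s=float(row["t_start_s"]),
                    duration_s=float(row["duration_s"]),
                    pellet_eaten=bool(int(row["pellet_eaten"] or 0)),
                )
                if ev.arm is not None and not (1 <= ev.arm <= config.n_arms):
                    raise EventGrammarError(
                        f"arm {ev.arm} outside 1..{config.n_arms}")
                key = (row["rat_id"], int(row["day"]))
                trials.setdefault(key, []).append(ev)
                meta[key] = row["group"]
            except (EventGrammarError, ValueError, KeyError) as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise EventGrammarError(f"{path}: " + "; ".join(errors))
    out = [
        TrialRecord(rat_id=rat, group=meta[(rat, day)], day=day,
                    events=tuple(evs))
        for (rat, day), evs in sorted(trials.items())
    ]
    for tr in out:
        tr.validate(config)
    return out


def summaries_to_frame(summaries: Sequence[TrialSummary]) -> pd.DataFrame:
    """One row per rat-day with all raw and normalised measures."""
    rows = []
    for s in summaries:
        row: dict = {"rat_id": s.rat_id, "group": s.group, "day": s.day,
                     "trial_duration_s": s.trial_duration_s,
                     "normalised_defined": s.normalised_defined}
        row.update(s.counts)
        row.update({k: v for k, v in s.durations_s.items()})
        for k in [f"{m}_per_entry" for m in DURATION_MEASURES] + [
                f"{m}_per_entry" for m in COUNT_MEASURES if m != "total_entries"]:
            row[k] = s.normalised.get(k, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_summaries(summaries: Sequence[TrialSummary], path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


def read_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path)
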