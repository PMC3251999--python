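"""Executable rule engine for high-level activity inference.

Low-level activity events (from video, wearable and motion sensors) are
matched against a catalog of known activities; out-of-catalog events are
diverted to an *unknown log* (kept, never silently dropped — e.g.
locking/unlocking a bathroom door typically shows up as an unknown
activity flanking "taking a bath").  Known events then flow through a
small set of expert rules that emit reminders, device commands and
high-level activities:

* Rule 1 — at least two distinct motion contents (bending, jacking,
  jumping, running, skipping, siding, walking, waving) by one person
  within a session window  =>  high-level activity "Exercise".
* Rule 2 — an eating event with no taking-medicine event earlier that
  day  =>  reminder "take medicine".
* Rule 3 — a reading event while the TV is on  =>  turnOff(TV).
* Rule 4 — an unknown activity with no successor event within a
  timeout  =>  reminder "movements are wrong".
* Rule 5 — entering the kitchen or bedroom  =>  turnOn(lights).

A per-day knowledge base gates obligations so replaying a stream never
doubles a reminder; day flags reset at local midnight.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import datetime, timedelta

from .errors import ContractError

__all__ = [
    "ActivityEvent",
    "ActivityCatalog",
    "DEFAULT_CATALOG",
    "MOTION_CONTENTS",
    "KnowledgeBase",
    "Decision",
    "RuleConfig",
    "filter_unknown",
    "apply_rules",
    "match_activities",
    "evaluate_matchmaking",
    "MatchScore",
]


def _norm(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


@dataclass(frozen=True)
class ActivityEvent:
    """One timestamped low-level activity."""

    id: str
    name: str
    type: str
    time: datetime
    person: str
    location: str = ""
    consequent_action: str | None = None


#: Motion contents that count toward Rule 1's exercise session.
MOTION_CONTENTS = frozenset(
    ["bending", "jacking", "jumping", "running", "skipping", "siding",
     "walking", "waving"]
)

#: Default 18-activity catalog: every low-level activity the engine's
#: rules and upstream recognizers name; configurable per deployment.
DEFAULT_CATALOG = (
    "walking", "bending", "jacking", "jumping", "running", "skipping",
    "siding", "waving", "eating", "having tea", "reading",
    "taking medicine", "tooth brushing", "sitting", "watching tv",
    "entering kitchen", "entering bedroom", "exercising",
)


@dataclass(frozen=True)
class ActivityCatalog:
    """The set of expected (recognizable) activity names."""

    known: frozenset = frozenset(DEFAULT_CATALOG)

    def __post_init__(self):
        if not self.known:
            raise ContractError("the activity catalog must be non-empty")
        object.__setattr__(self, "known", frozenset(_norm(n) for n in self.known))

    def __contains__(self, name: str) -> bool:
        return _norm(name) in self.known


@dataclass
class _DayFlags:
    medicine_taken: bool = False
    medicine_reminded: bool = False
    exercised: bool = False


@dataclass
class KnowledgeBase:
    """Mutable state the rules consult: per-day obligation flags, device
    states and the event history."""

    tv_on: bool = False
    lights_on: dict = dc_field(default_factory=dict)  # room -> bool
    history: list = dc_field(default_factory=list)
    _day_flags: dict = dc_field(default_factory=dict)  # (date, person) -> _DayFlags

    def day(self, event: ActivityEvent) -> _DayFlags:
        key = (event.time.date(), event.person)
        if key not in self._day_flags:
            self._day_flags[key] = _DayFlags()
        return self._day_flags[key]


@dataclass(frozen=True)
class Decision:
    """An emitted outcome: a reminder, a device command, or a high-level
    activity, with the ids of the events that triggered it."""

    kind: str  # reminder | device_command | high_level_activity
    payload: str
    triggers: tuple
    time: datetime


@dataclass
class RuleConfig:
    """Rule parameters: Rule 1 session window, Rule 4 successor timeout,
    and which rules run."""

    session_window: timedelta = timedelta(minutes=30)
    rule4_timeout: timedelta = timedelta(minutes=5)
    enabled: frozenset = frozenset({1, 2, 3, 4, 5})


def filter_unknown(events, catalog: ActivityCatalog | None = None):
    """Split a stream into (known, unknown-log); conserves every event."""
    catalog = catalog or ActivityCatalog()
    known, unknown = [], []
    for ev in events:
        (known if ev.name in catalog else unknown).append(ev)
    return known, unknown


def _check_sorted(events):
    for a, b in zip(events, events[1:]):
        if b.time < a.time:
            raise ContractError("event stream must be time-sorted")


def apply_rules(events, kb: KnowledgeBase | None = None,
                config: RuleConfig | None = None,
                catalog: ActivityCatalog | None = None) -> list[Decision]:
    """Run Rules 1–5 over a time-sorted event stream.

    Unknown-named events participate only in Rule 4; device/obligation
    state lives in ``kb`` and persists across calls, so satisfied
    obligations never re-fire (the knowledge base is updated to avoid
    further reminders).
    """
    events = list(events)
    _check_sorted(events)
    kb = kb if kb is not None else KnowledgeBase()
    config = config or RuleConfig()
    catalog = catalog or ActivityCatalog()
    decisions: list[Decision] = []
    session: dict = {}  # person -> list of recent motion events

    for i, ev in enumerate(events):
        name = _norm(ev.name)
        known = ev.name in catalog
        kb.history.append(ev)
        flags = kb.day(ev)

        if not known:
            if 4 in config.enabled:
                nxt = next((e for e in events[i + 1 :] if e.person == ev.person), None)
                if nxt is None or nxt.time - ev.time > config.rule4_timeout:
                    decisions.append(Decision(
                        kind="reminder", payload="movements are wrong",
                        triggers=(ev.id,), time=ev.time + config.rule4_timeout,
                    ))
            continue

        # state updates from known events
        if name == "watching tv":
            kb.tv_on = True
        if name == "taking medicine":
            flags.medicine_taken = True

        # Rule 5: entering kitchen/bedroom -> lights on in that room
        if 5 in config.enabled and name in ("entering kitchen", "entering bedroom"):
            room = name.split()[-1]
            if not kb.lights_on.get(room, False):
                kb.lights_on[room] = True
                decisions.append(Decision(
                    kind="device_command", payload=f"turnOn(lights:{room})",
                    triggers=(ev.id,), time=ev.time,
                ))

        # Rule 2: eating without medicine taken earlier that day
        if 2 in config.enabled and name == "eating":
            if not flags.medicine_taken and not flags.medicine_reminded:
                flags.medicine_reminded = True
                decisions.append(Decision(
                    kind="reminder", payload="take medicine",
                    triggers=(ev.id,), time=ev.time,
                ))

        # Rule 3: reading while the TV is on
        if 3 in config.enabled and name == "reading" and kb.tv_on:
            kb.tv_on = False
            decisions.append(Decision(
                kind="device_command", payload="turnOff(TV)",
                triggers=(ev.id,), time=ev.time,
            ))

        # Rule 1: >= 2 distinct motion contents by one person in a session
        if 1 in config.enabled and name in MOTION_CONTENTS:
            recent = [e for e in session.get(ev.person, [])
                      if ev.time - e.time <= config.session_window]
            recent.append(ev)
            session[ev.person] = recent
            distinct = {_norm(e.name) for e in recent}
            if len(distinct) >= 2 and not flags.exercised:
                flags.exercised = True
                decisions.append(Decision(
                    kind="high_level_activity", payload="Exercise",
                    triggers=tuple(e.id for e in recent), time=ev.time,
                ))
    return decisions


def match_activities(predicted, truth, tolerance: timedelta = timedelta(seconds=60)):
    """Greedy earliest-first 1-to-1 matching by name equality and
    ``|Δtime| <= tolerance``.

    Returns ``(matched, unmatched_pred, unmatched_truth)`` with
    ``matched`` a list of (predicted, truth) pairs.  Deterministic:
    predictions are scanned in time order and each takes the earliest
    unmatched truth event of the same name within tolerance.
    """
    predicted = sorted(predicted, key=lambda e: e.time)
    truth = sorted(truth, key=lambda e: e.time)
    used = [False] * len(truth)
    matched, unmatched_pred = [], []
    for p in predicted:
        best = None
        for j, t in enumerate(truth):
            if used[j] or _norm(t.name) != _norm(p.name):
                continue
            if abs(t.time - p.time) <= tolerance:
                best = j
                break
        if best is None:
            unmatched_pred.append(p)
        else:
            used[best] = True
            matched.append((p, truth[best]))
    unmatched_truth = [t for t, u in zip(truth, used) if not u]
    return matched, unmatched_pred, unmatched_truth


@dataclass(frozen=True)
class MatchScore:
    precision: float
    recall: float
    precision_defined: bool = True
    recall_defined: bool = True


def evaluate_matchmaking(matched, unmatched_pred, unmatched_truth) -> MatchScore:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN).

    An empty denominator is reported as 1.0 with the corresponding
    ``*_defined`` flag set to False.
    """
    tp = len(matched)
    fp = len(unmatched_pred)
    fn = len(unmatched_truth)
    if tp + fp:
        precision, p_def = tp / (tp + fp), True
    else:
        precision, p_def = 1.0, False
    if tp + fn:
        recall, r_def = tp / (tp + fn), True
    else:
        recall, r_def = 1.0, False
    return MatchScore(precision, recall, p_def, r_def)
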