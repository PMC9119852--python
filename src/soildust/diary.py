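"""Synthetic 24-hour activity diaries.

Stands in for a time-activity diary database: each diary is a contiguous
sequence of timed events covering exactly 24 h, with events no shorter
than one minute and no longer than one hour (longer activity blocks are
chopped into hourly events, matching how diary surveys report sleep and
play).  A simulated person-year is the "8-diary" structure — one weekday
and one weekend diary for each of the four seasons, weighted by calendar
day counts (365/4 days per season, split 5:2 weekday:weekend).

Age-specific time budgets (sleep including naps, bathing, handwashing,
and seasonal outdoor fractions) come from the ``[diary]`` section of the
model configuration.  Children under one year are assumed to have no
ground-level contact outdoors (carried or in a stroller), so their
outdoor events are generated with ``ground_contact = False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import AGE_GROUP_INDEX, AGE_GROUPS, UNDER_ONE_YEAR

__all__ = [
    "SEASONS", "DAY_TYPES", "DiaryEvent", "Diary", "DiaryYear",
    "DiaryError", "season_of", "generate_diary", "build_diary_year",
    "read_diary_csv", "write_diary_csv",
]

SEASONS = ("winter", "spring", "summer", "fall")
DAY_TYPES = ("weekday", "weekend")
ACTIVITIES = ("sleep", "bath", "handwash", "play", "other")
LOCATIONS = ("indoor", "outdoor")

#: Days represented by each (season, day_type) diary: 365/4 per season,
#: split 5:2 across weekdays and weekend days.
DAY_WEIGHTS = {
    (s, d): (365.0 / 4.0) * (5.0 / 7.0 if d == "weekday" else 2.0 / 7.0)
    for s in SEASONS for d in DAY_TYPES
}

MINUTES_PER_DAY = 1440
MAX_EVENT_MIN = 60


class DiaryError(ValueError):
    """Invalid diary or infeasible generator time budget."""


def season_of(month: int) -> str:
    """Map a calendar month to its season (Dec-Feb winter, Mar-May spring,
    Jun-Aug summer, Sep-Nov fall)."""
    if not 1 <= int(month) <= 12:
        raise DiaryError(f"month must be in 1..12, got {month}")
    m = int(month)
    if m in (12, 1, 2):
        return "winter"
    if m in (3, 4, 5):
        return "spring"
    if m in (6, 7, 8):
        return "summer"
    return "fall"


@dataclass(frozen=True)
class DiaryEvent:
    start: int            # minutes since midnight
    duration: int         # minutes, 1..60
    location: str         # indoor / outdoor
    activity: str         # sleep / bath / handwash / play / other
    ground_contact: bool = False   # soil reachable during this event?


@dataclass
class Diary:
    """One simulated day: ordered, contiguous events covering 24 h."""

    events: list[DiaryEvent]
    age_group: str
    season: str
    day_type: str

    def total_minutes(self) -> int:
        return sum(e.duration for e in self.events)

    def validate(self) -> None:
        if self.total_minutes() != MINUTES_PER_DAY:
            raise DiaryError(
                f"diary covers {self.total_minutes()} min, expected {MINUTES_PER_DAY}")
        t = 0
        for e in self.events:
            if e.start != t:
                raise DiaryError(f"event at {e.start} not contiguous (expected {t})")
            if not 1 <= e.duration <= MAX_EVENT_MIN:
                raise DiaryError(f"event duration {e.duration} outside 1..{MAX_EVENT_MIN}")
            if e.location not in LOCATIONS or e.activity not in ACTIVITIES:
                raise DiaryError(f"bad event labels: {e}")
            t += e.duration


@dataclass
class DiaryYear:
    """The 8-diary representation of one person-year."""

    diaries: dict[tuple[str, str], Diary]
    weights: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DAY_WEIGHTS))

    def total_days(self) -> float:
        return sum(self.weights.values())


# ------------------------------------------------------------- generation --

def _chop(segments, age_group, rng):
    """Turn (activity, location, minutes, ground) segments into <=60-min events."""
    events: list[DiaryEvent] = []
    t = 0
    for activity, location, minutes, ground in segments:
        left = int(minutes)
        while left > 0:
            d = min(left, MAX_EVENT_MIN)
            # avoid a trailing sliver shorter than a minute of the next chop
            if 0 < left - d < 1:
                d = left
            events.append(DiaryEvent(t, d, location, activity, ground))
            t += d
            left -= d
    return events


def _split(total: int, n: int, rng) -> list[int]:
    """Split ``total`` minutes into ``n`` nonnegative integer chunks."""
    if n <= 0:
        return []
    w = rng.random(n) + 0.1
    raw = (w / w.sum()) * total
    chunks = [int(x) for x in raw]
    # distribute the rounding remainder
    i = 0
    while sum(chunks) < total:
        chunks[i % n] += 1
        i += 1
    return chunks


def generate_diary(age_group: str, season: str, day_type: str,
                   gen_params: dict, rng) -> Diary:
    """Generate one synthetic 24-h diary.

    ``gen_params`` is the ``[diary]`` config section (global keys plus an
    ``age`` table).  Raises :class:`DiaryError` if the requested time
    budget cannot fit into 24 h.
    """
    if age_group not in AGE_GROUP_INDEX:
        raise DiaryError(f"unknown age group {age_group!r}")
    if season not in SEASONS or day_type not in DAY_TYPES:
        raise DiaryError(f"unknown season/day type: {season}, {day_type}")
    g = gen_params["age"][age_group]

    sleep_min = int(round(g["sleep_h"] * 60))
    nap_min = int(g.get("nap_min", 0))
    bath_min = int(gen_params.get("bath_min", 12))
    hw_min = int(gen_params.get("handwash_min", 2))
    n_bath = int(round(g.get("baths_per_day", 1.0)))
    n_hw = int(rng.poisson(g.get("handwash_per_day", 2.0)))

    night_min = sleep_min - nap_min
    if night_min < 0:
        raise DiaryError("nap time exceeds total sleep budget")
    awake = MINUTES_PER_DAY - sleep_min
    fixed = n_bath * bath_min + n_hw * hw_min
    if sleep_min > MINUTES_PER_DAY or fixed > awake:
        raise DiaryError(
            f"infeasible time budget for {age_group}: sleep {sleep_min} min "
            f"+ fixed activities {fixed} min exceed 24 h")

    frac = float(g["outdoor_frac"][season])
    if day_type == "weekend":
        frac *= float(gen_params.get("weekend_outdoor_multiplier", 1.0))
    outdoor_min = int(round(min(frac, 1.0) * (awake - fixed)))
    indoor_free = awake - fixed - outdoor_min

    wake_mu = float(gen_params.get("wake_time_mean_min", 420))
    wake_sd = float(gen_params.get("wake_time_sd_min", 30))
    wake = int(min(max(rng.normal(wake_mu, wake_sd), 240), 600))
    wake = min(wake, night_min)
    evening_night = night_min - wake

    ground = AGE_GROUP_INDEX[age_group] >= len(UNDER_ONE_YEAR)

    # daytime components in chronological order; bath goes last before bed
    comps: list[tuple[str, str, int, bool]] = []
    hw_first = n_hw // 2
    comps += [("handwash", "indoor", hw_min, False)] * hw_first
    if nap_min > 0:
        comps.append(("sleep", "indoor", nap_min, False))
    if outdoor_min > 0:
        halves = _split(outdoor_min, 2 if outdoor_min > 90 else 1, rng)
        comps += [("play", "outdoor", h, ground) for h in halves if h > 0]
    comps += [("handwash", "indoor", hw_min, False)] * (n_hw - hw_first)
    comps += [("bath", "indoor", bath_min, False)] * n_bath

    fillers = _split(indoor_free, len(comps) + 1, rng)
    segments: list[tuple[str, str, int, bool]] = []
    if wake > 0:
        segments.append(("sleep", "indoor", wake, False))
    for i, comp in enumerate(comps):
        if fillers[i] > 0:
            segments.append(("play" if i % 2 == 0 else "other",
                             "indoor", fillers[i], False))
        segments.append(comp)
    if fillers[len(comps)] > 0:
        segments.append(("other", "indoor", fillers[len(comps)], False))
    if evening_night > 0:
        segments.append(("sleep", "indoor", evening_night, False))

    diary = Diary(_chop(segments, age_group, rng), age_group, season, day_type)
    diary.validate()
    return diary


def build_diary_year(age_group: str, gen_params: dict, streams) -> DiaryYear:
    """One diary per (season, day type), with calendar day-count weights."""
    diaries = {
        (s, d): generate_diary(age_group, s, d, gen_params, streams.diary(s, d))
        for s in SEASONS for d in DAY_TYPES
    }
    return DiaryYear(diaries)


# -------------------------------------------------------------------- I/O --

CSV_COLUMNS = ["start", "duration", "location", "activity", "ground_contact"]


def write_diary_csv(diary: Diary, path: str | Path) -> None:
    df = pd.DataFrame([
        {"start": e.start, "duration": e.duration, "location": e.location,
         "activity": e.activity, "ground_contact": e.ground_contact}
        for e in diary.events
    ], columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_diary_csv(path: str | Path, age_group: str,
                   season: str = "spring", day_type: str = "weekday") -> Diary:
    """Read a pre-tabulated diary so external diary extracts can be used."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise DiaryError(f"diary CSV missing columns: {missing}")
    if "ground_contact" not in df.columns:
        df["ground_contact"] = False
    events = [
        DiaryEvent(int(r.start), int(r.duration), str(r.location),
                   str(r.activity), bool(r.ground_contact))
        for r in df.itertuples()
    ]
    diary = Diary(events, age_group, season, day_type)
    diary.validate()
    return diary
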