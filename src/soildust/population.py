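"""Population runs and summary statistics.

Simulates ``n_persons`` children of one age group, each for a full
simulated year via the 8-diary structure, and summarizes annual and
seasonal average daily ingestion (mg/day) with the six population
statistics used for exposure distributions: mean, SD, geometric mean,
geometric SD, median, and the empirical 95th percentile.

Annual averages are the day-count-weighted means over the eight diaries;
seasonal averages weight the season's weekday and weekend diaries 5:2.
Geometric statistics are computed over strictly positive values, with the
count of zeros reported alongside (soil ingestion is exactly zero for
children whose diaries never put them on outdoor ground).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ModelConfig, draw_person_params
from .diary import DAY_WEIGHTS, SEASONS, build_diary_year
from .engine import simulate_person_day
from .rng import PersonStreams

__all__ = ["run_age_group", "summarize", "PERIODS", "VALUE_COLUMNS"]

PERIODS = ("annual",) + SEASONS

#: Per-day ingestion columns carried through the person records, mg/day.
VALUE_COLUMNS = (
    "hand_mouth_dust", "hand_mouth_soil",
    "object_mouth_dust", "object_mouth_soil",
    "pacifier_dust", "pacifier_soil",
    "dust", "soil", "total",
)


def _day_record(ledger) -> dict[str, float]:
    d = ledger.daily_mg()
    rec = {
        "hand_mouth_dust": d[("hand_mouth", "dust")],
        "hand_mouth_soil": d[("hand_mouth", "soil")],
        "object_mouth_dust": d[("object_mouth", "dust")],
        "object_mouth_soil": d[("object_mouth", "soil")],
        "pacifier_dust": d[("pacifier", "dust")],
        "pacifier_soil": d[("pacifier", "soil")],
    }
    rec["dust"] = rec["hand_mouth_dust"] + rec["object_mouth_dust"] + rec["pacifier_dust"]
    rec["soil"] = rec["hand_mouth_soil"] + rec["object_mouth_soil"] + rec["pacifier_soil"]
    rec["total"] = rec["dust"] + rec["soil"]
    return rec


def run_age_group(age_group: str, n_persons: int, config: ModelConfig,
                  master_seed: int) -> pd.DataFrame:
    """Simulate one age group's population for one year per person.

    Returns a tidy frame with one row per person per period ("annual" plus
    the four seasons) and the mg/day columns in :data:`VALUE_COLUMNS`.
    Runs are reproducible: the same ``master_seed`` yields identical
    output, and every person's draws come from independent substreams.
    """
    rows: list[dict] = []
    for p in range(int(n_persons)):
        streams = PersonStreams(master_seed, age_group, p)
        person = draw_person_params(age_group, config, streams)
        year = build_diary_year(age_group, config.diary, streams)

        day_recs: dict[tuple[str, str], dict[str, float]] = {}
        for (season, day_type), diary in year.diaries.items():
            ledger = simulate_person_day(
                diary, person, streams.engine(season, day_type),
                var_rng=streams.var, record_events=False)
            day_recs[(season, day_type)] = _day_record(ledger)

        total_days = sum(year.weights.values())
        annual = {"person": p, "period": "annual"}
        for col in VALUE_COLUMNS:
            annual[col] = sum(year.weights[k] * day_recs[k][col]
                              for k in day_recs) / total_days
        rows.append(annual)
        for season in SEASONS:
            wk = year.weights[(season, "weekday")]
            we = year.weights[(season, "weekend")]
            rec = {"person": p, "period": season}
            for col in VALUE_COLUMNS:
                rec[col] = (wk * day_recs[(season, "weekday")][col]
                            + we * day_recs[(season, "weekend")][col]) / (wk + we)
            rows.append(rec)

    df = pd.DataFrame(rows)
    df.insert(0, "age_group", age_group)
    return df


def _stats(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    pos = x[x > 0]
    out = {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "median": float(np.median(x)),
        "p95": float(np.quantile(x, 0.95)),  # linear interpolation
        "n": int(x.size),
        "n_zero": int(x.size - pos.size),
    }
    if pos.size:
        logs = np.log(pos)
        out["gm"] = float(np.exp(np.mean(logs)))
        out["gsd"] = float(np.exp(np.std(logs, ddof=1))) if pos.size > 1 else 1.0
    else:
        out["gm"] = 0.0
        out["gsd"] = float("nan")
    return out


def summarize(records: pd.DataFrame,
              media: tuple[str, ...] = ("total", "dust", "soil")) -> pd.DataFrame:
    """Six population statistics per (age group, period, medium).

    GM and GSD are computed over strictly positive values; ``n_zero``
    reports how many records were exactly zero.
    """
    if records.empty:
        raise ValueError("summarize requires at least one person record")
    rows = []
    for (age, period), grp in records.groupby(["age_group", "period"], sort=False):
        for medium in media:
            row = {"age_group": age, "period": period, "medium": medium}
            row.update(_stats(grp[medium].to_numpy()))
            rows.append(row)
    cols = ["age_group", "period", "medium",
            "mean", "sd", "gm", "gsd", "median", "p95", "n", "n_zero"]
    return pd.DataFrame(rows)[cols]
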