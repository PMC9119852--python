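"""Sensitivity analyses.

Two complementary designs:

* **One-at-a-time (OAT) ratios.**  A deterministic base run fixes every
  input at the median of its distribution (probability-valued inputs enter
  multiplicatively in expectation, since the median of a Bernoulli check
  would be degenerate) on a fixed reference diary.  Each variable is then
  moved alone to a low-exposure and a high-exposure setting (by default its
  5th and 95th percentiles, oriented so "high" increases exposure) and the
  influence is reported as the high/low exposure ratio, classified as:
  most sensitive (> 2), marginally sensitive (1.5-2], least sensitive
  (1.1-1.5], not sensitive (<= 1.1).

* **Distribution-shift scenarios.**  A named variable's distribution is
  replaced wholesale (e.g. pacifier washing from never-washed to a uniform
  with mean 0.10) and the full stochastic population is rerun with common
  random numbers; the result is the percent change in mean daily ingestion
  relative to the base run.  Because every (person, variable) pair has its
  own random substream, all draws other than the shifted variable's are
  bit-identical between base and scenario, so the paired comparison has
  far smaller variance than independent reruns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (AGE_GROUP_INDEX, ModelConfig, PACIFIER_AGE_GROUPS,
                     REQUIRED_VARS, UNDER_ONE_YEAR)
from .diary import Diary, DiaryEvent, MINUTES_PER_DAY
from .distributions import DistributionSpec
from .engine import OBJECT_MOUTH_PACIFIER_ADJUST, SOIL_PACIFIER_AGE
from .population import run_age_group

__all__ = [
    "SensitivityRow", "TABLE_OAT_VARS", "classify_ratio", "median_values",
    "reference_diary", "expected_day", "base_run_at_medians", "oat_ratio",
    "oat_table", "distribution_shift_run", "ShiftResult",
]

#: Variables screened in the OAT table for the infant dust scenario.
TABLE_OAT_VARS = (
    "dust_home_soft", "pacifier_drop", "p_blanket", "pacifier_transfer",
    "p_pacifier", "pacifier_frac_soft", "p_home_soft", "pacifier_size",
    "f_blanket",
)


@dataclass(frozen=True)
class SensitivityRow:
    variable: str
    low_exposure_value: float    # mg/day at the low-exposure setting
    high_exposure_value: float   # mg/day at the high-exposure setting
    ratio: float                 # high / low, >= 1 by construction
    sensitivity: str             # most / marginal / least / not

    @property
    def sensitivity_class(self) -> str:
        return self.sensitivity


def classify_ratio(ratio: float) -> str:
    """Classification bands partitioning [1, inf)."""
    if ratio > 2.0:
        return "most"
    if ratio > 1.5:
        return "marginal"
    if ratio > 1.1:
        return "least"
    return "not"


def median_values(age_group: str, config: ModelConfig,
                  overrides: dict[str, float] | None = None) -> dict[str, float]:
    """Every variable at the analytical median of its (truncated)
    distribution, with optional point overrides."""
    vals = {v: config.spec(age_group, v).median() for v in REQUIRED_VARS}
    if overrides:
        vals.update(overrides)
    return vals


def reference_diary(age_group: str, config: ModelConfig | None = None) -> Diary:
    """A fixed deterministic day for OAT runs.

    Sleep at the age group's budget, hourly indoor awake events, and —
    for ages with soil contact — one outdoor ground-contact hour.
    """
    sleep_h = 14 if AGE_GROUP_INDEX[age_group] < 5 else 10
    awake_min = MINUTES_PER_DAY - sleep_h * 60
    outdoor = age_group not in UNDER_ONE_YEAR
    events = [DiaryEvent(0, 60, "indoor", "sleep")]
    t = 60
    while t < sleep_h * 60:
        events.append(DiaryEvent(t, 60, "indoor", "sleep"))
        t += 60
    hours = awake_min // 60
    for h in range(hours):
        if outdoor and h == hours // 2:
            events.append(DiaryEvent(t, 60, "outdoor", "play", True))
        else:
            events.append(DiaryEvent(t, 60, "indoor", "play"))
        t += 60
    if t < MINUTES_PER_DAY:
        events.append(DiaryEvent(t, MINUTES_PER_DAY - t, "indoor", "other"))
    d = Diary(events, age_group, "spring", "weekday")
    d.validate()
    return d


def expected_day(values: dict[str, float], diary: Diary,
                 age_group: str) -> dict[str, float]:
    """Deterministic expected daily ingestion (mg/day) by pathway/medium.

    Evaluates the engine's event chain in expectation: Bernoulli checks
    enter as probability weights, mouthing counts as frequency x duration,
    and the carpet/bare and soft/hard mixtures as probability-weighted
    averages.  Hand loadings evolve deterministically through the day.
    """
    v = values
    under1 = age_group in UNDER_ONE_YEAR
    pac_adjust = age_group in PACIFIER_AGE_GROUPS

    blanket_factor = 1.0 - v["p_blanket"] * (1.0 - v["f_blanket"])
    p_soft = v["p_home_soft"]
    loading_mix = p_soft * v["dust_home_soft"] + (1.0 - p_soft) * v["dust_home_hard"]
    # E[pacifier_frac x loading] couples the floor-type coin to both factors
    frac_loading_mix = (p_soft * v["pacifier_frac_soft"] * v["dust_home_soft"]
                        + (1.0 - p_soft) * v["pacifier_frac_hard"] * v["dust_home_hard"])
    adher_ug = v["adherence_soil"] * 1000.0

    hand_d = 0.0
    hand_s = 0.0
    out = {"hand_mouth_dust": 0.0, "hand_mouth_soil": 0.0,
           "object_mouth_dust": 0.0, "object_mouth_soil": 0.0,
           "pacifier_dust": 0.0, "pacifier_soil": 0.0}

    for ev in diary.events:
        if ev.activity == "sleep":
            continue
        if ev.activity == "bath":
            hand_d *= 1.0 - v["bath_removal"]
            hand_s *= 1.0 - v["bath_removal"]
            continue
        if ev.activity == "handwash":
            hand_d *= 1.0 - v["handwash_removal"]
            hand_s *= 1.0 - v["handwash_removal"]
            continue
        dur_h = ev.duration / 60.0
        indoor = ev.location == "indoor"

        if indoor:
            target = loading_mix * blanket_factor * v["dust_transfer_hand"]
            if target > hand_d:
                hand_d += (target - hand_d) * v["hand_contact_fraction"]
        elif ev.ground_contact and not under1:
            hand_s = max(hand_s, adher_ug)

        n_hm = v["hand_mouth_freq"] * dur_h
        r = v["hand_mouth_fraction"] * v["saliva_removal"]
        if r > 0.0 and n_hm > 0.0:
            removed = 1.0 - (1.0 - r) ** n_hm
            out["hand_mouth_dust"] += hand_d * v["hand_surface_area"] * removed
            out["hand_mouth_soil"] += hand_s * v["hand_surface_area"] * removed
            hand_d *= 1.0 - removed
            hand_s *= 1.0 - removed

        om_freq = v["object_mouth_freq_indoor" if indoor else "object_mouth_freq_outdoor"]
        adj = OBJECT_MOUTH_PACIFIER_ADJUST if pac_adjust else 1.0
        if om_freq > 0.0:
            n_om = om_freq * dur_h
            if indoor:
                out["object_mouth_dust"] += (
                    v["dust_object"] * blanket_factor * v["object_mouth_area"]
                    * v["dust_transfer_hand"] * v["saliva_removal"] * n_om * adj)
            elif ev.ground_contact and not under1:
                out["object_mouth_soil"] += (
                    adher_ug * v["object_mouth_area"]
                    * v["saliva_removal"] * n_om * adj)

        p_pac = v["p_pacifier"]
        if p_pac > 0.0 and v["pacifier_drop"] > 0.0:
            if indoor:
                out["pacifier_dust"] += (
                    p_pac * v["pacifier_drop"] * dur_h
                    * (1.0 - v["pacifier_washing"]) * v["pacifier_size"]
                    * frac_loading_mix * blanket_factor * v["pacifier_transfer"])
            elif (age_group == SOIL_PACIFIER_AGE and ev.ground_contact):
                out["pacifier_soil"] += (
                    p_pac * v["pacifier_drop"] * dur_h
                    * (1.0 - v["pacifier_washing"]) * v["pacifier_size"]
                    * v["pacifier_frac_soft"] * adher_ug)

    res = {k: x / 1000.0 for k, x in out.items()}  # ug -> mg
    res["dust"] = res["hand_mouth_dust"] + res["object_mouth_dust"] + res["pacifier_dust"]
    res["soil"] = res["hand_mouth_soil"] + res["object_mouth_soil"] + res["pacifier_soil"]
    res["total"] = res["dust"] + res["soil"]
    return res


def base_run_at_medians(age_group: str, config: ModelConfig,
                        diary: Diary | None = None,
                        metric: str = "dust") -> float:
    """Deterministic daily ingestion (mg/day) with all inputs at medians."""
    if diary is None:
        diary = reference_diary(age_group, config)
    vals = median_values(age_group, config)
    return expected_day(vals, diary, age_group)[metric]


def oat_ratio(variable: str, age_group: str, config: ModelConfig,
              diary: Diary | None = None,
              percentiles: tuple[float, float] = (0.05, 0.95),
              low: float | None = None, high: float | None = None,
              metric: str = "dust") -> SensitivityRow:
    """High/low exposure ratio for one variable, all others at medians.

    ``low``/``high`` override the default percentile settings (use the
    distribution's min/max by passing ``percentiles=(0, 1)``).  Settings
    are exposure-oriented after evaluation: the larger result is the
    high-exposure value, so the ratio is always >= 1 (a protective
    variable like blanket-use probability has its *lower* setting as the
    high-exposure setting).
    """
    if (age_group, variable) not in config.bindings:
        raise KeyError(f"variable {variable!r} not bound for {age_group}")
    if diary is None:
        diary = reference_diary(age_group, config)
    spec = config.spec(age_group, variable)
    a = spec.ppf(percentiles[0]) if low is None else low
    b = spec.ppf(percentiles[1]) if high is None else high
    vals = median_values(age_group, config)
    res = []
    for setting in (a, b):
        vals_i = dict(vals)
        vals_i[variable] = setting
        res.append(expected_day(vals_i, diary, age_group)[metric])
    lo_val, hi_val = min(res), max(res)
    ratio = hi_val / lo_val if lo_val > 0 else (1.0 if hi_val == lo_val else math.inf)
    return SensitivityRow(variable, lo_val, hi_val, ratio, classify_ratio(ratio))


def oat_table(age_group: str, config: ModelConfig,
              variables: tuple[str, ...] = TABLE_OAT_VARS,
              metric: str = "dust", **kwargs) -> pd.DataFrame:
    """OAT screening table, sorted by descending high/low ratio."""
    base = base_run_at_medians(age_group, config, metric=metric)
    rows = [oat_ratio(v, age_group, config, metric=metric, **kwargs)
            for v in variables]
    df = pd.DataFrame([{
        "variable": r.variable,
        "low_exposure": r.low_exposure_value,
        "high_exposure": r.high_exposure_value,
        "ratio": r.ratio,
        "sensitivity": r.sensitivity,
    } for r in rows]).sort_values("ratio", ascending=False, ignore_index=True)
    df.attrs["base_run"] = base
    return df


# ------------------------------------------------- distribution shifts ----

@dataclass(frozen=True)
class ShiftResult:
    variable: str
    age_group: str
    n_persons: int
    base_mean: float       # mg/day
    scenario_mean: float   # mg/day
    percent_change: float  # 100 x (base - scenario) / base
    se_percent: float      # delta-method SE of the paired estimate


def _metric_by_person(df: pd.DataFrame, pathway: str, medium: str) -> np.ndarray:
    col = f"{pathway}_{medium}" if pathway != "all" else medium
    return (df[df["period"] == "annual"]
            .sort_values("person")[col].to_numpy(dtype=float))


def distribution_shift_run(age_group: str, config: ModelConfig, variable: str,
                           new_spec: DistributionSpec, n_persons: int,
                           master_seed: int, pathway: str = "pacifier",
                           medium: str = "dust",
                           base_values: np.ndarray | None = None) -> ShiftResult:
    """Percent change in mean daily ingestion when one variable's
    distribution is replaced, using common random numbers.

    ``base_values`` lets callers reuse a precomputed base run (per-person
    annual averages in person order) when screening several scenarios
    against the same base.
    """
    if base_values is None:
        base_df = run_age_group(age_group, n_persons, config, master_seed)
        base_values = _metric_by_person(base_df, pathway, medium)
    scen_cfg = config.with_spec(variable, new_spec)
    scen_df = run_age_group(age_group, n_persons, scen_cfg, master_seed)
    scen_values = _metric_by_person(scen_df, pathway, medium)

    b, s = np.asarray(base_values), np.asarray(scen_values)
    mb, ms = float(b.mean()), float(s.mean())
    ratio = ms / mb
    n = b.size
    # delta-method variance of the ratio of paired means
    cov = np.cov(s, b, ddof=1)
    var_ratio = (cov[0, 0] - 2 * ratio * cov[0, 1] + ratio**2 * cov[1, 1]) / (n * mb**2)
    return ShiftResult(
        variable=variable, age_group=age_group, n_persons=n,
        base_mean=mb, scenario_mean=ms,
        percent_change=100.0 * (mb - ms) / mb,
        se_percent=100.0 * math.sqrt(max(var_ratio, 0.0)),
    )
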