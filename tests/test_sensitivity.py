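"""Sensitivity analyses: OAT ratios and distribution shifts."""

import math

import numpy as np
import pytest

from soildust import DistributionSpec
from soildust.analytic import ANALYTIC_VALUES, analytic_config
from soildust.sensitivity import (base_run_at_medians, classify_ratio,
                                  distribution_shift_run, expected_day,
                                  median_values, oat_ratio, oat_table,
                                  reference_diary)


def pacifier_only_config(**overrides):
    """Analytic config with hand/object pathways switched off."""
    vals = {"hand_mouth_freq": 0.0, "object_mouth_freq_indoor": 0.0,
            "object_mouth_freq_outdoor": 0.0}
    vals.update(overrides)
    return analytic_config(vals)


class TestBaseRun:
    def test_all_point_config_base_equals_closed_form(self):
        """Pacifier-only day at points: E = p_pac * drop * hours * size *
        E[frac x loading] * transfer / 1000 per awake hour."""
        cfg = pacifier_only_config()
        diary = reference_diary("6m-<1y")
        awake_h = sum(e.duration for e in diary.events
                      if e.activity not in ("sleep", "bath")) / 60
        v = ANALYTIC_VALUES
        per_hour = (v["p_pacifier"] * v["pacifier_drop"] * v["pacifier_size"]
                    * 0.375 * v["dust_home_soft"] * v["pacifier_transfer"]) / 1000
        base = base_run_at_medians("6m-<1y", cfg, diary)
        assert base == pytest.approx(per_hour * awake_h, rel=1e-12)

    def test_base_run_idempotent(self, cfg):
        a = base_run_at_medians("6m-<1y", cfg)
        b = base_run_at_medians("6m-<1y", cfg)
        assert a == b and a > 0

    def test_probability_medians_enter_multiplicatively(self, cfg):
        """Doubling only P_pacifier's median doubles the pacifier term."""
        diary = reference_diary("6m-<1y")
        vals = median_values("6m-<1y", cfg)
        lo = dict(vals, p_pacifier=0.3)
        hi = dict(vals, p_pacifier=0.6)
        r = expected_day(hi, diary, "6m-<1y")["pacifier_dust"] / \
            expected_day(lo, diary, "6m-<1y")["pacifier_dust"]
        assert r == pytest.approx(2.0, rel=1e-12)


class TestOAT:
    def test_blanket_factor_ratio_matches_closed_form(self):
        """Pacifier-only OAT on F_blanket with blanket-use probability p:
        ratio = (p*F_hi + 1 - p) / (p*F_lo + 1 - p)."""
        p = 0.6
        cfg = pacifier_only_config(p_blanket=p)
        cfg = cfg.with_spec("f_blanket", DistributionSpec("uniform", (0.1, 0.4)))
        row = oat_ratio("f_blanket", "6m-<1y", cfg, percentiles=(0.05, 0.95))
        f_lo = 0.1 + 0.05 * 0.3
        f_hi = 0.1 + 0.95 * 0.3
        expected = (p * f_hi + 1 - p) / (p * f_lo + 1 - p)
        assert row.ratio == pytest.approx(expected, rel=1e-10)
        assert row.sensitivity == classify_ratio(row.ratio)

    def test_protective_variable_high_exposure_is_low_setting(self, cfg):
        """More blanket use means less dust: P_blanket's high-exposure
        value comes from its lower percentile."""
        row = oat_ratio("p_blanket", "6m-<1y", cfg)
        assert row.high_exposure_value >= row.low_exposure_value
        assert row.ratio >= 1.0
        # direct check of orientation
        diary = reference_diary("6m-<1y")
        vals = median_values("6m-<1y", cfg)
        lo_p = expected_day(dict(vals, p_blanket=0.05), diary, "6m-<1y")["dust"]
        hi_p = expected_day(dict(vals, p_blanket=0.95), diary, "6m-<1y")["dust"]
        assert lo_p > hi_p

    def test_null_influence_variable_ratio_one(self):
        """Pacifier size has no influence when the drop rate is zero."""
        cfg = pacifier_only_config(pacifier_drop=0.0)
        cfg = cfg.with_spec("pacifier_size", DistributionSpec("uniform", (8.0, 11.0)))
        row = oat_ratio("pacifier_size", "6m-<1y", cfg)
        assert row.ratio == pytest.approx(1.0)
        assert row.sensitivity == "not"

    def test_unknown_variable_rejected(self, cfg):
        with pytest.raises(KeyError):
            oat_ratio("no_such_input", "6m-<1y", cfg)

    def test_table_sorted_with_bands(self, cfg):
        table = oat_table("6m-<1y", cfg)
        assert list(table["ratio"]) == sorted(table["ratio"], reverse=True)
        assert set(table["sensitivity"]) <= {"most", "marginal", "least", "not"}
        assert (table["ratio"] >= 1.0 - 1e-12).all()

    def test_classification_bands_partition(self):
        assert classify_ratio(2.5) == "most"
        assert classify_ratio(2.0) == "marginal"
        assert classify_ratio(1.7) == "marginal"
        assert classify_ratio(1.5) == "least"
        assert classify_ratio(1.2) == "least"
        assert classify_ratio(1.1) == "not"
        assert classify_ratio(1.0) == "not"


class TestDistributionShift:
    def test_null_shift_changes_nothing(self, cfg):
        """Replacing a distribution with itself is a 0% change exactly
        (common random numbers reproduce every draw)."""
        res = distribution_shift_run(
            "6m-<1y", cfg, "pacifier_transfer",
            DistributionSpec("uniform", (0.25, 0.75)), n_persons=40,
            master_seed=5)
        assert res.percent_change == pytest.approx(0.0, abs=1e-12)

    def test_washing_shift_reduces_ingestion_by_about_its_mean(self, cfg):
        res = distribution_shift_run(
            "6m-<1y", cfg, "pacifier_washing",
            DistributionSpec("uniform", (0.05, 0.15)), n_persons=300,
            master_seed=5)
        assert res.percent_change == pytest.approx(10.0, abs=3 * res.se_percent + 0.5)

    def test_paired_design_beats_independent_reruns(self, cfg):
        """Common random numbers shrink the scenario-vs-base SE far below
        the unpaired two-sample SE."""
        base = run_values = None
        from soildust.population import run_age_group
        from soildust.sensitivity import _metric_by_person
        spec = DistributionSpec("uniform", (0.05, 0.15))
        n = 150
        base_df = run_age_group("6m-<1y", n, cfg, 11)
        b = _metric_by_person(base_df, "pacifier", "dust")
        scen_df = run_age_group("6m-<1y", n, cfg.with_spec("pacifier_washing", spec), 11)
        s = _metric_by_person(scen_df, "pacifier", "dust")
        paired_se = np.std(b - s, ddof=1) / math.sqrt(n)
        unpaired_se = math.sqrt(np.var(b, ddof=1) / n + np.var(s, ddof=1) / n)
        assert paired_se < unpaired_se / 3
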