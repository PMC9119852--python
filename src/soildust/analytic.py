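"""An all-point "analytic" configuration.

Every distribution is collapsed to a point and every probability check is
forced to 0 or 1, so a simulated day has a closed-form answer: with one
indoor awake hour, the pacifier pathway ingests

    10 ug/cm^2 x 9.5 cm^2 x 0.375 x 0.5 = 17.8125 ug/drop
    17.8125 x 5 drops/h x 1 h x (1 - 0) = 89.0625 ug = 0.0890625 mg/day.

Used by the test suite as the exact oracle for the event engine, and
written out by the ``fixtures`` CLI subcommand.
"""

from __future__ import annotations

from .config import ModelConfig, default_config
from .distributions import DistributionSpec


def _pt(value: float) -> DistributionSpec:
    return DistributionSpec("point", (value,))


#: Point values of the analytic configuration.
ANALYTIC_VALUES: dict[str, float] = {
    "p_blanket": 0.0,
    "f_blanket": 0.25,
    "pacifier_size": 9.5,
    "pacifier_frac_hard": 0.375,
    "pacifier_frac_soft": 0.375,
    "pacifier_transfer": 0.5,
    "pacifier_washing": 0.0,
    "pacifier_drop": 5.0,
    "p_pacifier": 1.0,
    "adherence_soil": 0.0,
    "hand_mouth_fraction": 0.10,
    "hand_mouth_freq": 0.0,
    "object_mouth_area": 10.0,
    "object_mouth_freq_indoor": 0.0,
    "object_mouth_freq_outdoor": 0.0,
    "hand_surface_area": 100.0,
    "dust_home_soft": 10.0,
    "dust_home_hard": 10.0,
    "dust_object": 10.0,
    "p_home_soft": 0.5,
    "dust_transfer_hand": 0.5,
    "saliva_removal": 0.5,
    "handwash_removal": 0.9,
    "bath_removal": 1.0,
    "hand_contact_fraction": 1.0,
}


def analytic_config(overrides: dict[str, float] | None = None) -> ModelConfig:
    """Default config with every variable collapsed to a point value."""
    values = dict(ANALYTIC_VALUES)
    if overrides:
        values.update(overrides)
    cfg = default_config()
    for name, value in values.items():
        cfg = cfg.with_spec(name, _pt(value))
    return cfg
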