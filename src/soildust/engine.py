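"""Event-driven soil and dust ingestion engine.

Walks a day's diary chronologically and accumulates ingested mass through
three pathways:

* **hand-to-mouth** — hands pick up dust (indoors) or soil (outdoors,
  ground-level contact) and a fraction of one hand's area is mouthed at an
  age-specific hourly frequency; saliva removes a fraction of the loading
  on the mouthed area, which is both ingested and depleted from the hand;
* **object-to-mouth** — toys and similar objects carrying surface dust are
  mouthed at an hourly frequency; for pacifier-using ages the predicted
  object-to-mouth ingestion is reduced 4% because the pacifier is modelled
  explicitly as its own pathway;
* **pacifier** — a dropped pacifier picks up floor dust over the contacted
  fraction of its area and transfers it to the mouth on re-insertion:

      dust_per_drop       = surface_dust_loading x pacifier_size
                            x pacifier_frac x pacifier_transfer    [ug/drop]
      exp_pacifier_event  = dust_per_drop x pacifier_drop
                            x event_duration x (1 - pacifier_washing)  [ug]
      exp_pacifier_daily  = sum(exp_pacifier_event) / 1000        [mg/day]

  For 1-<2 y children playing outdoors at ground level, the soil adherence
  factor (converted mg/cm^2 -> ug/cm^2) replaces the product
  surface_dust_loading x pacifier_transfer.

A blanket (crib, stroller, sheet — any barrier) in use during an event
multiplies the surface loading seen by every pathway by the per-person
barrier factor ``f_blanket``; blanket use is re-decided on every event.
Hand loadings persist across events (including overnight) and are reduced
only by mouthing, handwashing, and bathing.  Sleeping and bathing events
have no contacts.  Children under one year have no soil contact at all.

All per-event masses are in micrograms; daily roll-ups are in mg/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import (AGE_GROUP_INDEX, PACIFIER_AGE_GROUPS, PersonParams,
                     UNDER_ONE_YEAR)
from .diary import Diary

__all__ = [
    "PATHWAYS", "MEDIA", "HandState", "LedgerEntry", "ExposureLedger",
    "effective_loading", "dust_per_drop", "exp_pacifier_event",
    "exp_pacifier_daily", "pacifier_soil_event", "hand_contact_event",
    "hand_to_mouth_event", "object_to_mouth_event", "removal_event",
    "simulate_person_day", "SOIL_PACIFIER_AGE", "OBJECT_MOUTH_PACIFIER_ADJUST",
]

PATHWAYS = ("hand_mouth", "object_mouth", "pacifier")
MEDIA = ("dust", "soil")

#: Only 1-<2 y children can transfer soil to a dropped pacifier outdoors.
SOIL_PACIFIER_AGE = "1-<2y"

#: Deterministic multiplier removing the pacifier portion from generic
#: object-to-mouth predictions for pacifier-using ages.
OBJECT_MOUTH_PACIFIER_ADJUST = 0.96

MG_PER_UG = 1e-3


@dataclass
class HandState:
    """Dust and soil loadings on the hands, ug/cm^2 (never negative)."""

    dust: float = 0.0
    soil: float = 0.0


@dataclass(frozen=True)
class LedgerEntry:
    event_index: int
    pathway: str
    medium: str
    amount_ug: float


@dataclass
class ExposureLedger:
    """Per-event ingestion records and their daily roll-up."""

    record_events: bool = True
    events: list[LedgerEntry] = field(default_factory=list)
    totals_ug: dict[tuple[str, str], float] = field(
        default_factory=lambda: {(p, m): 0.0 for p in PATHWAYS for m in MEDIA})

    def add(self, event_index: int, pathway: str, medium: str,
            amount_ug: float) -> None:
        if amount_ug < 0:
            raise ValueError("ingested amount cannot be negative")
        self.totals_ug[(pathway, medium)] += amount_ug
        if self.record_events:
            self.events.append(LedgerEntry(event_index, pathway, medium, amount_ug))

    def daily_mg(self) -> dict[tuple[str, str], float]:
        """mg/day by (pathway, medium)."""
        return {k: v * MG_PER_UG for k, v in self.totals_ug.items()}

    def medium_mg(self, medium: str) -> float:
        return sum(v for (p, m), v in self.totals_ug.items()
                   if m == medium) * MG_PER_UG

    def total_mg(self) -> float:
        return sum(self.totals_ug.values()) * MG_PER_UG


# ------------------------------------------------------- pure event algebra --

def effective_loading(surface_loading: float, blanket_in_use: bool,
                      f_blanket: float) -> float:
    """Surface loading seen through the blanket barrier, if one is in use."""
    return surface_loading * f_blanket if blanket_in_use else surface_loading


def dust_per_drop(surface_dust_loading: float, pacifier_size: float,
                  pacifier_frac: float, pacifier_transfer: float) -> float:
    """ug of dust picked up by one pacifier drop."""
    return surface_dust_loading * pacifier_size * pacifier_frac * pacifier_transfer


def exp_pacifier_event(dust_per_drop_ug: float, pacifier_drop: float,
                       duration_h: float, pacifier_washing: float) -> float:
    """ug of dust ingested via the pacifier over one indoor awake event."""
    return dust_per_drop_ug * pacifier_drop * duration_h * (1.0 - pacifier_washing)


def exp_pacifier_daily(event_amounts_ug) -> float:
    """mg/day: sum of per-event pacifier amounts, ug -> mg."""
    return sum(event_amounts_ug) * MG_PER_UG


def pacifier_soil_event(adherence_soil_mg: float, pacifier_size: float,
                        pacifier_frac: float, pacifier_drop: float,
                        duration_h: float, pacifier_washing: float,
                        age_group: str) -> float:
    """ug of *soil* ingested via an outdoor pacifier event (1-<2 y only).

    The soil adherence factor (mg/cm^2, converted to ug/cm^2) replaces the
    surface_dust_loading x pacifier_transfer product of the dust equation.
    """
    if age_group in UNDER_ONE_YEAR:
        raise ValueError(
            f"{age_group}: children under one year have no soil contact")
    adherence_ug = adherence_soil_mg * 1000.0
    return (adherence_ug * pacifier_size * pacifier_frac
            * pacifier_drop * duration_h * (1.0 - pacifier_washing))


def hand_contact_event(hand: HandState, medium: str, loading_ug: float,
                       transfer: float, contact_fraction: float,
                       blanket_in_use: bool = False,
                       f_blanket: float = 1.0) -> HandState:
    """One hand-surface contact.

    Dust: the hand loading moves toward the effective surface loading times
    the dust-to-hand transfer efficiency, over the contacted fraction of
    the hand (saturating — repeated contacts do not accumulate without
    bound).  Soil: adherence behaves as a loading, so contact brings the
    hand's soil loading up to the adherence level.
    """
    eff = effective_loading(loading_ug, blanket_in_use, f_blanket)
    if medium == "dust":
        target = eff * transfer
        if target > hand.dust:
            hand.dust += (target - hand.dust) * contact_fraction
    elif medium == "soil":
        if eff > hand.soil:
            hand.soil = eff
    else:
        raise ValueError(f"unknown medium {medium!r}")
    return hand


def hand_to_mouth_event(hand: HandState, hand_mouth_fraction: float,
                        one_hand_area: float, saliva_removal: float):
    """One mouthing of a fraction of one hand.

    Returns the updated hand state and the ingested ug by medium.  The
    mass removed by saliva from the mouthed area is exactly the mass
    ingested, so hands deplete with repeated mouthing.
    """
    r = hand_mouth_fraction * saliva_removal
    ingested = {
        "dust": hand.dust * one_hand_area * r,
        "soil": hand.soil * one_hand_area * r,
    }
    hand.dust *= (1.0 - r)
    hand.soil *= (1.0 - r)
    return hand, ingested


def object_to_mouth_event(surface_loading: float, object_mouth_area: float,
                          transfer: float, saliva_removal: float,
                          blanket_in_use: bool = False, f_blanket: float = 1.0,
                          pacifier_adjustment: bool = False) -> float:
    """ug ingested by mouthing one object carrying surface dust or soil."""
    eff = effective_loading(surface_loading, blanket_in_use, f_blanket)
    amount = eff * object_mouth_area * transfer * saliva_removal
    if pacifier_adjustment:
        amount *= OBJECT_MOUTH_PACIFIER_ADJUST
    return amount


def removal_event(hand: HandState, kind: str, handwash_removal: float,
                  bath_removal: float) -> HandState:
    """Handwashing or bathing removes a fraction of both hand loadings."""
    if kind == "handwash":
        keep = 1.0 - handwash_removal
    elif kind == "bath":
        keep = 1.0 - bath_removal
    else:
        raise ValueError(f"unknown removal kind {kind!r}")
    hand.dust *= keep
    hand.soil *= keep
    return hand


# ------------------------------------------------------------- a whole day --

def simulate_person_day(diary: Diary, person: PersonParams, rng,
                        var_rng=None, record_events: bool = True) -> ExposureLedger:
    """Simulate one diary day for one person.

    ``rng`` drives event-level stochasticity (Bernoulli checks for blanket
    use, carpet vs bare floor and pacifier use, plus Poisson mouthing
    counts).  ``var_rng``, if given, maps a variable name to the stream
    used for its per-event draws (kept separate so that paired scenario
    runs share all other randomness); it defaults to ``rng``.
    """
    if var_rng is None:
        var_rng = lambda name: rng  # noqa: E731

    v = person.values
    age = person.age_group
    under1 = age in UNDER_ONE_YEAR
    pac_adjust = age in PACIFIER_AGE_GROUPS

    p_blanket = v["p_blanket"]
    p_soft = v["p_home_soft"]
    p_pac = v["p_pacifier"]
    f_blanket = v["f_blanket"]
    hm_freq = v["hand_mouth_freq"]
    hm_frac = v["hand_mouth_fraction"]
    hand_area = v["hand_surface_area"]
    saliva = v["saliva_removal"]
    contact_frac = v["hand_contact_fraction"]
    transfer_hand = v["dust_transfer_hand"]
    adherence = v["adherence_soil"]
    obj_area = v["object_mouth_area"]
    pac_size = v["pacifier_size"]
    pac_drop = v["pacifier_drop"]
    pac_wash = v["pacifier_washing"]

    ledger = ExposureLedger(record_events=record_events)
    hand = HandState()

    for i, ev in enumerate(diary.events):
        if ev.activity == "sleep":
            continue
        if ev.activity == "bath":
            removal_event(hand, "bath", v["handwash_removal"], v["bath_removal"])
            continue
        if ev.activity == "handwash":
            removal_event(hand, "handwash", v["handwash_removal"], v["bath_removal"])
            continue

        dur_h = ev.duration / 60.0
        indoor = ev.location == "indoor"
        blanket = rng.random() < p_blanket
        carpet = rng.random() < p_soft

        surface = v["dust_home_soft"] if carpet else v["dust_home_hard"]
        if indoor:
            hand_contact_event(hand, "dust", surface, transfer_hand,
                               contact_frac, blanket, f_blanket)
        elif ev.ground_contact and not under1:
            hand_contact_event(hand, "soil", adherence * 1000.0, 1.0, 1.0)

        # hand-to-mouth mouthings
        n_hm = rng.poisson(hm_freq * dur_h)
        if n_hm and (hand.dust > 0.0 or hand.soil > 0.0):
            for _ in range(n_hm):
                hand, ing = hand_to_mouth_event(hand, hm_frac, hand_area, saliva)
                if ing["dust"] > 0.0:
                    ledger.add(i, "hand_mouth", "dust", ing["dust"])
                if ing["soil"] > 0.0:
                    ledger.add(i, "hand_mouth", "soil", ing["soil"])

        # object-to-mouth mouthings
        om_freq = v["object_mouth_freq_indoor" if indoor else "object_mouth_freq_outdoor"]
        if om_freq > 0.0 and (indoor or (ev.ground_contact and not under1)):
            n_om = rng.poisson(om_freq * dur_h)
            for _ in range(n_om):
                if indoor:
                    amt = object_to_mouth_event(
                        v["dust_object"], obj_area, transfer_hand, saliva,
                        blanket, f_blanket, pac_adjust)
                    if amt > 0.0:
                        ledger.add(i, "object_mouth", "dust", amt)
                else:
                    amt = object_to_mouth_event(
                        adherence * 1000.0, obj_area, 1.0, saliva,
                        False, 1.0, pac_adjust)
                    if amt > 0.0:
                        ledger.add(i, "object_mouth", "soil", amt)

        # pacifier pathway (indoors and awake; soil variant for 1-<2 y outdoors)
        if p_pac > 0.0 and pac_drop > 0.0:
            if indoor:
                if rng.random() < p_pac:
                    frac = v["pacifier_frac_soft"] if carpet else v["pacifier_frac_hard"]
                    eff = effective_loading(surface, blanket, f_blanket)
                    transfer = person.sample_event(
                        "pacifier_transfer", var_rng("pacifier_transfer"))
                    dpd = dust_per_drop(eff, pac_size, frac, transfer)
                    amt = exp_pacifier_event(dpd, pac_drop, dur_h, pac_wash)
                    if amt > 0.0:
                        ledger.add(i, "pacifier", "dust", amt)
            elif age == SOIL_PACIFIER_AGE and ev.ground_contact:
                if rng.random() < p_pac:
                    amt = pacifier_soil_event(
                        adherence, pac_size, v["pacifier_frac_soft"],
                        pac_drop, dur_h, pac_wash, age)
                    if amt > 0.0:
                        ledger.add(i, "pacifier", "soil", amt)

    return ledger
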