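"""Generate a synthetic 24-h activity diary and a full diary-year.

Each simulated day is a contiguous sequence of 1-60 minute events with
location and activity labels; a person-year is one weekday and one
weekend diary per season, weighted by calendar day counts.
"""

from soildust import default_config, generate_diary
from soildust.diary import build_diary_year
from soildust.rng import PersonStreams, substream

cfg = default_config()

diary = generate_diary("2-<3y", "summer", "weekend", cfg.diary,
                       substream(1, "example"))
print("Summer weekend day of a 2-<3 y child:")
for e in diary.events[:12]:
    print(f"  {e.start:4d} +{e.duration:2d} min  {e.location:7s} {e.activity}"
          + ("  (ground contact)" if e.ground_contact else ""))
print(f"  ... {len(diary.events)} events, total {diary.total_minutes()} min")
outdoor = sum(e.duration for e in diary.events if e.location == "outdoor")
sleep = sum(e.duration for e in diary.events if e.activity == "sleep")
print(f"outdoor {outdoor} min, sleep {sleep} min")

year = build_diary_year("2-<3y", cfg.diary, PersonStreams(1, "2-<3y", 0))
print(f"\nDiary-year: {len(year.diaries)} diaries, "
      f"weights sum to {sum(year.weights.values()):.2f} days")
# The 8 weights (91.25 days per season split 5:2 weekday:weekend) are what
# turn per-day ingestion into annual averages.
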