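"""Label game sessions relative to medication intakes.

Each session is attributed to the nearest logged intake and labeled
"before" (up to 5 h before / 15 min after for 1-2 intakes per day, 1 h
before for more frequent regimens), "after" (30 min - 3 h, or 30-90 min),
or excluded.
"""

from datetime import datetime, timezone

from tremorkit import MedicationLog, label_session, nearest_intake

UTC = timezone.utc
logs = [
    MedicationLog("P1", datetime(2024, 3, 1, 8, 0, tzinfo=UTC), intakes_per_day=2),
    MedicationLog("P1", datetime(2024, 3, 1, 20, 0, tzinfo=UTC), intakes_per_day=2),
]

for hh, mm in [(7, 0), (8, 10), (9, 0), (8, 20), (14, 0)]:
    start = datetime(2024, 3, 1, hh, mm, tzinfo=UTC)
    intake, delta = nearest_intake(start, logs)
    label = label_session(delta, intakes_per_day=2)
    print(f"session {hh:02d}:{mm:02d} -> nearest intake "
          f"{intake.intake_time:%H:%M}, delta {delta:+6.0f} min -> {label}")

# 07:00 (-60 min) and 08:10 (+10 min, inside the 15-min absorption
# grace) count as "before"; 09:00 (+60 min) as "after"; 08:20 (+20 min)
# falls in the gap between windows and is excluded; 14:00 is equidistant
# from both intakes and the tie goes to the earlier one (+360 -> excluded).
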