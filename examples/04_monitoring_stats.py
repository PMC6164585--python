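"""Campaign statistics: accuracy tables, bookkeeping and night screening.

Rebuilds the evaluation arithmetic a monitoring campaign reports: per-area
accuracy from correct/incorrect localisation counts, the valid-record
identity, per-bird calling rates, and the grouped night-time area
distribution used to flag feeding problems.
"""

from coopssl import (
    SslEvent,
    accuracy_table,
    area_distribution,
    per_bird_rate,
    validity_bookkeeping,
)

# Laboratory double-array evaluation: (correct, incorrect) per area.
lab = {"I": (66, 6), "II": (52, 34), "III": (18, 3), "IV": (59, 23)}
print("laboratory accuracy table:")
print(accuracy_table(lab).to_string())

print("\nsingle-array campaign bookkeeping:")
valid = validity_bookkeeping(total_ssls=3272, non_null=1087, invalid=19)
print(f"  3272 attempts, 1087 non-null, 19 invalid -> {valid} valid")

print("\nper-bird calling rates (flock of 15):")
print(f"  600 calls during feeding -> {per_bird_rate(600, 15):.0f} per bird")
print(f"  795 calls over a day     -> {per_bird_rate(795, 15):.0f} per bird")

# A starving flock crowds the feeder side at night: 9 valid events on the
# nest/activity side vs 127 on the feeding/drinking side.
events = [SslEvent(float(i), 5.0, 5.0, 0.9, "I", "valid") for i in range(5)]
events += [SslEvent(50.0 + i, -5.0, 5.0, 0.9, "II", "valid") for i in range(4)]
events += [SslEvent(100.0 + i, -5.0, -5.0, 0.9, "III", "valid") for i in range(70)]
events += [SslEvent(300.0 + i, 5.0, -5.0, 0.9, "IV", "valid") for i in range(57)]
night = area_distribution(events, grouping=[{"I", "II"}, {"III", "IV"}])
print(f"\nnight area distribution: {night}")
print("a feeder-side majority at night points at late or inadequate feeding")
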