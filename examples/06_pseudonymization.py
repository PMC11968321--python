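"""Snapshot preparation: pseudonymization and date coarsening.

Direct identifiers are replaced by keyed-hash pseudonyms with the linkage
map kept separately; dates of birth lose their day-of-month before upload.
"""

import pandas as pd

from fedshield.datagen import coarsen_date, pseudonymize

roster = pd.DataFrame(
    {
        "national_id": ["AB123", "CD456", "EF789"],
        "dob": ["1987-06-23", "1990-01-05", "1979-11-30"],
        "bmi": [24.1, 27.8, 31.0],
    }
)

snapshot, linkage = pseudonymize(roster, "national_id", key="custodian-secret")
snapshot["dob"] = coarsen_date(snapshot["dob"], "month")
print("uploadable snapshot:")
print(snapshot.to_string(index=False))

print("\nlinkage map (kept separately, custodian only):")
for pseud, orig in linkage.items():
    print(f"  {pseud} -> {orig}")

again, _ = pseudonymize(roster, "national_id", key="custodian-secret")
other, _ = pseudonymize(roster, "national_id", key="other-key")
print(f"\nsame key links records: {snapshot['national_id'].tolist() == again['national_id'].tolist()}")
print(f"different key is unlinkable: {set(snapshot['national_id']).isdisjoint(other['national_id'])}")
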