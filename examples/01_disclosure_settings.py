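"""Disclosure-control settings and privacy levels.

Shows the custodian-facing parameter vector every node enforces, what its
validation rejects, and which server-side functions each privacy level
blocks.
"""

import dataclasses

from fedshield.settings import (
    blocked_functions,
    default_settings,
    settings_to_mapping,
    validate_settings,
)

s = default_settings()
print("shipped defaults (custodian key spelling):")
for key, value in settings_to_mapping(s).items():
    print(f"  {key} = {value}")

bad = dataclasses.replace(s, glm_ratio=1.2, subset_threshold=0)
verdict = validate_settings(bad)
print(f"\ninvalid override rejected: accepted={verdict.accepted}, fields={verdict.violations}")

print("\nfunctions blocked per privacy level:")
for level in ("permissive", "banana", "avocado", "non-permissive"):
    names = sorted(blocked_functions(level))
    print(f"  {level:15s} ({len(names):2d}): {', '.join(names) or '-'}")

# The default level 'banana' blocks seeded random generation (inference
# attacks) but still allows subsetting; 'avocado' is the reverse;
# 'non-permissive' blocks both groups plus repDS.
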