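"""Classify candidate biosensors from an equilibrium fluorescence panel.

Each engineered cysteine variant of the scaffold protein, conjugated to a
coumarin dye, is challenged with saturating target ligands and a non-specific
control carbohydrate.  A variant is a working biosensor when its peak
fluorescence changes by at least the threshold for every target AND stays
below it for every control.  The published five-variant panel yields 4/5
responsive at the default 5% threshold.
"""

import cinc
from cinc.refdata import CONTROL_LIGANDS, TARGET_LIGANDS, TOGB_RESPONSE_PANEL

result = cinc.classify_responses(TOGB_RESPONSE_PANEL, TARGET_LIGANDS,
                                 CONTROL_LIGANDS, threshold=5.0)

print(f"threshold: |change| >= {result['threshold_percent']}% on all targets, "
      f"< {result['threshold_percent']}% on all controls\n")
for variant, verdict in sorted(result["verdicts"].items()):
    status = "responsive" if verdict["responsive"] else "NOT responsive"
    print(f"  {variant:<18} {status}")
print(f"\nsuccess rate: {result['n_responsive']}/{result['n_variants']} "
      f"= {result['success_rate_percent']:.0f}%")
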