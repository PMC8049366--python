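"""Fit organ kinetics, integrate to residence times, and compute doses.

Takes a simulated subject, fits sums of exponentials to every organ curve,
applies the 3.5 h dynamic bladder voiding model, and runs the MIRD dose
engine with a toy S-value phantom.
"""

import dataclasses

from mirdkit.dosimetry import compute_absorbed_doses, effective_dose
from mirdkit.nuclide import GA68
from mirdkit.pipeline import fit_residence_times
from mirdkit.synthetic import SubjectConfig, generate_subject, generate_toy_svalue_table

cfg = dataclasses.replace(SubjectConfig(), seed=1)
subject = generate_subject(cfg)

tiacs, models, bladder = fit_residence_times(subject.tacs, GA68, voiding_interval_h=3.5)
print("residence times (h):")
for organ, tiac in sorted(tiacs.organs.items()):
    print(f"  {organ:20s} {tiac:.4f}")
print(f"  {'remainder of body':20s} {tiacs.remainder_of_body:.4f}")
print(f"sum of TIACs: {tiacs.total():.4f} h  (physical bound {GA68.mean_life_hours:.4f} h)")
print(f"fitted excreted fraction {bladder.excreted_fraction:.3f}, "
      f"biologic half-life {bladder.biologic_half_life:.0f} min")

sv = generate_toy_svalue_table(
    len(tiacs.organs), seed=1, organ_names=list(tiacs.organs), whole_body_target=True
)

report = compute_absorbed_doses(tiacs, sv)
e = effective_dose(report)
print(f"\neffective dose on the toy phantom: {e:.4f} mSv/MBq")
# Each TIAC is the organ's disintegrations per unit injected activity; their
# sum must stay below the Ga-68 mean life (1.635 h).  The bladder entry
# reflects the 3.5 h voiding model, so it is smaller than the no-void value.
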