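"""Equilibrium and kinetic binding constants from stopped-flow titrations.

Amplitudes of the fluorescence change vs ligand concentration follow the
hyperbolic isotherm Y = B_max * c / (K_D + c); apparent rates grow linearly
with concentration with slope k_on.  This example evaluates both models at
the published concentration designs and affinities for the two main ligands
(4,5-unsaturated and saturated digalacturonide) and refits them.
"""

import cinc
from cinc import refdata

for ligand, conc, kd in [
        ("unsatdigalUA", refdata.UNSATDIGALUA_CONCENTRATIONS_UM, refdata.KD_UNSATDIGALUA_UM),
        ("digalUA", refdata.DIGALUA_CONCENTRATIONS_UM, refdata.KD_DIGALUA_UM)]:
    amplitudes = cinc.hyperbola(conc, 1.0, kd)
    curve = cinc.fit_kd(conc, amplitudes)
    print(f"{ligand}: K_D = {curve.k_d:.3g} uM (SE {curve.stderr['k_d']:.1e}), "
          f"B_max = {curve.b_max:.3g} a.u.")
    # half-saturation identity: Y(K_D) = B_max / 2
    assert abs(cinc.hyperbola(curve.k_d, curve.b_max, curve.k_d)
               - curve.b_max / 2) < 1e-12

rates = refdata.KON_UNSATDIGALUA * refdata.UNSATDIGALUA_CONCENTRATIONS_UM
line = cinc.fit_kon(refdata.UNSATDIGALUA_CONCENTRATIONS_UM, rates)
print(f"unsatdigalUA: k_on = {line.k_on:.3g} uM^-1 s^-1 "
      f"(intercept {line.params['intercept']:.2g} s^-1)")
print("\nK_D is the ligand concentration at half-maximal response; k_on the")
print("bimolecular association rate constant from the k_app vs c slope.")
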