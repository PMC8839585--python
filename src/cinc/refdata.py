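"""Published reference values for the TogB oligogalacturonide biosensor set.

These are experimental constants and printed result tables from the study
that characterized MDCC-labeled TogB cysteine variants as biosensors for
pectin breakdown products.  They serve as worked-example inputs: the
equilibrium response panel feeds the responsiveness classifier, the enzyme
progress-curve fit parameters seed forward simulations, and the stopped-flow
concentration series define the designs used for binding-curve fits.
"""

from __future__ import annotations

import numpy as np

from .kinetics import ResponsePanel

TARGET_LIGANDS = ["unsatdigalUA", "digalUA", "trigalUA"]
CONTROL_LIGANDS = ["galacturonic_acid"]

# Equilibrium fluorescence response panel: percent change in peak
# fluorescence of each MDCC-labeled TogB variant on ligand addition
# (saturating ligand; n = 1 per cell).
TOGB_RESPONSE_PANEL = ResponsePanel.from_records([
    ("TogB K99C-MDCC", "unsatdigalUA", +2.0),
    ("TogB K99C-MDCC", "digalUA", -4.0),
    ("TogB K99C-MDCC", "trigalUA", -4.0),
    ("TogB K99C-MDCC", "galacturonic_acid", -2.0),
    ("TogB F247C-MDCC", "unsatdigalUA", -14.0),
    ("TogB F247C-MDCC", "digalUA", -10.0),
    ("TogB F247C-MDCC", "trigalUA", -20.0),
    ("TogB F247C-MDCC", "galacturonic_acid", -1.0),
    ("TogB A284C-MDCC", "unsatdigalUA", -31.0),
    ("TogB A284C-MDCC", "digalUA", -31.0),
    ("TogB A284C-MDCC", "trigalUA", -30.0),
    ("TogB A284C-MDCC", "galacturonic_acid", -1.0),
    ("TogB K362C-MDCC", "unsatdigalUA", -32.0),
    ("TogB K362C-MDCC", "digalUA", -25.0),
    ("TogB K362C-MDCC", "trigalUA", -29.0),
    ("TogB K362C-MDCC", "galacturonic_acid", -2.0),
    ("TogB D363C-MDCC", "unsatdigalUA", -60.0),
    ("TogB D363C-MDCC", "digalUA", -39.0),
    ("TogB D363C-MDCC", "trigalUA", -44.0),
    ("TogB D363C-MDCC", "galacturonic_acid", -1.0),
])

# Two-exponential fit parameters for biosensor-detected product release
# during polygalacturonic acid degradation (mean of 6 replicates):
# burst phase (first product release) then multiple-turnover phase.
YEPL2B_PROGRESS_FIT = {
    "f_inf": 0.545, "a1": 0.05, "k_app1": 39.0, "a2": 0.37, "k_app2": 0.033,
}
YEGH28_PROGRESS_FIT = {
    "f_inf": 0.565, "a1": 0.03, "k_app1": 33.0, "a2": 0.30, "k_app2": 0.021,
}

# Stopped-flow ligand-binding results for TogB D363C-MDCC.
KD_UNSATDIGALUA_UM = 1.3   # hyperbolic-fit dissociation constant, uM
KD_DIGALUA_UM = 6.0
KON_UNSATDIGALUA = 18.6    # linear-fit association rate constant, uM^-1 s^-1
KON_DIGALUA = 6.0

# Concentration designs of the stopped-flow titrations (uM).
UNSATDIGALUA_CONCENTRATIONS_UM = np.array([0.3, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0])
DIGALUA_CONCENTRATIONS_UM = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 16.0, 20.0])
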