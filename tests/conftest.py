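"""Shared fixtures: printed-report cohort values and synthetic patients."""

from __future__ import annotations

import pytest

from dosepipe import PatientKineticsParams, RunConfig, generate_patient

# Published cohort of 8 evaluable patients: normalized absorbed doses
# (Gy/GBq) for the organs at risk, the normalized effective dose
# (mSv/MBq), and the per-lesion tumor doses (Gy/GBq). These printed values
# serve as inputs to the planning arithmetic.
PATIENT_IDS = ["1", "2", "3", "4", "6", "7", "8", "9"]

ORGAN_DOSES_GY_PER_GBQ = {
    "red_marrow": [0.326, 0.346, 0.564, 0.499, 0.301, 0.206, 0.226, 0.375],
    "kidneys": [0.063, 0.097, 0.054, 0.053, 0.078, 0.094, 0.250, 0.691],
    "bone_surfaces": [1.080, 1.180, 1.980, 1.780, 1.040, 0.635, 0.641, 1.220],
}

EFFECTIVE_DOSE_MSV_PER_MBQ = [0.143, 0.130, 0.216, 0.177, 0.109, 0.095, 0.106, 0.158]

PRINTED_MTA_GBQ = [6.1, 5.8, 3.5, 4.0, 6.6, 9.7, 8.8, 5.3]

TUMOR_DOSES_GY_PER_GBQ = {
    "1": [5.02, 2.37, 5.37, 6.98, 2.53],
    "2": [5.15, 3.70, 1.72, 0.92, 1.56],
    "3": [3.63, 3.00, 1.65, 1.66, 4.10],
    "4": [2.85, 3.86, 2.25, 5.91, 4.39],
    "6": [2.03, 2.52, 2.79, 3.54, 4.36],
    "7": [8.05, 8.94, 3.69, 6.57, 4.26],
    "8": [6.13, 3.44, 1.17, 3.26, 2.84],
    "9": [7.94, 11.26, 9.27, 3.51],
}


@pytest.fixture(scope="session")
def noiseless_patient():
    """Default synthetic patient (no noise) with its ground truth."""
    return generate_patient(PatientKineticsParams())


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()
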