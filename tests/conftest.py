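import numpy as np
import pytest

from imrangio.cohort import CohortParams, generate_cohort
from imrangio.indices import compute_panels


@pytest.fixture(scope="session")
def default_cohort():
    """Default-parameter cohort at study scale (45 patients, seed 0)."""
    params = CohortParams()
    return params, generate_cohort(params)


@pytest.fixture(scope="session")
def large_cohort():
    """Default-noise cohort of ~2,000 lesions for calibration-level checks."""
    params = CohortParams(n_patients=870, seed=0)
    cohort = generate_cohort(params)
    panels = compute_panels(
        [r for p in cohort for r in p.physio],
        [r for p in cohort for r in p.angio],
    )
    return params, cohort, panels


def truth_by_lesion(cohort):
    """Map (lesion_id, timepoint) -> latent true resistance."""
    out = {}
    for p in cohort:
        out[(p.ira_lesion_id, "pre_pci")] = p.true_R_pre
        out[(p.ira_lesion_id, "post_pci")] = p.true_R_post
        if p.true_R_nonira is not None:
            out[(p.nonira_lesion_id, "post_pci")] = p.true_R_nonira
    return out
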