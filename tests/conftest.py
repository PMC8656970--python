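import numpy as np
import pytest

from ihcgate import imagequant as iq
from ihcgate import synthslide as ss


@pytest.fixture(scope="session")
def tumor_slide():
    """One rendered carcinoma section at full resolution, noiseless, with its
    ground truth: the shared fixture for measurement-chain tests."""
    cohort = ss.CohortConfig(
        group_counts={"VSCC_HPV_independent": 1},
        adjacent_counts={},
        image_size=(600, 600),
        microns_per_pixel=0.5,
        cell_density=3000.0,
        margin_px=10,
    )
    plan = ss.plan_cohort(cohort, seed=5)[0]
    profiles = {
        "VSCC_HPV_independent": ss.profile_for_target_hscore(
            118, tissue_type="VSCC_HPV_independent", marker_id="avb6"
        )
    }
    cells = ss.sample_cells(plan, profiles)
    image = ss.render_slide(plan, cells, noise_sd=0.0)
    return plan, cells, image


@pytest.fixture(scope="session")
def tumor_measurements(tumor_slide):
    """Hematoxylin/DAB channels and detected nuclei of the shared section."""
    plan, cells, image = tumor_slide
    od = iq.rgb_to_od(image)
    hema, dab = iq.separate_stains(od)
    params = iq.DetectionParams(microns_per_pixel=plan.microns_per_pixel)
    nuclei = iq.detect_nuclei(hema, params)
    return plan, cells, hema, dab, nuclei, params
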