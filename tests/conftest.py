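import numpy as np
import pytest

from recadim import repair_analysis as ra
from recadim import synthetic_data as sd


@pytest.fixture(scope="session")
def cohort():
    """Seeded default-condition cohort (n=200) with its track tables and truth."""
    cfg = sd.CohortConfig(n_cells=200, seed=1)
    cells = sd.generate_cohort(cfg)
    return {
        "config": cfg,
        "cells": cells,
        "frames": sd.cohort_frames_df(cells),
        "foci": sd.cohort_foci_df(cells),
        "events": sd.cohort_events_df(cells),
    }


@pytest.fixture(scope="session")
def cohort_results(cohort):
    """Pipeline output on the seeded cohort, merged with ground truth."""
    res = ra.analyze_cohort(cohort["frames"], cohort["foci"])
    merged = res.per_cell.merge(cohort["events"], on="cell_id",
                                suffixes=("", "_truth"))
    return {"results": res, "merged": merged}


@pytest.fixture(scope="session")
def snr10_fixture():
    """Standing 5-spot frame at SNR ~ 10 with stored ground truth (seed 1)."""
    rng = np.random.default_rng(1)
    spots = [(float(x), float(y), 300.0) for x, y in rng.uniform(10, 54, (5, 2))]
    img = sd.generate_spot_image(spots, psf_sigma_px=1.5, background=100.0,
                                 poisson=True, gaussian_sd=2.0, seed=1)
    return img
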