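import numpy as np
import pandas as pd
import pytest

from cvikit import BScan, PixelScale, PhantomSpec, generate_scan


@pytest.fixture
def rng():
    return np.random.default_rng(20160212)


@pytest.fixture
def unit_scale():
    return PixelScale(lateral_um_per_px=1.0, axial_um_per_px=1.0)


@pytest.fixture
def spectralis_scale():
    # 8.9 mm scan over 768 columns; Spectralis axial pitch.
    return PixelScale(lateral_um_per_px=11.6, axial_um_per_px=3.87)


@pytest.fixture
def random_bscan(rng, unit_scale):
    return BScan(pixels=rng.uniform(size=(16, 16)), scale=unit_scale)


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom at default settings, shared across tests (read-only)."""
    return generate_scan(PhantomSpec(seed=7))


@pytest.fixture
def screening_cohort():
    """400 records with disjoint failing groups: 9 fail visual acuity,
    7 spherical equivalent, 6 glaucoma, 18 retinal disease, 15 scan quality;
    the remaining 345 pass every filter."""
    n = 400
    df = pd.DataFrame({
        "id": [f"P{i:03d}" for i in range(n)],
        "logmar_va": 0.0,
        "se_d": -1.0,
        "glaucoma_flag": 0,
        "retinal_disease_flag": 0,
        "scan_quality_db": 25.0,
        "sex_female": ([1] * 190 + [0] * 155 + [0] * 55),
    })
    df.loc[345:353, "logmar_va"] = 0.5             # 9 fail VA
    df.loc[354:360, "se_d"] = -7.0                 # 7 fail SE
    df.loc[361:366, "glaucoma_flag"] = 1           # 6 glaucoma
    df.loc[367:384, "retinal_disease_flag"] = 1    # 18 retinal disease
    df.loc[385:399, "scan_quality_db"] = 12.0      # 15 poor quality
    return df
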