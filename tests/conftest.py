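import numpy as np
import pytest

from aecphantom import (
    GE_PRISTINA,
    HvlModel,
    PhantomSpec,
    StudyConfig,
    apply_dosimetry,
    generate_study,
)
from aecphantom.synthetic_data import JitterModel


@pytest.fixture(scope="session")
def full_study():
    """Complete synthetic study (363 studies) with dose columns, seed 123."""
    table = generate_study(StudyConfig(seed=123))
    apply_dosimetry(table, hvl_model=HvlModel.default())
    return table


@pytest.fixture(scope="session")
def small_dm_study():
    """GE-only DM study over three thicknesses, no image rendering."""
    table = generate_study(StudyConfig(
        systems=(GE_PRISTINA,),
        thicknesses=(30.0, 45.0, 60.0),
        modalities=("DM",),
        seed=7,
        measure_images=False,
    ))
    apply_dosimetry(table, hvl_model=HvlModel.default())
    return table


@pytest.fixture
def phantom45():
    return PhantomSpec(pmma_thickness_mm=45.0)


@pytest.fixture
def planted_image():
    """Noise-free render helper: background 1000, insert 800, pitch 100 um."""
    def make(pitch_um=100.0, background=1000.0, insert=800.0, noise_sd=0.0,
             shape_mm=(90.0, 60.0), phantom=None, seed=0):
        phantom = phantom or PhantomSpec(pmma_thickness_mm=45.0)
        pitch_mm = pitch_um / 1000.0
        n_rows = int(round(shape_mm[0] / pitch_mm))
        n_cols = int(round(shape_mm[1] / pitch_mm))
        img = np.full((n_rows, n_cols), background, dtype=np.float64)
        depth, lateral = phantom.insert_offset_mm
        half = phantom.insert_side_mm / 2.0
        r0 = int(round((depth - half) / pitch_mm))
        r1 = int(round((depth + half) / pitch_mm))
        c0 = int(round(n_cols / 2.0 + (lateral - half) / pitch_mm))
        c1 = int(round(n_cols / 2.0 + (lateral + half) / pitch_mm))
        img[r0:r1, c0:c1] = insert
        if noise_sd > 0:
            rng = np.random.default_rng(seed)
            img += rng.normal(0.0, noise_sd, size=img.shape)
        return img
    return make
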