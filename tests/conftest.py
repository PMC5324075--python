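import numpy as np
import pytest

from histobridge import PhantomConfig, generate_section


def small_config(**overrides):
    """A fast 500x300 px section at 20 um/px; full geometry, scaled raster."""
    defaults = dict(
        seed=0,
        pixel_pitch_um=20.0,
        noise_sd=0.0,
        agglomerate_count=0,
        canal_spec=[],
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


@pytest.fixture(scope="session")
def noiseless_truth():
    """One representative noiseless phantom with every feature present."""
    return generate_section(
        small_config(
            seed=11,
            canal_spec=[0.5, 0.3],
            agglomerate_count=8,
            agglomerate_area_mm2=(0.02, 0.3),
        )
    )


@pytest.fixture(scope="session")
def noisy_truth():
    return generate_section(
        small_config(
            seed=12,
            noise_sd=10.0,
            canal_spec=[0.5],
            agglomerate_count=8,
            agglomerate_area_mm2=(0.02, 0.0),
        )
    )


@pytest.fixture()
def flat_frame():
    """A 10x10 all-cortical frame for hand-counted metric tests."""
    from histobridge import DefectGeometry, DefectROIs

    geom = DefectGeometry(
        drill_left=0,
        drill_right=10,
        periosteal_margin=np.zeros(10, dtype=int),
        endosteal_margin=np.full(10, 10),
        pixel_pitch_um=100.0,
    )
    cort = np.ones((10, 10), dtype=bool)
    med = np.zeros((10, 10), dtype=bool)
    return DefectROIs(cortical_mask=cort, medullary_mask=med, geometry=geom)
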