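import numpy as np
import pytest

from fsodt.dmd_patterns import DMDFrame, IlluminationSet, PlaneWaveSpec, SystemGeometry


@pytest.fixture(scope="session")
def geom():
    """A representative optical geometry: 4 mm objective, 2x DMD relay,
    785 nm light, immersion-oil background."""
    return SystemGeometry(
        objective_focal_length=4.0,
        magnification_dmd_to_bfp=2.0,
        wavelength=0.785,
        carrier_frequency=(0.03, 0.03),
        dmd_center=(4000.0, 4000.0),
        mirror_pitch=7.56,
        dmd_shape=(1080, 1920),
        illumination_na=1.0,
        detection_na=1.0,
        background_index=1.515,
    )


@pytest.fixture(scope="session")
def water_geom():
    return SystemGeometry(
        objective_focal_length=4.0,
        magnification_dmd_to_bfp=2.0,
        wavelength=0.785,
        carrier_frequency=(0.03, 0.03),
        dmd_center=(4000.0, 4000.0),
        mirror_pitch=7.56,
        dmd_shape=(1080, 1920),
        illumination_na=1.0,
        detection_na=1.0,
        background_index=1.333,
    )


def snap_beam(beam: PlaneWaveSpec, n: int, pitch: float, shrink: float = 0.98) -> PlaneWaveSpec:
    """Snap a beam frequency onto the FFT grid of an n x pitch field (keeps
    synthetic plane waves exactly periodic)."""
    df = 1.0 / (n * pitch)
    f = np.round(np.asarray(beam.object_frequency) * shrink / df) * df
    return PlaneWaveSpec(object_frequency=f, position_offset=beam.position_offset,
                         phase=beam.phase, amplitude=beam.amplitude)


def single_beam_illum(beams) -> IlluminationSet:
    """One-beam-per-frame illumination set without rendered mirror frames."""
    return IlluminationSet(
        frames=[DMDFrame(np.zeros((0, 0), np.uint8), []) for _ in beams],
        beams_per_frame=[[b] for b in beams],
    )
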