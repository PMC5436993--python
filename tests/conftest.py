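import numpy as np
import pytest

from capiflow import Calibration, PhantomSpec, VesselPhantom, generate_phantom, random_spec

CAL = Calibration(pixel_pitch_um=2.8, frame_rate=25.0, fov_area_mm2=1.776)


@pytest.fixture(scope="session")
def calibration():
    return CAL


@pytest.fixture(scope="session")
def bed_phantom():
    """A small random capillary-bed phantom with ground truth (shared)."""
    spec = random_spec(seed=7, frame_shape=(300, 300), n_frames=160, target_tvd=12.0)
    stack, truth = generate_phantom(spec)
    return spec, stack, truth


def straight_venule(velocity_um_s, seed=0, width_um=30.0, n_frames=170, noise_sd=2.0):
    """One near-horizontal wide vessel spanning the frame, for kymographs."""
    ctrl = tuple((120.0 + 0.05 * i, 10.0 + 110.0 * i) for i in range(5))
    cal = Calibration(pixel_pitch_um=2.8, frame_rate=25.0,
                      fov_area_mm2=240 * 476 * (2.8 / 1000.0) ** 2)
    spec = PhantomSpec(
        frame_shape=(240, 476),
        n_frames=n_frames,
        calibration=cal,
        vessels=(VesselPhantom(control_points=ctrl, width_um=width_um,
                               velocity_um_s=velocity_um_s),),
        seed=seed,
        noise_sd=noise_sd,
    )
    stack, truth = generate_phantom(spec)
    stack.stable_window = (0, n_frames)
    return stack, truth
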