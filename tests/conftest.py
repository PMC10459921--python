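import numpy as np
import pytest

from fpmdetect.optics import (
    CoherentTransferFunction,
    LEDArray,
    simulate_stack,
)
from fpmdetect.phantom import PhantomConfig, generate_scene, render_highres


@pytest.fixture(scope="session")
def small_scene():
    cfg = PhantomConfig(field_of_view=51.2, n_wbc=2, n_rbc=15, overlap_prob=0.2)
    return generate_scene(cfg, seed=3)


@pytest.fixture(scope="session")
def green_field(small_scene):
    return render_highres(small_scene, 128, "green")


@pytest.fixture(scope="session")
def led_7x7():
    return LEDArray(rows=7, cols=7, wavelengths={"green": 0.532})


@pytest.fixture(scope="session")
def green_ctf(green_field):
    return CoherentTransferFunction(
        na=0.1, wavelength=0.532, grid_side=green_field.side,
        pixel_pitch_highres=green_field.pixel_pitch,
    )


@pytest.fixture(scope="session")
def green_stack(green_field, led_7x7, green_ctf):
    return simulate_stack(
        {"green": green_field}, led_7x7, {"green": green_ctf}, ratio=4
    )


@pytest.fixture(scope="session")
def rgb_stack(small_scene, led_7x7):
    wavelengths = {"red": 0.632, "green": 0.532, "blue": 0.470}
    array = LEDArray(rows=3, cols=3, wavelengths=wavelengths)
    fields = {ch: render_highres(small_scene, 64, ch) for ch in wavelengths}
    ctfs = {
        ch: CoherentTransferFunction(
            na=0.1, wavelength=wavelengths[ch], grid_side=64,
            pixel_pitch_highres=fields[ch].pixel_pitch,
        )
        for ch in wavelengths
    }
    return simulate_stack(fields, array, ctfs, ratio=4)
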