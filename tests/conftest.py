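import numpy as np
import pytest

from gelkit import synthetic as syn


@pytest.fixture
def three_lane_spec():
    """A clean 3-lane gel: distinct band patterns, mild noise, SNR >= 10."""
    lanes = [
        syn.LaneSpec(x_center=150, width=40, name="A", bands=[
            syn.BandSpec(y_center=80, peak_intensity=180, sigma=2.5),
            syn.BandSpec(y_center=160, peak_intensity=160, sigma=2.5),
            syn.BandSpec(y_center=260, peak_intensity=170, sigma=2.5),
        ]),
        syn.LaneSpec(x_center=450, width=40, name="B", bands=[
            syn.BandSpec(y_center=80, peak_intensity=175, sigma=2.5),
            syn.BandSpec(y_center=210, peak_intensity=165, sigma=2.5),
        ]),
        syn.LaneSpec(x_center=750, width=40, name="C", bands=[
            syn.BandSpec(y_center=160, peak_intensity=170, sigma=2.5),
            syn.BandSpec(y_center=260, peak_intensity=180, sigma=2.5),
        ]),
    ]
    return syn.GelSpec(width_px=1000, height_px=340, lanes=lanes,
                       background_level=20, background_gradient=0.02,
                       noise_sigma=5.0, seed=11)


@pytest.fixture
def three_lane_gel(three_lane_spec):
    return syn.generate_gel(three_lane_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
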