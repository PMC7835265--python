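"""Synthetic gel-image generator with exact ground truth.

Renders idealised but realistic 1-D electrophoresis images: vertical (or
tilted) lanes on a dark background, each lane carrying bands with Gaussian
vertical profiles, a linear per-row background gradient and additive Gaussian
pixel noise.  Every rendered lane and band is recorded in a
:class:`GroundTruth` object, so detection, densitometry, calibration and all
downstream fingerprint statistics can be validated against known answers.

Conventions: 0-based row-major pixels, y increasing downward (wells at the
top, migration downward), half-open intervals ``[lo, hi)``, bands brighter
than background.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .image import BANDS_BRIGHT, GelImage


@dataclass
class BandSpec:
    """One band: Gaussian in y, uniform across the lane width."""

    y_center: float
    peak_intensity: float = 150.0
    sigma: float = 2.5
    mw: float | None = None


@dataclass
class LaneSpec:
    """One lane: x interval centred on `x_center`, optionally tilted.

    `tilt` is the horizontal offset (px) of the lane at the bottom edge
    relative to the top edge; edges stay straight (a quadrilateral lane).
    """

    x_center: float
    width: float
    tilt: float = 0.0
    name: str = ""
    bands: list = field(default_factory=list)

    def x_interval(self, frac: float) -> tuple[int, int]:
        """Half-open column interval at fractional depth `frac` in [0, 1]."""
        lo = int(round(self.x_center - self.width / 2 + frac * self.tilt))
        return lo, lo + int(round(self.width))


@dataclass
class GelSpec:
    width_px: int
    height_px: int
    lanes: list = field(default_factory=list)
    background_level: float = 20.0
    background_gradient: float = 0.0  # per-row additive slope
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class TruthBand:
    lane_index: int
    y_center: float
    integrated_signal: float
    mw: float | None = None


@dataclass
class TruthLane:
    index: int
    x_top: tuple[int, int]
    x_bottom: tuple[int, int]
    name: str = ""


@dataclass
class GroundTruth:
    lanes: list
    bands: list

    def to_json(self) -> str:
        return json.dumps(
            {
                "lanes": [vars(l).copy() for l in self.lanes],
                "bands": [vars(b).copy() for b in self.bands],
            },
            sort_keys=True,
        )


def _validate(spec: GelSpec) -> None:
    H, W = spec.height_px, spec.width_px
    if H < 1 or W < 1:
        raise ValueError("image dimensions must be positive")
    intervals = []
    for i, lane in enumerate(spec.lanes):
        top = lane.x_interval(0.0)
        bot = lane.x_interval(1.0)
        for lo, hi in (top, bot):
            if lo < 0 or hi > W or hi <= lo:
                raise ValueError(f"lane {i} x-range [{lo}, {hi}) outside image")
        intervals.append((top, bot))
        for band in lane.bands:
            if not (0 <= band.y_center < H):
                raise ValueError(
                    f"band at y={band.y_center} outside lane {i} (image height {H})"
                )
    for i in range(len(intervals)):
        for j in range(i + 1, len(intervals)):
            for k in range(2):  # top edge, bottom edge
                a, b = intervals[i][k], intervals[j][k]
                if a[0] < b[1] and b[0] < a[1]:
                    raise ValueError(f"lanes {i} and {j} overlap")


def generate_gel(spec: GelSpec) -> tuple[GelImage, GroundTruth]:
    """Render `spec` into an image and its exact ground truth.

    The noiseless signal is ``background + sum of band profiles``; Gaussian
    noise of ``spec.noise_sigma`` is then added and the result clamped to
    [0, 255].  Identical spec + seed gives a bit-identical image.
    """
    _validate(spec)
    H, W = spec.height_px, spec.width_px
    rows = np.arange(H, dtype=float)
    canvas = np.tile(
        (spec.background_level + spec.background_gradient * rows)[:, None], (1, W)
    )
    truth_lanes, truth_bands = [], []
    for i, lane in enumerate(spec.lanes):
        profile = np.zeros(H)
        per_band = []
        for band in lane.bands:
            p = band.peak_intensity * np.exp(
                -0.5 * ((rows - band.y_center) / band.sigma) ** 2
            )
            per_band.append(p)
            profile += p
        # paint row by row so tilted lanes shift their column interval
        widths = np.empty(H)
        for r in range(H):
            lo, hi = lane.x_interval(r / (H - 1) if H > 1 else 0.0)
            canvas[r, lo:hi] += profile[r]
            widths[r] = hi - lo
        truth_lanes.append(
            TruthLane(index=i, x_top=lane.x_interval(0.0),
                      x_bottom=lane.x_interval(1.0), name=lane.name)
        )
        for band, p in zip(lane.bands, per_band):
            truth_bands.append(
                TruthBand(lane_index=i, y_center=band.y_center,
                          integrated_signal=float(np.sum(p * widths)),
                          mw=band.mw)
            )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    img = GelImage(pixels=pixels, polarity=BANDS_BRIGHT,
                   provenance=[{"op": "synthetic", "seed": spec.seed}])
    return img, GroundTruth(lanes=truth_lanes, bands=truth_bands)


@dataclass
class LogLinearMap:
    """Migration model: relative mobility linear in log10(size).

    Anchored at two points: size `mw_a` migrates to `rf_a`, `mw_b` to `rf_b`
    (``mw_a > mw_b``, ``rf_a < rf_b`` — big molecules move least).
    """

    rf_a: float = 0.1
    mw_a: float = 10000.0
    rf_b: float = 0.9
    mw_b: float = 100.0

    def rf_of(self, mw: float) -> float:
        la, lb = math.log10(self.mw_a), math.log10(self.mw_b)
        return self.rf_a + (self.rf_b - self.rf_a) * (la - math.log10(mw)) / (la - lb)


def generate_ladder_lane(
    mw_list,
    calibration_model: LogLinearMap,
    height_px: int,
    x_center: float = 30.0,
    width: float = 30.0,
    peak_intensity: float = 180.0,
    sigma: float = 2.5,
    name: str = "ladder",
) -> LaneSpec:
    """Place ladder bands so Rf -> size calibration recovers `mw_list`.

    Band y positions follow the log-linear migration model over the lane's
    full height: ``y = rf * (height_px - 1)``, matching the Rf convention of
    :func:`gelkit.quantify.compute_rf` (well at the first row, front at the
    last row).
    """
    mws = list(mw_list)
    if any(b >= a for a, b in zip(mws, mws[1:])):
        raise ValueError("mw_list must be strictly decreasing")
    bands = []
    for mw in mws:
        rf = calibration_model.rf_of(mw)
        if not (0.0 < rf < 1.0):
            raise ValueError(f"size {mw} maps to Rf {rf:.3f} outside (0, 1)")
        bands.append(
            BandSpec(y_center=rf * (height_px - 1), peak_intensity=peak_intensity,
                     sigma=sigma, mw=mw)
        )
    return LaneSpec(x_center=x_center, width=width, name=name, bands=bands)


def random_gel_spec(
    rng: np.random.Generator,
    n_lanes: int | None = None,
    bands_per_lane: tuple[int, int] = (2, 10),
    width_px: int = 1000,
    height_px: int = 500,
    lane_width: float = 40.0,
    noise_sigma: float = 5.0,
    lane_loading: float = 470.0,
    sigma_range: tuple[float, float] = (2.0, 3.0),
) -> GelSpec:
    """Draw a random but detection-valid gel layout.

    Defaults reflect a well-run gel photographed at moderate resolution:
    3-8 well-separated lanes, 2-10 bands per lane with centre-to-centre
    spacing of at least five band widths, and peak signal-to-noise >= 10.
    Lanes follow an equal-loading model: the total signal per lane is
    roughly constant (`lane_loading` grey levels split across its bands),
    as when the same amount of sample is loaded in every well, with each
    band's peak clamped into [10 x noise_sigma, 235] so the weakest band
    keeps SNR >= 10 and the brightest stays below saturation.
    """
    if n_lanes is None:
        n_lanes = int(rng.integers(3, 9))
    margin = 30
    slot = (width_px - 2 * margin) / n_lanes
    if slot < lane_width + 10:
        raise ValueError("too many lanes for the image width")
    lanes = []
    for i in range(n_lanes):
        x_center = margin + slot * (i + 0.5)
        n_bands = int(rng.integers(bands_per_lane[0], bands_per_lane[1] + 1))
        sigmas = rng.uniform(*sigma_range, size=n_bands)
        min_sep = max(12.0, 5.0 * float(sigmas.max()))
        lo, hi = 25.0, height_px - 25.0
        # rejection-free placement: jitter a regular grid that always fits
        max_fit = int((hi - lo) / min_sep) + 1
        n_bands = min(n_bands, max_fit)
        base = np.linspace(lo, hi, n_bands)
        slack = max((hi - lo) / max(n_bands - 1, 1) - min_sep, 0.0)
        amp = min(0.3 * slack, 20.0)  # keep jittered bands inside [lo, hi]
        jitter = rng.uniform(-amp, amp, size=n_bands)
        centers = np.sort(np.clip(base + jitter, lo, hi))
        peak_base = rng.uniform(0.85, 1.0) * lane_loading / n_bands
        peaks = np.clip(peak_base * rng.uniform(0.9, 1.1, size=n_bands),
                        max(10.0 * noise_sigma, 40.0), 235.0)
        bands = [
            BandSpec(y_center=float(c), peak_intensity=float(p), sigma=float(s))
            for c, p, s in zip(centers, peaks, sigmas[:n_bands])
        ]
        lanes.append(LaneSpec(x_center=x_center, width=lane_width,
                              name=f"S{i + 1}", bands=bands))
    return GelSpec(width_px=width_px, height_px=height_px, lanes=lanes,
                   background_level=20.0, background_gradient=0.02,
                   noise_sigma=noise_sigma, seed=int(rng.integers(2**31)))
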