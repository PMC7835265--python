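"""Automatic lane/band detection and the manual-edit vocabulary.

Lanes are found as plateaus in the baseline-subtracted column intensity
profile; bands as prominent peaks in each lane's row profile.  On top of the
automatic detector sits the full manual-edit vocabulary: add, remove, resize
and tilt for lanes; add, remove and resize for bands; and split/merge for
both.  Any change to lane geometry triggers automatic band re-detection in
the affected lanes; band-level edits do not.

Pixel conventions: 0-based, y downward, half-open intervals ``[lo, hi)``.
A tilted lane is a straight-edged quadrilateral whose x interval is linearly
interpolated per row between its top and bottom intervals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import minimum_filter1d, uniform_filter1d

from .image import BANDS_BRIGHT, GelImage

_ids = itertools.count(1)


def _next_id() -> int:
    return next(_ids)


@dataclass
class Band:
    """A detected (or user-drawn) band within one lane.

    Densitometry fields (`density`, `rf`, `mw`, `quantity`) start as ``None``
    and are filled in by :mod:`gelkit.quantify`.
    """

    y_top: float
    y_center: float
    y_bottom: float
    lane_id: int = 0
    id: int = field(default_factory=_next_id)
    density: float | None = None
    rf: float | None = None
    mw: float | None = None
    quantity: float | None = None

    def __post_init__(self):
        if not (self.y_top <= self.y_center <= self.y_bottom):
            raise ValueError("band must satisfy y_top <= y_center <= y_bottom")


@dataclass
class Lane:
    """A lane: half-open x intervals at the top and bottom image edges.

    `x_top == x_bottom` for an untilted lane.  `y_range` defaults to the
    full image height.
    """

    x_top: tuple[int, int]
    x_bottom: tuple[int, int] | None = None
    y_range: tuple[int, int] | None = None
    sample_name: str = ""
    id: int = field(default_factory=_next_id)
    bands: list = field(default_factory=list)

    def __post_init__(self):
        self.x_top = (int(self.x_top[0]), int(self.x_top[1]))
        if self.x_bottom is None:
            self.x_bottom = self.x_top
        else:
            self.x_bottom = (int(self.x_bottom[0]), int(self.x_bottom[1]))
        for lo, hi in (self.x_top, self.x_bottom):
            if hi <= lo:
                raise ValueError("lane x interval must be non-empty")

    def x_interval_at(self, row: float, height: int) -> tuple[int, int]:
        """Linearly interpolated column interval at `row`."""
        frac = row / (height - 1) if height > 1 else 0.0
        lo = self.x_top[0] + frac * (self.x_bottom[0] - self.x_top[0])
        hi = self.x_top[1] + frac * (self.x_bottom[1] - self.x_top[1])
        return int(round(lo)), int(round(hi))

    @property
    def tilted(self) -> bool:
        return self.x_top != self.x_bottom


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class LaneSet:
    """The lanes of one gel, kept pairwise non-overlapping at both edges."""

    lanes: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for a, b in itertools.combinations(self.lanes, 2):
            if _overlap(a.x_top, b.x_top) or _overlap(a.x_bottom, b.x_bottom):
                raise ValueError(
                    f"lanes {a.id} and {b.id} overlap: {a.x_top}/{b.x_top}"
                )

    def __iter__(self):
        return iter(self.lanes)

    def __len__(self):
        return len(self.lanes)

    def get(self, lane_id: int) -> Lane:
        for lane in self.lanes:
            if lane.id == lane_id:
                return lane
        raise KeyError(f"no lane with id {lane_id}")

    def sorted(self) -> "LaneSet":
        return LaneSet(sorted(self.lanes, key=lambda l: l.x_top[0]))


@dataclass
class Profile:
    """A 1-D baseline-subtracted, smoothed mean-intensity profile."""

    axis: str  # "column" | "row"
    values: np.ndarray
    smoothing_window: int = 3


def _baseline_subtract(raw: np.ndarray, window: int, smooth: int = 3) -> np.ndarray:
    baseline = minimum_filter1d(raw, size=window, mode="nearest")
    vals = np.clip(raw - baseline, 0.0, None)
    if smooth > 1:
        vals = uniform_filter1d(vals, size=smooth, mode="nearest")
    return vals


def column_profile(img: GelImage, smoothing_window: int = 3) -> Profile:
    """Mean intensity per column, baseline-subtracted and lightly smoothed.

    The baseline is a rolling minimum with a window of 5% of the image width
    (at least 3 px), which removes both a constant offset and the slow
    background gradient while leaving lane plateaus narrower than the window
    intact.
    """
    if not img.is_grayscale:
        raise ValueError("column_profile requires a grayscale image")
    if img.polarity != BANDS_BRIGHT:
        raise ValueError("column_profile requires bands-bright polarity; invert first")
    raw = img.pixels.mean(axis=0).astype(float)
    window = max(3, int(round(0.05 * img.width)))
    return Profile("column", _baseline_subtract(raw, window, smoothing_window),
                   smoothing_window)


def _row_profile_raw(img: GelImage, lane: Lane) -> np.ndarray:
    y0, y1 = lane.y_range if lane.y_range is not None else (0, img.height)
    raw = np.zeros(img.height)
    for r in range(y0, y1):
        lo, hi = lane.x_interval_at(r, img.height)
        lo, hi = max(lo, 0), min(hi, img.width)
        if hi > lo:
            raw[r] = img.pixels[r, lo:hi].mean()
    return raw


def row_profile(img: GelImage, lane: Lane, smoothing_window: int = 3) -> Profile:
    """Mean intensity per row within the (possibly tilted) lane."""
    if not img.is_grayscale:
        raise ValueError("row_profile requires a grayscale image")
    raw = _row_profile_raw(img, lane)
    window = max(3, int(round(0.05 * img.height)))
    return Profile("row", _baseline_subtract(raw, window, smoothing_window),
                   smoothing_window)


def detect_lanes(img: GelImage, min_lane_width: int = 5,
                 threshold_frac: float = 0.2) -> LaneSet:
    """Find lanes as thresholded runs of the column profile.

    Runs of columns whose profile is at least ``threshold_frac`` of the
    profile maximum become lanes; runs narrower than `min_lane_width` are
    discarded and runs separated by gaps narrower than ``min_lane_width / 2``
    are merged.  Lanes come back left-to-right, untilted, spanning the full
    image height.

    Degenerate case: a single lane filling the whole width produces a flat
    column profile (indistinguishable from a blank image by columns alone);
    if the whole-image row profile nevertheless shows band structure, one
    full-width lane is returned.
    """
    prof = column_profile(img)
    vals = prof.values
    if vals.max() <= 1e-9:
        whole = Lane(x_top=(0, img.width), y_range=(0, img.height))
        rp = row_profile(img, whole)
        if rp.values.max() > 1.0:  # bands present but no column contrast
            whole.bands = detect_bands(img, whole)
            return LaneSet([whole])
        return LaneSet([])
    mask = vals >= threshold_frac * vals.max()
    runs = []
    in_run = False
    for x, m in enumerate(mask):
        if m and not in_run:
            start, in_run = x, True
        elif not m and in_run:
            runs.append([start, x])
            in_run = False
    if in_run:
        runs.append([start, len(mask)])
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_lane_width / 2:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    lanes = [
        Lane(x_top=(lo, hi), y_range=(0, img.height))
        for lo, hi in merged
        if hi - lo >= min_lane_width
    ]
    for lane in lanes:
        lane.bands = detect_bands(img, lane)
    return LaneSet(lanes)


def detect_bands(img: GelImage, lane: Lane, min_prominence_frac: float = 0.1,
                 min_separation: int = 3) -> list:
    """Find bands as prominent peaks of the lane's row profile.

    Peaks need prominence of at least ``min_prominence_frac`` times the
    profile maximum and pairwise separation of at least `min_separation`
    rows.  Band extents (`y_top`, `y_bottom`) are taken at the
    half-prominence crossings, the conventional half-height band width.
    """
    for lo, hi in (lane.x_top, lane.x_bottom):
        if lo < 0 or hi > img.width:
            raise ValueError("lane lies outside the image")
    prof = row_profile(img, lane)
    vals = prof.values
    if vals.max() <= 1e-9:
        return []
    peaks, props = signal.find_peaks(
        vals, prominence=min_prominence_frac * vals.max(),
        distance=max(1, int(min_separation)),
    )
    if len(peaks) == 0:
        return []
    widths, _, left_ips, right_ips = signal.peak_widths(
        vals, peaks, rel_height=0.5,
        prominence_data=(props["prominences"], props["left_bases"],
                         props["right_bases"]),
    )
    bands = []
    for p, lo_ip, hi_ip in zip(peaks, left_ips, right_ips):
        bands.append(Band(y_top=float(lo_ip), y_center=float(p),
                          y_bottom=float(hi_ip), lane_id=lane.id))
    bands.sort(key=lambda b: b.y_center)
    return bands


# ---------------------------------------------------------------------------
# lane edits (geometry changes re-detect bands)
# ---------------------------------------------------------------------------

def _redetect(img: GelImage, lane: Lane, **detect_kwargs) -> Lane:
    lane.bands = detect_bands(img, lane, **detect_kwargs)
    return lane


def split_lane(img: GelImage, lanes: LaneSet, lane_id: int, x_split: int,
               **detect_kwargs) -> LaneSet:
    """Split one lane into two at column `x_split` (strictly inside it).

    Tilt offsets are interpolated proportionally; bands of both new lanes
    are re-detected.
    """
    lane = lanes.get(lane_id)
    lo, hi = lane.x_top
    if not (lo < x_split < hi):
        raise ValueError(f"x_split {x_split} not strictly inside [{lo}, {hi})")
    frac = (x_split - lo) / (hi - lo)
    blo, bhi = lane.x_bottom
    b_split = int(round(blo + frac * (bhi - blo)))
    b_split = min(max(b_split, blo + 1), bhi - 1) if bhi - blo > 1 else bhi
    left = Lane(x_top=(lo, x_split), x_bottom=(blo, b_split),
                y_range=lane.y_range, sample_name=lane.sample_name)
    right = Lane(x_top=(x_split, hi), x_bottom=(b_split, bhi),
                 y_range=lane.y_range, sample_name="")
    _redetect(img, left, **detect_kwargs)
    _redetect(img, right, **detect_kwargs)
    others = [l for l in lanes if l.id != lane_id]
    return LaneSet(others + [left, right]).sorted()


def merge_lanes(img: GelImage, lanes: LaneSet, ids, **detect_kwargs) -> LaneSet:
    """Merge two or more lanes into one spanning their hull; bands re-detected."""
    ids = list(ids)
    if len(ids) < 2:
        raise ValueError("merging needs at least two lane ids")
    members = [lanes.get(i) for i in ids]
    top = (min(l.x_top[0] for l in members), max(l.x_top[1] for l in members))
    bot = (min(l.x_bottom[0] for l in members), max(l.x_bottom[1] for l in members))
    merged = Lane(x_top=top, x_bottom=bot, y_range=members[0].y_range,
                  sample_name=members[0].sample_name)
    _redetect(img, merged, **detect_kwargs)
    others = [l for l in lanes if l.id not in ids]
    return LaneSet(others + [merged]).sorted()


def edit_lane(img: GelImage, lanes: LaneSet, action: str, *, lane_id: int = None,
              x_top: tuple = None, x_bottom: tuple = None, y_range: tuple = None,
              sample_name: str = "", **detect_kwargs) -> LaneSet:
    """Apply one manual lane edit: ``add``, ``remove``, ``resize`` or ``set_tilt``.

    All edits are validated against the no-overlap invariant; geometry edits
    re-detect the affected lane's bands.
    """
    if action == "add":
        if x_top is None:
            raise ValueError("add requires x_top")
        lane = Lane(x_top=x_top, x_bottom=x_bottom,
                    y_range=y_range or (0, img.height), sample_name=sample_name)
        _redetect(img, lane, **detect_kwargs)
        return LaneSet(list(lanes) + [lane]).sorted()
    if action == "remove":
        lanes.get(lane_id)  # raise if unknown
        return LaneSet([l for l in lanes if l.id != lane_id])
    if action in ("resize", "set_tilt"):
        lane = lanes.get(lane_id)
        new = replace(lane, x_top=x_top if x_top is not None else lane.x_top,
                      x_bottom=x_bottom if x_bottom is not None else
                      (x_top if action == "resize" and x_bottom is None and x_top is not None
                       else lane.x_bottom),
                      y_range=y_range if y_range is not None else lane.y_range,
                      bands=[])
        _redetect(img, new, **detect_kwargs)
        return LaneSet([l for l in lanes if l.id != lane_id] + [new]).sorted()
    raise ValueError(f"unknown lane action {action!r}")


# ---------------------------------------------------------------------------
# band edits (never trigger re-detection)
# ---------------------------------------------------------------------------

def _check_band_overlap(bands) -> None:
    bands = sorted(bands, key=lambda b: b.y_top)
    for a, b in zip(bands, bands[1:]):
        if b.y_top < a.y_bottom:
            raise ValueError(f"bands {a.id} and {b.id} overlap in y")


def split_band(lane: Lane, band_id: int, y_split: float) -> Lane:
    """Split one band into two at `y_split` (strictly inside its extent).

    Each half's centre is the midpoint of its new extent.
    """
    band = next((b for b in lane.bands if b.id == band_id), None)
    if band is None:
        raise KeyError(f"no band with id {band_id}")
    if not (band.y_top < y_split < band.y_bottom):
        raise ValueError("y_split must lie strictly inside the band extent")
    upper = Band(y_top=band.y_top, y_center=(band.y_top + y_split) / 2,
                 y_bottom=y_split, lane_id=lane.id)
    lower = Band(y_top=y_split, y_center=(y_split + band.y_bottom) / 2,
                 y_bottom=band.y_bottom, lane_id=lane.id)
    new_bands = [b for b in lane.bands if b.id != band_id] + [upper, lower]
    new_bands.sort(key=lambda b: b.y_center)
    return replace(lane, bands=new_bands)


def merge_bands(lane: Lane, band_ids) -> Lane:
    """Merge two or more bands of one lane into a single band.

    The merged extent is the hull; the centre is the density-weighted
    centroid of the members (extent midpoint when densities are absent),
    preserving the first moment of the signal.
    """
    ids = list(band_ids)
    if len(ids) < 2:
        raise ValueError("merging needs at least two band ids")
    members = []
    for bid in ids:
        band = next((b for b in lane.bands if b.id == bid), None)
        if band is None:
            raise ValueError(f"band {bid} does not belong to lane {lane.id}")
        members.append(band)
    y_top = min(b.y_top for b in members)
    y_bottom = max(b.y_bottom for b in members)
    if all(b.density is not None for b in members) and sum(
            b.density for b in members) > 0:
        total = sum(b.density for b in members)
        y_center = sum(b.density * b.y_center for b in members) / total
        density = total
    else:
        y_center = (y_top + y_bottom) / 2
        density = None
    merged = Band(y_top=y_top, y_center=y_center, y_bottom=y_bottom,
                  lane_id=lane.id, density=density)
    new_bands = [b for b in lane.bands if b.id not in ids] + [merged]
    new_bands.sort(key=lambda b: b.y_center)
    return replace(lane, bands=new_bands)


def edit_band(lane: Lane, action: str, *, band_id: int = None,
              y_top: float = None, y_bottom: float = None) -> Lane:
    """Apply one manual band edit: ``add``, ``remove`` or ``resize``."""
    if action == "add":
        if y_top is None or y_bottom is None:
            raise ValueError("add requires y_top and y_bottom")
        band = Band(y_top=y_top, y_center=(y_top + y_bottom) / 2,
                    y_bottom=y_bottom, lane_id=lane.id)
        new_bands = sorted(lane.bands + [band], key=lambda b: b.y_center)
        _check_band_overlap(new_bands)
        return replace(lane, bands=new_bands)
    if action == "remove":
        if not any(b.id == band_id for b in lane.bands):
            raise KeyError(f"no band with id {band_id}")
        return replace(lane, bands=[b for b in lane.bands if b.id != band_id])
    if action == "resize":
        band = next((b for b in lane.bands if b.id == band_id), None)
        if band is None:
            raise KeyError(f"no band with id {band_id}")
        new = replace(band, y_top=y_top, y_bottom=y_bottom,
                      y_center=(y_top + y_bottom) / 2)
        new_bands = sorted([b for b in lane.bands if b.id != band_id] + [new],
                           key=lambda b: b.y_center)
        _check_band_overlap(new_bands)
        return replace(lane, bands=new_bands)
    raise ValueError(f"unknown band action {action!r}")
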