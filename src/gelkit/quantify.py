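"""Per-band densitometry outputs and the presence/absence fingerprint.

Implements the classical 1-D gel outputs: relative mobility (Rf), molecular
weight/size from a ladder calibration (piecewise-linear in Rf vs log10 size),
band density (baseline-corrected summed intensity), quantity by linear
proportionality to a reference band, the band-class x sample presence/absence
matrix, and the polymorphism percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import minimum_filter1d

from .detection import Band, Lane, _row_profile_raw
from .image import BANDS_BRIGHT, GelImage


class ExtrapolationWarning(UserWarning):
    """Rf queried outside the calibrated ladder range."""


def compute_rf(band: Band, lane: Lane, y_well: float | None = None,
               y_front: float | None = None) -> float:
    """Relative mobility of a band within its lane.

    ``rf = (y_center - y_well) / (y_front - y_well)``, in [0, 1].  The well
    and front default to the lane's top row and last row; pass explicit
    positions when the loading well or dye front was located elsewhere.
    """
    y0, y1 = lane.y_range if lane.y_range is not None else (0, int(band.y_bottom) + 1)
    if y_well is None:
        y_well = y0
    if y_front is None:
        y_front = y1 - 1  # last row of the lane
    if y_front <= y_well:
        raise ValueError("y_front must exceed y_well")
    if not (y_well <= band.y_center <= y_front):
        raise ValueError("band centre outside [y_well, y_front]")
    return (band.y_center - y_well) / (y_front - y_well)


@dataclass
class Calibration:
    """Ladder calibration: piecewise-linear interpolation of log10(MW) vs Rf."""

    knots: list  # (rf, mw), rf strictly increasing, mw strictly decreasing

    def __post_init__(self):
        if len(self.knots) < 2:
            raise ValueError("calibration needs at least 2 knots")
        rfs = [k[0] for k in self.knots]
        mws = [k[1] for k in self.knots]
        if any(m <= 0 for m in mws):
            raise ValueError("molecular weights must be positive")
        if any(b <= a for a, b in zip(rfs, rfs[1:])):
            raise ValueError("knot Rf values must be strictly increasing")
        if any(b >= a for a, b in zip(mws, mws[1:])):
            raise ValueError("knot MW values must be strictly decreasing")

    def estimate_mw(self, rf: float) -> float:
        """Size estimate at `rf`; warns when extrapolating beyond the knots.

        Outside the calibrated range the end segment is extended linearly in
        log space and an :class:`ExtrapolationWarning` is emitted.
        """
        rfs = np.array([k[0] for k in self.knots])
        logs = np.log10([k[1] for k in self.knots])
        if rf < rfs[0] or rf > rfs[-1]:
            warnings.warn(
                f"Rf {rf:.4f} outside calibrated range [{rfs[0]:.4f}, {rfs[-1]:.4f}];"
                " extrapolating", ExtrapolationWarning, stacklevel=2)
            seg = (0, 1) if rf < rfs[0] else (len(rfs) - 2, len(rfs) - 1)
        else:
            i = int(np.searchsorted(rfs, rf, side="right")) - 1
            i = min(max(i, 0), len(rfs) - 2)
            seg = (i, i + 1)
        i, j = seg
        slope = (logs[j] - logs[i]) / (rfs[j] - rfs[i])
        return float(10 ** (logs[i] + slope * (rf - rfs[i])))

    def is_extrapolated(self, rf: float) -> bool:
        return rf < self.knots[0][0] or rf > self.knots[-1][0]


def fit_ladder(ladder_bands, known_mws) -> Calibration:
    """Build a :class:`Calibration` from ladder bands with Rf attached.

    `known_mws` must be strictly decreasing (largest fragment nearest the
    well) and match the bands one-to-one in migration order.
    """
    rfs = [b.rf for b in ladder_bands]
    if any(r is None for r in rfs):
        raise ValueError("ladder bands must carry Rf values (run compute_rf first)")
    if len(rfs) != len(known_mws):
        raise ValueError("band count does not match the ladder size list")
    return Calibration(knots=list(zip(rfs, known_mws)))


def band_density(img: GelImage, lane: Lane, band: Band) -> float:
    """Baseline-corrected summed intensity over the band rectangle.

    The rectangle is the lane's x interval crossed with ``[y_top, y_bottom]``.
    The per-row baseline is a rolling minimum of the lane's raw row profile
    (window 5% of image height, at least 3), and each pixel contributes
    ``max(0, value - baseline[row])``.
    """
    if img.polarity != BANDS_BRIGHT:
        raise ValueError("band_density requires bands-bright polarity")
    if band.lane_id != lane.id:
        raise ValueError(f"band {band.id} does not belong to lane {lane.id}")
    raw = _row_profile_raw(img, lane)
    window = max(3, int(round(0.05 * img.height)))
    baseline = minimum_filter1d(raw, size=window, mode="nearest")
    y0 = max(int(np.floor(band.y_top)), 0)
    y1 = min(int(np.ceil(band.y_bottom)), img.height - 1)
    total = 0.0
    for r in range(y0, y1 + 1):
        lo, hi = lane.x_interval_at(r, img.height)
        lo, hi = max(lo, 0), min(hi, img.width)
        if hi > lo:
            vals = img.pixels[r, lo:hi].astype(float) - baseline[r]
            total += float(np.clip(vals, 0.0, None).sum())
    return total


def estimate_quantity(density: float, reference: tuple[float, float]) -> float:
    """Quantity by linear proportionality to one reference band.

    `reference` is ``(density_ref, known_quantity_ref)``; the returned value
    shares the reference's units (e.g. ng of DNA).
    """
    density_ref, known_quantity_ref = reference
    if density_ref <= 0 or known_quantity_ref <= 0:
        raise ValueError("reference density and quantity must be positive")
    return density * known_quantity_ref / density_ref


@dataclass
class BandClass:
    """One matched band class across samples."""

    value: float  # representative MW or Rf: arithmetic mean of members
    members: list  # (sample_name, band_value) or (gel, sample, value)


@dataclass
class PresenceMatrix:
    """Binary band-class x sample table — the fingerprint representation."""

    band_classes: list
    samples: list
    entries: np.ndarray  # (n_classes, n_samples) of 0/1
    basis: str = "mw"

    @property
    def class_values(self):
        return [c.value for c in self.band_classes]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.class_values,
                            columns=self.samples)


def _greedy_classes(items, tolerance):
    """Greedy single-pass clustering of (sort_key-ordered) (sample, value) items.

    A band joins the open class iff its value is within `tolerance` of the
    class's running mean and its sample is not yet represented; otherwise a
    new class opens.
    """
    classes = []
    current, mean = None, None
    for sample, value, payload in items:
        if current is not None and abs(value - mean) <= tolerance and \
                sample not in {s for s, _, _ in current}:
            current.append((sample, value, payload))
            mean = sum(v for _, v, _ in current) / len(current)
        else:
            if current:
                classes.append(current)
            current, mean = [(sample, value, payload)], value
    if current:
        classes.append(current)
    return classes


def build_presence_matrix(lanes, tolerance: float = 0.0,
                          basis: str = "mw") -> PresenceMatrix:
    """Pool bands across lanes and match them into classes by MW or Rf.

    Bands are sorted by the basis value and clustered greedily: a band joins
    the open class iff it is within `tolerance` of the class mean and its
    lane has no member there yet.  Entry (class, sample) is 1 iff the lane
    contributed a band.
    """
    if basis not in ("mw", "rf"):
        raise ValueError("basis must be 'mw' or 'rf'")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    samples = [lane.sample_name or f"lane{idx}" for idx, lane in enumerate(lanes)]
    items = []
    for sample, lane in zip(samples, lanes):
        for band in lane.bands:
            value = getattr(band, basis)
            if value is None:
                raise ValueError(
                    f"band {band.id} in lane {lane.id} lacks a {basis} value")
            items.append((sample, float(value), None))
    items.sort(key=lambda t: (t[1], samples.index(t[0])))
    groups = _greedy_classes(items, tolerance)
    classes = [BandClass(value=sum(v for _, v, _ in g) / len(g),
                         members=[(s, v) for s, v, _ in g]) for g in groups]
    classes.sort(key=lambda c: c.value)
    entries = np.zeros((len(classes), len(samples)), dtype=int)
    for ci, cls in enumerate(classes):
        for s, _ in cls.members:
            entries[ci, samples.index(s)] = 1
    return PresenceMatrix(band_classes=classes, samples=samples,
                          entries=entries, basis=basis)


MONOMORPHIC, POLYMORPHIC, UNIQUE = "monomorphic", "polymorphic", "unique"


def polymorphism_percent(m: PresenceMatrix) -> tuple[float, list]:
    """Percentage of polymorphic band classes, with a per-class label.

    A class present in every sample is monomorphic; present in exactly one,
    unique; present in at least one but not all, polymorphic.  Unique classes
    count as polymorphic in the percentage (the fingerprinting convention)
    but keep their own label so users can recompute otherwise.
    """
    n_classes, n_samples = m.entries.shape
    if n_samples < 2:
        raise ValueError("polymorphism needs at least 2 samples")
    if n_classes == 0:
        raise ValueError("polymorphism undefined with no band classes")
    labels = []
    n_poly = 0
    for row in m.entries:
        count = int(row.sum())
        if count == n_samples:
            labels.append(MONOMORPHIC)
        elif count == 1:
            labels.append(UNIQUE)
            n_poly += 1
        else:
            labels.append(POLYMORPHIC)
            n_poly += 1
    return 100.0 * n_poly / n_classes, labels


def annotate_lanes(img: GelImage, lanes, calibration: Calibration | None = None,
                   reference=None) -> None:
    """Fill rf/mw/density/quantity on every band of every lane, in place."""
    for lane in lanes:
        for band in lane.bands:
            band.rf = compute_rf(band, lane)
            if calibration is not None:
                band.mw = calibration.estimate_mw(band.rf)
            band.density = band_density(img, lane, band)
            if reference is not None:
                band.quantity = estimate_quantity(band.density, reference)


def bands_table(lanes) -> pd.DataFrame:
    """Long-format per-band table (lane, sample, rf, mw, density, quantity)."""
    rows = []
    for lane in lanes:
        for band in lane.bands:
            rows.append({
                "lane_id": lane.id, "sample": lane.sample_name,
                "y_center": band.y_center, "rf": band.rf, "mw": band.mw,
                "density": band.density, "quantity": band.quantity,
            })
    return pd.DataFrame(rows)
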