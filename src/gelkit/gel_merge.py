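"""Cross-gel band matching: combine several per-gel analyses into one table.

Band migration shifts slightly between gels run under nominally identical
conditions, so the same fragment lands at slightly different estimated sizes
on different images.  This module pools all bands from all gels, sorts them
by molecular weight/size and matches them greedily: bands within a
user-defined MW tolerance of the running class mean are declared the same
band, each class taking the arithmetic mean of its members' sizes as its
combined size.  Classes whose members all come from one gel are flagged as
unique to that gel.  A manual override fuses classes regardless of their
size difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import BandClass, PresenceMatrix, _greedy_classes


@dataclass
class GelBands:
    """One gel's analysed bands: (sample, mw) pairs plus the sample roster."""

    gel: str
    samples: list
    bands: list  # (sample_name, mw)

    def __post_init__(self):
        for sample, mw in self.bands:
            if sample not in self.samples:
                raise ValueError(f"band sample {sample!r} not in gel {self.gel!r}")
            if mw is None:
                raise ValueError(f"band of sample {sample!r} lacks a MW")


def gel_bands_from_lanes(gel: str, lanes) -> GelBands:
    """Collect a :class:`GelBands` table from analysed lanes (MW attached)."""
    samples, bands = [], []
    for idx, lane in enumerate(lanes):
        name = lane.sample_name or f"{gel}:lane{idx}"
        samples.append(name)
        for band in lane.bands:
            bands.append((name, band.mw))
    return GelBands(gel=gel, samples=samples, bands=bands)


@dataclass
class CombinedClass(BandClass):
    """A matched cross-gel band class; members are (gel, sample, mw)."""

    source_gels: set = field(default_factory=set)
    unique_to_gel: bool = False


@dataclass
class CombinedMatrix(PresenceMatrix):
    """Presence/absence over the concatenated sample axis of all gels."""

    gels: list = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        df = super().to_dataframe()
        df.insert(0, "unique_to_gel",
                  [c.unique_to_gel for c in self.band_classes])
        return df


def _build_combined(groups, samples, gels) -> CombinedMatrix:
    classes = []
    for g in groups:
        mws = [v for _, v, _ in g]
        members = [(payload, s, v) for s, v, payload in g]
        source = {payload for s, v, payload in g}
        classes.append(CombinedClass(
            value=sum(mws) / len(mws),
            members=members,
            source_gels=source,
            unique_to_gel=len(source) == 1,
        ))
    classes.sort(key=lambda c: c.value)
    entries = np.zeros((len(classes), len(samples)), dtype=int)
    index = {s: i for i, s in enumerate(samples)}
    for ci, cls in enumerate(classes):
        for _, s, _ in cls.members:
            entries[ci, index[s]] = 1
    return CombinedMatrix(band_classes=classes, samples=samples,
                          entries=entries, basis="mw", gels=gels)


def merge_analyses(analyses, tolerance: float) -> CombinedMatrix:
    """Automatically match bands across gels by MW within `tolerance`.

    Bands from all gels are pooled, sorted by MW (ties broken by gel order
    then lane order) and clustered in one deterministic greedy pass: a band
    joins the open class iff its MW is within `tolerance` of the class's
    running mean and its sample has no member there yet.  The class MW is
    the arithmetic mean of its final members.
    """
    if len(analyses) < 2:
        raise ValueError("merging needs at least two analyses")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    samples, gels = [], []
    for a in analyses:
        gels.append(a.gel)
        for s in a.samples:
            if s in samples:
                raise ValueError(f"duplicate sample name {s!r} across gels")
            samples.append(s)
    items = []
    for gi, a in enumerate(analyses):
        for bi, (sample, mw) in enumerate(a.bands):
            items.append((sample, float(mw), a.gel, gi, bi))
    # stable sort: MW, then gel order, then within-gel band order
    items.sort(key=lambda t: (t[1], t[3], t[4]))
    groups = _greedy_classes([(s, v, g) for s, v, g, _, _ in items], tolerance)
    return _build_combined(groups, samples, gels)


def manual_match(combined: CombinedMatrix, class_indices) -> CombinedMatrix:
    """Fuse the named classes into one, whatever their MW differences.

    Rejected when any sample contributes to more than one of them (a sample
    cannot carry the same band twice).
    """
    idx = sorted(set(class_indices))
    if len(idx) < 2:
        raise ValueError("manual matching needs at least two classes")
    chosen = []
    for i in idx:
        if not (0 <= i < len(combined.band_classes)):
            raise ValueError(f"no class with index {i}")
        chosen.append(combined.band_classes[i])
    seen = set()
    for cls in chosen:
        for _, s, _ in cls.members:
            if s in seen:
                raise ValueError(f"sample {s!r} appears in more than one class")
            seen.add(s)
    members = [m for cls in chosen for m in cls.members]
    groups = [[(s, v, g) for g, s, v in members]]
    for i, cls in enumerate(combined.band_classes):
        if i not in idx:
            groups.append([(s, v, g) for g, s, v in cls.members])
    return _build_combined(groups, combined.samples, combined.gels)


def combined_table(combined: CombinedMatrix) -> pd.DataFrame:
    """Classes x samples table with the combined MW as the first column."""
    df = pd.DataFrame(combined.entries, columns=combined.samples)
    df.insert(0, "mw", [c.value for c in combined.band_classes])
    df.insert(1, "unique_to_gel", [c.unique_to_gel for c in combined.band_classes])
    return df
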