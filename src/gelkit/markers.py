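"""Molecular-marker detection from presence/absence fingerprints.

A positive marker is a band class carried by (essentially all of) a
user-chosen preferred group of samples and (essentially) absent from the
rest; a negative marker is the mirror image — absent from the preferred
group and carried by the rest.  The defaults demand perfect separation, the
textbook marker definition; the two fraction thresholds relax it.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

POSITIVE, NEGATIVE = "positive", "negative"


@dataclass
class MarkerCall:
    """One marker: the class value, its type and the supporting fractions."""

    class_index: int
    class_value: float
    type: str  # "positive" | "negative"
    p: float  # presence fraction within the positive group
    q: float  # presence fraction among the remaining samples
    positive_group: frozenset
    min_presence_frac: float
    max_contamination_frac: float


def detect_markers(m, positive_group, min_presence_frac: float = 1.0,
                   max_contamination_frac: float = 0.0):
    """Call positive and negative markers on a presence/absence matrix.

    With p = presence fraction in the positive group and q = presence
    fraction in the complement: a class is a positive marker iff
    ``p >= min_presence_frac`` and ``q <= max_contamination_frac``; a
    negative marker iff the symmetric condition on absence holds,
    ``(1 - p) >= min_presence_frac`` and ``(1 - q) <= max_contamination_frac``.
    A class is at most one marker type (positive takes precedence in the
    overlap only reachable at ``min_presence_frac <= 0.5``).
    """
    group = frozenset(positive_group)
    samples = list(m.samples)
    if not group or not group < set(samples):
        raise ValueError("positive_group must be a non-empty proper subset of samples")
    pos_idx = [i for i, s in enumerate(samples) if s in group]
    neg_idx = [i for i, s in enumerate(samples) if s not in group]
    calls = []
    values = m.class_values
    for ci, row in enumerate(m.entries):
        p = sum(int(row[i]) for i in pos_idx) / len(pos_idx)
        q = sum(int(row[i]) for i in neg_idx) / len(neg_idx)
        if p >= min_presence_frac and q <= max_contamination_frac:
            mtype = POSITIVE
        elif (1 - p) >= min_presence_frac and (1 - q) <= max_contamination_frac:
            mtype = NEGATIVE
        else:
            continue
        calls.append(MarkerCall(
            class_index=ci, class_value=values[ci], type=mtype, p=p, q=q,
            positive_group=group, min_presence_frac=min_presence_frac,
            max_contamination_frac=max_contamination_frac))
    return calls


def markers_table(calls, group_name: str = "preferred") -> pd.DataFrame:
    """Tabulate marker calls for CSV export."""
    return pd.DataFrame([
        {"class_value": c.class_value, "type": c.type, "p": c.p, "q": c.q,
         "group": group_name}
        for c in calls
    ])
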