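"""Binned differential-accessibility calling between two conditions.

Net accessibility scores are discretized into five ordered bins —
[0, 0.5), [0.5, 1), [1, 2), [2, 4), [4, inf) — and a residue is called
differential when its *replicate-averaged* bin differs between the
conditions by at least one. Bin intervals are half-open with the lower
boundary inclusive; negative scores (protection below background) fall in
bin 0, which lets more-protected residues surface as bin decreases.

The severity tier of a call comes from the paired per-replicate bin
changes (the color scheme used on secondary-structure diagrams):

    low    (yellow) — no replicate pair changes by two or more bins
    medium (orange) — exactly one replicate pair changes by >= 2 bins
    high   (red)    — two or more replicate pairs change by >= 2 bins

Change detection on the averaged profile and severity on per-replicate
bins is a deliberate split: averaging precedes binning in the score
pipeline, while the tier wording speaks of per-sample bin changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .accessibility import AccessibilityProfile
from .reference import ReferenceSequence

SEVERITY_COLORS = {"low": "yellow", "medium": "orange", "high": "red"}


@dataclass(frozen=True)
class BinScale:
    """The five-range accessibility scale used to discretize net scores."""

    boundaries: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries)
        if b.size != 5 or (np.diff(b) <= 0).any():
            raise ValueError("bin scale needs exactly 5 strictly increasing boundaries")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries)

    def edges(self) -> np.ndarray:
        """Interior boundaries used for assignment (the leading 0.0 is not an
        edge: values below it clamp into bin 0)."""
        return np.asarray(self.boundaries[1:])


DEFAULT_SCALE = BinScale()


def assign_bin(value, scale: BinScale = DEFAULT_SCALE):
    """Bin index (0..4) of a net accessibility value (vectorized).

    Half-open intervals, lower boundary inclusive: 0.5 is bin 1, 4.0 is
    bin 4; negative values clamp to bin 0. NaN maps to -1 (undefined).
    """
    arr = np.asarray(value, dtype=float)
    bins = np.searchsorted(scale.edges(), arr, side="right").astype(np.int64)
    bins = np.where(np.isnan(arr), -1, bins)
    return bins if np.ndim(value) else int(bins)


@dataclass
class DifferentialCall:
    """A residue whose accessibility bin changes between conditions."""

    position: int  # internal 1-based coordinate
    reported_position: int  # position + numbering offset
    base: str
    direction: str  # "more_accessible" | "more_protected"
    severity: str  # "low" | "medium" | "high"
    bin_cond1: int
    bin_cond2: int
    rep_bins_cond1: tuple[int, ...]
    rep_bins_cond2: tuple[int, ...]
    net_cond1: float
    net_cond2: float

    @property
    def delta_bins(self) -> int:
        return self.bin_cond2 - self.bin_cond1

    @property
    def color(self) -> str:
        return SEVERITY_COLORS[self.severity]


def severity_from_replicate_deltas(deltas: tuple[int, ...]) -> str:
    """Tier from paired per-replicate |bin changes|: (1,1) low, (1,2)
    medium, (2,2) high; generally, the count of pairs changing >= 2 bins."""
    n_big = sum(1 for d in deltas if abs(d) >= 2)
    if n_big == 0:
        return "low"
    if n_big == 1:
        return "medium"
    return "high"


def call_changes(
    cond1_reps: list[AccessibilityProfile],
    cond2_reps: list[AccessibilityProfile],
    cond1_avg: AccessibilityProfile | None = None,
    cond2_avg: AccessibilityProfile | None = None,
    scale: BinScale = DEFAULT_SCALE,
    ref: ReferenceSequence | None = None,
) -> tuple[list[DifferentialCall], list[int]]:
    """Emit a call at every position whose averaged bin differs.

    Replicates are paired by list order across conditions (the sample-sheet
    order). Positions undefined in any required profile are skipped and
    returned as the second element. Averages are recomputed from the
    replicates when not supplied.
    """
    from .accessibility import average_replicates

    if len(cond1_reps) != len(cond2_reps):
        raise ValueError(
            f"replicate count mismatch: {len(cond1_reps)} vs {len(cond2_reps)}"
        )
    if not cond1_reps:
        raise ValueError("need at least one replicate per condition")
    cond1_avg = cond1_avg or average_replicates(cond1_reps)
    cond2_avg = cond2_avg or average_replicates(cond2_reps)

    all_profiles = [cond1_avg, cond2_avg, *cond1_reps, *cond2_reps]
    common = all_profiles[0].positions
    for p in all_profiles[1:]:
        common = np.intersect1d(common, p.positions)
    union = all_profiles[0].positions
    for p in all_profiles[1:]:
        union = np.union1d(union, p.positions)
    skipped = [int(x) for x in np.setdiff1d(union, common)]

    def net_at(p: AccessibilityProfile) -> np.ndarray:
        return p.net[np.searchsorted(p.positions, common)]

    net1, net2 = net_at(cond1_avg), net_at(cond2_avg)
    bins1, bins2 = assign_bin(net1, scale), assign_bin(net2, scale)
    rep_bins1 = [assign_bin(net_at(p), scale) for p in cond1_reps]
    rep_bins2 = [assign_bin(net_at(p), scale) for p in cond2_reps]
    bases = all_profiles[0].bases[np.searchsorted(all_profiles[0].positions, common)]
    offset = ref.numbering_offset if ref is not None else 0

    calls: list[DifferentialCall] = []
    for i in np.flatnonzero(bins1 != bins2):
        delta = int(bins2[i] - bins1[i])
        rep_deltas = tuple(
            int(rb2[i] - rb1[i]) for rb1, rb2 in zip(rep_bins1, rep_bins2)
        )
        calls.append(
            DifferentialCall(
                position=int(common[i]),
                reported_position=int(common[i]) + offset,
                base=str(bases[i]),
                direction="more_accessible" if delta > 0 else "more_protected",
                severity=severity_from_replicate_deltas(rep_deltas),
                bin_cond1=int(bins1[i]),
                bin_cond2=int(bins2[i]),
                rep_bins_cond1=tuple(int(rb[i]) for rb in rep_bins1),
                rep_bins_cond2=tuple(int(rb[i]) for rb in rep_bins2),
                net_cond1=float(net1[i]),
                net_cond2=float(net2[i]),
            )
        )
    return calls, skipped


def summarize(calls: list[DifferentialCall]) -> tuple[dict, pd.DataFrame]:
    """Counts by direction and severity plus the annotated call table."""
    counts = {
        "total": len(calls),
        "more_accessible": sum(c.direction == "more_accessible" for c in calls),
        "more_protected": sum(c.direction == "more_protected" for c in calls),
        "low": sum(c.severity == "low" for c in calls),
        "medium": sum(c.severity == "medium" for c in calls),
        "high": sum(c.severity == "high" for c in calls),
    }
    table = pd.DataFrame(
        [
            {
                "position": c.reported_position,
                "base": c.base,
                "direction": c.direction,
                "severity": c.severity,
                "color": c.color,
                "bin_cond1": c.bin_cond1,
                "bin_cond2": c.bin_cond2,
                "rep_bins_cond1": "/".join(map(str, c.rep_bins_cond1)),
                "rep_bins_cond2": "/".join(map(str, c.rep_bins_cond2)),
                "net_cond1": c.net_cond1,
                "net_cond2": c.net_cond2,
            }
            for c in sorted(calls, key=lambda c: c.position)
        ],
        columns=[
            "position", "base", "direction", "severity", "color",
            "bin_cond1", "bin_cond2", "rep_bins_cond1", "rep_bins_cond2",
            "net_cond1", "net_cond2",
        ],
    )
    return counts, table


def structure_colors(calls: list[DifferentialCall]) -> pd.DataFrame:
    """Position -> color export for secondary-structure drawing programs."""
    return pd.DataFrame(
        [
            {"position": c.reported_position, "color": c.color}
            for c in sorted(calls, key=lambda c: c.position)
        ],
        columns=["position", "color"],
    )
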