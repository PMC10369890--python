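"""DMS accessibility normalization and replicate averaging.

The accessibility score for an A or C residue is computed from a paired
treated/mock library: both rates are divided by the mean mutational rate
of the *untreated* sample over all defined residues of the same base class
(A and C are scaled by their own class means, since DMS methylates N1-A
and N3-C with different chemistry), and the scaled untreated value is then
subtracted from the scaled treated value:

    net(x) = rate_T(x) / mean_U(class x)  -  rate_U(x) / mean_U(class x)

The untreated class mean measures the background (RT + sequencing error),
so the scaled untreated values average exactly 1 per class and the net
score is in units of background. Net accessibility may be negative —
residues more protected in one condition depend on the sign. Replicates
are averaged after subtraction, position-wise, keeping only positions
defined in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .profile import MutationProfile
from .reference import A, C, ReferenceSequence


class DataError(RuntimeError):
    """Fatal data problem (e.g. no untreated background signal to scale by)."""


@dataclass
class AccessibilityProfile:
    """Normalized accessibility values at A/C positions for one sample pair.

    Defined only at A/C positions passing the coverage floor in both the
    treated and the mock library. ``net`` is NaN until
    :func:`subtract_background` fills it.
    """

    positions: np.ndarray  # 1-based, sorted
    bases: np.ndarray  # "A" or "C" per position
    norm_treated: np.ndarray
    norm_untreated: np.ndarray
    net: np.ndarray
    condition: str
    replicate: int | None  # None for a replicate average
    averaged: bool = False

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "base": self.bases,
                "normalized_treated": self.norm_treated,
                "normalized_untreated": self.norm_untreated,
                "net": self.net,
                "condition": self.condition,
                "replicate": "avg" if self.averaged else self.replicate,
            }
        )

    def net_at(self, position: int) -> float:
        idx = np.searchsorted(self.positions, position)
        if idx >= len(self.positions) or self.positions[idx] != position:
            raise KeyError(f"position {position} not defined in profile")
        return float(self.net[idx])


def untreated_class_means(
    mock: MutationProfile, ref: ReferenceSequence, positions: np.ndarray | None = None
) -> dict[str, float]:
    """Mean untreated mutational rate per base class (A, C) over defined
    positions (optionally restricted to ``positions``, 1-based)."""
    if mock.rates is None:
        raise ValueError("mock profile has no rates; run rate() first")
    means = {}
    for base, code in (("A", A), ("C", C)):
        mask = (ref.codes == code) & mock.defined
        if positions is not None:
            sel = np.zeros(ref.length, dtype=bool)
            sel[positions - 1] = True
            mask &= sel
        vals = mock.rates[mask]
        means[base] = float(vals.mean()) if vals.size else float("nan")
    return means


def pooled_class_means(
    mocks: list[MutationProfile], ref: ReferenceSequence
) -> dict[str, float]:
    """Class means pooled across several mock libraries (optional mode;
    the default keeps each replicate's own background)."""
    pooled = {"A": [], "C": []}
    for mock in mocks:
        for base, code in (("A", A), ("C", C)):
            mask = (ref.codes == code) & mock.defined
            pooled[base].append(mock.rates[mask])
    return {b: float(np.concatenate(v).mean()) if v else float("nan") for b, v in pooled.items()}


def normalize_by_untreated_mean(
    treated: MutationProfile,
    mock: MutationProfile,
    ref: ReferenceSequence,
    condition: str | None = None,
    replicate: int | None = None,
    class_means: dict[str, float] | None = None,
) -> AccessibilityProfile:
    """Scale treated and mock rates by the untreated per-class mean.

    Both profiles must be on the same reference; the result covers the A/C
    positions where both have defined rates. ``class_means`` overrides the
    per-pair untreated means (e.g. with :func:`pooled_class_means`).
    A zero untreated class mean is fatal: with no background signal there
    is no scale.
    """
    if treated.length != mock.length or treated.ref_name != mock.ref_name:
        raise ValueError("treated and mock profiles are not on the same reference")
    if treated.rates is None or mock.rates is None:
        raise ValueError("profiles must have rates filled (run rate() first)")

    is_ac = (ref.codes == A) | (ref.codes == C)
    ok = is_ac & treated.defined & mock.defined
    positions = np.flatnonzero(ok) + 1
    bases = np.array(list(ref.seq))[positions - 1]

    means = class_means or untreated_class_means(mock, ref)
    for base in ("A", "C"):
        if (bases == base).any() and not means.get(base, 0) > 0:
            raise DataError(
                f"untreated mean rate for base class {base} is zero or undefined; "
                "no background signal to scale by"
            )
    denom = np.where(bases == "A", means["A"], means["C"])

    return AccessibilityProfile(
        positions=positions,
        bases=bases,
        norm_treated=treated.rates[positions - 1] / denom,
        norm_untreated=mock.rates[positions - 1] / denom,
        net=np.full(positions.size, np.nan),
        condition=condition or treated.sample.condition,
        replicate=replicate if replicate is not None else treated.sample.replicate,
    )


def subtract_background(profile: AccessibilityProfile) -> AccessibilityProfile:
    """Fill net accessibility: scaled treated minus scaled untreated."""
    return replace(profile, net=profile.norm_treated - profile.norm_untreated)


def average_replicates(profiles: list[AccessibilityProfile]) -> AccessibilityProfile:
    """Position-wise arithmetic mean of net values across replicates.

    Positions undefined (absent) in any replicate are dropped from the
    average. Replicate order does not matter. All inputs must share a
    condition.
    """
    if not profiles:
        raise ValueError("need at least one replicate")
    conditions = {p.condition for p in profiles}
    if len(conditions) != 1:
        raise ValueError(f"cannot average across conditions: {sorted(conditions)}")
    if any(np.isnan(p.net).any() for p in profiles):
        raise ValueError("net values missing; run subtract_background first")
    # canonical order: the mean is then bit-identical under permutation
    profiles = sorted(
        profiles, key=lambda p: (p.replicate is None, p.replicate)
    )

    common = profiles[0].positions
    for p in profiles[1:]:
        common = np.intersect1d(common, p.positions)

    def take(p: AccessibilityProfile, arr: np.ndarray) -> np.ndarray:
        return arr[np.searchsorted(p.positions, common)]

    net = np.mean([take(p, p.net) for p in profiles], axis=0)
    return AccessibilityProfile(
        positions=common,
        bases=take(profiles[0], profiles[0].bases),
        norm_treated=np.mean([take(p, p.norm_treated) for p in profiles], axis=0),
        norm_untreated=np.mean([take(p, p.norm_untreated) for p in profiles], axis=0),
        net=net,
        condition=profiles[0].condition,
        replicate=None,
        averaged=True,
    )
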