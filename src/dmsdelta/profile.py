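"""Per-position coverage, mutation counts, and mutational rates.

The mutational rate at each nucleotide — mutation events divided by read
coverage — is the raw readout of mutational profiling: it measures the
propensity of the position to be modified by DMS (plus background error).
Every aligned base increments coverage at its position; every mismatch to
the reference increments the mutation count; N bases carry no evidence and
are excluded from both. Rates are only defined where coverage reaches a
floor; positions below it are flagged and excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .reads import AlignedRead, AlignmentBatch
from .reference import N_CODE, ReferenceSequence

DEFAULT_COVERAGE_FLOOR = 50


@dataclass
class SampleLabel:
    """Identity of one sequencing library."""

    condition: str
    replicate: int
    treatment: str = "DMS"  # "DMS" | "mock"

    def __str__(self) -> str:
        return f"{self.condition}_rep{self.replicate}_{self.treatment}"


@dataclass
class MutationProfile:
    """Per-position coverage and mutation-event counts for one library.

    Arrays are indexed by position - 1 (position 1-based). ``rates`` is NaN
    until :func:`rate` fills it; positions below the coverage floor stay
    NaN and ``defined`` False.
    """

    ref_name: str
    length: int
    coverage: np.ndarray
    mutations: np.ndarray
    sample: SampleLabel
    rates: np.ndarray | None = None
    coverage_floor: int | None = None

    @property
    def defined(self) -> np.ndarray:
        if self.rates is None:
            return np.zeros(self.length, dtype=bool)
        return ~np.isnan(self.rates)

    def validate(self) -> None:
        if (self.mutations > self.coverage).any():
            raise ValueError("mutation events exceed coverage at some position")
        if (self.coverage < 0).any() or (self.mutations < 0).any():
            raise ValueError("negative counts")

    def to_frame(self, ref: ReferenceSequence | None = None) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "position": np.arange(1, self.length + 1),
                "coverage": self.coverage,
                "mutations": self.mutations,
                "rate": self.rates if self.rates is not None else np.nan,
                "sample": str(self.sample),
            }
        )
        if ref is not None:
            frame.insert(1, "base", list(ref.seq))
        return frame


def count_mutations(
    alignments: Iterable[AlignedRead] | AlignmentBatch,
    ref: ReferenceSequence,
    sample: SampleLabel | None = None,
) -> MutationProfile:
    """Accumulate coverage and mutation events over a set of placements.

    Accepts either a stream of :class:`AlignedRead` or a vectorized
    :class:`AlignmentBatch`; the result is order-independent. Multiple
    mismatches within one read each count at their own position.
    """
    sample = sample or SampleLabel("unknown", 1)
    coverage = np.zeros(ref.length, dtype=np.int64)
    mutations = np.zeros(ref.length, dtype=np.int64)

    if isinstance(alignments, AlignmentBatch):
        _count_batch(alignments, ref, coverage, mutations)
    else:
        for aln in alignments:
            aln.check_bounds(ref)
            span = slice(aln.start - 1, aln.start - 1 + aln.length)
            is_n = aln.codes == N_CODE
            coverage[span] += ~is_n
            mutations[span] += (aln.codes != ref.codes[span]) & ~is_n

    prof = MutationProfile(
        ref_name=ref.name,
        length=ref.length,
        coverage=coverage,
        mutations=mutations,
        sample=sample,
    )
    prof.validate()
    return prof


def _count_batch(aln: AlignmentBatch, ref: ReferenceSequence, coverage, mutations) -> None:
    starts, lengths = aln.starts, aln.lengths
    if len(aln) == 0:
        return
    if (starts < 1).any() or (starts + lengths - 1 > ref.length).any():
        raise ValueError("alignment out of reference bounds")
    # coverage via interval difference array: O(reads + length)
    diff = np.zeros(ref.length + 1, dtype=np.int64)
    np.add.at(diff, starts - 1, 1)
    np.add.at(diff, starts - 1 + lengths, -1)
    coverage += np.cumsum(diff[:-1])
    # mismatches and Ns are sparse: scatter-add only where they occur
    for L in np.unique(lengths):
        sel = np.flatnonzero(lengths == L)
        cols = aln.offsets[sel, None] + np.arange(L)[None, :]
        codes = aln.seqs[sel[:, None], cols]
        rpos = starts[sel, None] - 1 + np.arange(L)[None, :]
        is_n = codes == N_CODE
        mism = (codes != ref.codes[rpos]) & ~is_n
        np.add.at(mutations, rpos[mism], 1)
        if is_n.any():
            np.add.at(coverage, rpos[is_n], -1)


def rate(
    profile: MutationProfile, coverage_floor: int = DEFAULT_COVERAGE_FLOOR
) -> MutationProfile:
    """Fill mutational rates where coverage reaches the floor.

    rate = mutations / coverage at positions with coverage >= floor; all
    other positions are NaN (undefined) and excluded downstream. Returns a
    new profile; the input is unchanged.
    """
    rates = np.full(profile.length, np.nan)
    ok = profile.coverage >= max(coverage_floor, 1)
    rates[ok] = profile.mutations[ok] / profile.coverage[ok]
    return replace(profile, rates=rates, coverage_floor=coverage_floor)


def coverage_report(
    profile: MutationProfile, coverage_floor: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-position coverage track plus summary QC figures."""
    floor = coverage_floor if coverage_floor is not None else (
        profile.coverage_floor or DEFAULT_COVERAGE_FLOOR
    )
    track = pd.DataFrame(
        {
            "position": np.arange(1, profile.length + 1),
            "coverage": profile.coverage,
            "above_floor": profile.coverage >= floor,
            "sample": str(profile.sample),
        }
    )
    n = profile.length
    summary = {
        "sample": str(profile.sample),
        "coverage_floor": int(floor),
        "fraction_above_floor": float((profile.coverage >= floor).sum() / n) if n else 0.0,
        "mean_coverage": float(profile.coverage.mean()) if n else 0.0,
        "median_coverage": float(np.median(profile.coverage)) if n else 0.0,
        "total_aligned_bases": int(profile.coverage.sum()),
        "total_mutation_events": int(profile.mutations.sum()),
    }
    return track, summary


def expected_coverage_profile(
    ref_length: int, fragment_length_range: tuple[int, int], n_reads: int
) -> np.ndarray:
    """Enumeration oracle for fragment-placement geometry.

    Expected coverage per position for ``n_reads`` fragments with uniform
    length in the given range and uniform start among valid positions:
    interior positions (>= max fragment length from either end) are flat,
    edge positions proportionally reduced.
    """
    lo, hi = fragment_length_range
    lengths = np.arange(lo, hi + 1)
    expected = np.zeros(ref_length)
    for L in lengths:
        n_starts = ref_length - L + 1
        if n_starts <= 0:
            continue
        per_start = 1.0 / (len(lengths) * n_starts)
        diff = np.zeros(ref_length + 1)
        diff[: ref_length - L + 1] += per_start
        diff[L : ref_length + 1] -= per_start
        expected += np.cumsum(diff[:-1])
    return expected * n_reads
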