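"""Read trimming and gapless placement on the reference.

Re-implements, at desk scale, the preprocessing that probing pipelines
delegate to adaptor trimmers and mutational-profiling aligners: 3' adaptor
removal, fixed end trims plus quality trimming, and gapless placement of
the mismatch-rich reads. Every operation exists both as a per-read
function (the contract, used in tests and for small inputs) and as a
vectorized batch equivalent used by the pipeline at full depth.

Placement is seeded: an error-free 20-nt k-mer anchors the read on the
reference and the rest is extended gaplessly; a candidate is accepted if
its mismatch fraction is at most 0.2, generous because DMS-induced
misincorporations are the signal, not noise. Reads whose anchor matches
two or more reference loci are dropped and counted as ambiguous.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import N_CODE, ReferenceSequence, decode_seq, encode_seq
from .simulate import DEFAULT_QUALITY, ReadBatch


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities must have equal length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedRead:
    """A gapless placement of a read on the reference.

    ``start`` is 1-based inclusive; the aligned bases are ``codes`` (uint8,
    same encoding as the reference). Match/mismatch calls against a
    reference are produced by :meth:`matches`.
    """

    read_id: str
    start: int
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.start < 1:
            raise ValueError("alignment start must be >= 1")

    @property
    def length(self) -> int:
        return self.codes.size

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + self.length - 1

    def check_bounds(self, ref: ReferenceSequence) -> None:
        if self.end > ref.length:
            raise ValueError(
                f"alignment [{self.start}, {self.end}] exceeds reference length {ref.length}"
            )

    def matches(self, ref: ReferenceSequence) -> np.ndarray:
        """Boolean match calls per aligned position (N never matches)."""
        self.check_bounds(ref)
        return self.codes == ref.codes[self.start - 1 : self.end]


# ---------------------------------------------------------------------------
# Adaptor trimming
# ---------------------------------------------------------------------------


def trim_adaptor(read: Read, adaptor: str, min_overlap: int = 10) -> Read:
    """Remove the 3' adaptor from a read.

    Finds the leftmost position where a prefix of ``adaptor`` of length
    >= ``min_overlap`` matches the read through its 3' end, allowing one
    mismatch per 10 adaptor bases of overlap; that position and everything
    3' of it are removed. Reads without a match are returned unchanged.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rcodes = encode_seq(read.sequence)
    acodes = encode_seq(adaptor)
    n, alen = rcodes.size, acodes.size
    for s in range(0, n - min_overlap + 1):
        overlap = min(alen, n - s)
        mism = int((rcodes[s : s + overlap] != acodes[:overlap]).sum())
        if mism <= overlap // 10:
            return Read(read.id, read.sequence[:s], read.qualities[:s])
    return read


def trim_adaptor_batch(batch: ReadBatch, adaptor: str, k: int = 16) -> ReadBatch:
    """Vectorized adaptor trimming for a batch.

    Locates the leftmost exact occurrence of the adaptor's first ``k``
    bases via a rolling base-4 hash and truncates the read there. Exact
    prefix matching suffices for simulated libraries, where the ligated
    adaptor carries no errors; external data with adaptor errors should go
    through :func:`trim_adaptor`.
    """
    acodes = encode_seq(adaptor)
    k = min(k, acodes.size)
    target = int(_poly_hash(acodes[:k][None, :], k)[0, 0])

    offs, lens = batch.offsets, batch.lengths
    width = int((offs + lens).max())
    safe = np.where(batch.seqs[:, :width] > 3, 0, batch.seqs[:, :width]).astype(np.int64)

    # incremental rolling hash, tracking each read's leftmost in-range hit
    n = len(batch)
    first = np.full(n, -1, dtype=np.int64)
    top = 4 ** (k - 1)
    h = np.zeros(n, dtype=np.int64)
    for j in range(k):
        h = h * 4 + safe[:, j]
    ends = offs + lens
    for s in range(0, width - k + 1):
        if s > 0:
            h = (h - safe[:, s - 1] * top) * 4 + safe[:, s + k - 1]
        hit = h == target  # rare: refine the candidates only when present
        if hit.any():
            hit &= (first < 0) & (s >= offs) & (s + k <= ends)
            first[hit] = s

    has_hit = first >= 0
    new_lengths = lens.copy()
    new_lengths[has_hit] = first[has_hit] - offs[has_hit]
    return ReadBatch(
        seqs=batch.seqs,
        lengths=new_lengths,
        origins=batch.origins.copy(),
        offsets=offs.copy(),
        quality=batch.quality,
        ids=batch.ids,
    )


def _poly_hash(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-4 hash of every k-mer along axis 1 (int64, exact)."""
    n, width = codes.shape
    out = np.zeros((n, width - k + 1), dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    top = 4 ** (k - 1)
    for j in range(k):
        h = h * 4 + codes[:, j]
    out[:, 0] = h
    for s in range(1, width - k + 1):
        h = (h - codes[:, s - 1] * top) * 4 + codes[:, s + k - 1]
        out[:, s] = h
    return out


# ---------------------------------------------------------------------------
# End and quality trimming
# ---------------------------------------------------------------------------


def trim_ends_and_quality(
    read: Read, n5: int = 5, n3: int = 5, qmin: int = 20, min_length: int = 20
) -> Read | None:
    """Remove the first ``n5`` and last ``n3`` bases, then trim inward from
    both ends while base quality < ``qmin``. Returns ``None`` when fewer
    than ``min_length`` bases remain (the read is discarded)."""
    lo, hi = n5, len(read) - n3  # python slice bounds
    while lo < hi and read.qualities[lo] < qmin:
        lo += 1
    while hi > lo and read.qualities[hi - 1] < qmin:
        hi -= 1
    if hi - lo < min_length:
        return None
    return Read(read.id, read.sequence[lo:hi], read.qualities[lo:hi])


def trim_ends_batch(
    batch: ReadBatch, n5: int = 5, n3: int = 5, qmin: int = 20, min_length: int = 20
) -> tuple[ReadBatch, int]:
    """Batch equivalent of :func:`trim_ends_and_quality` for constant-quality
    batches (quality trimming is a no-op when quality >= ``qmin``).
    Returns the filtered batch and the number of discarded reads."""
    if batch.quality < qmin:
        # every base fails the threshold: all reads are consumed
        empty = ReadBatch(
            seqs=batch.seqs[:0],
            lengths=batch.lengths[:0],
            origins=batch.origins[:0],
            quality=batch.quality,
        )
        return empty, len(batch)
    lengths = batch.lengths - n5 - n3
    keep = lengths >= min_length
    trimmed = ReadBatch(
        seqs=batch.seqs[keep],
        lengths=lengths[keep],
        origins=np.where(batch.origins[keep] > 0, batch.origins[keep] + n5, -1),
        offsets=batch.offsets[keep] + n5,
        quality=batch.quality,
        ids=[batch.ids[i] for i in np.flatnonzero(keep)] if batch.ids else None,
    )
    return trimmed, int((~keep).sum())


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


@dataclass
class PlacementStats:
    placed: int = 0
    unplaced: int = 0
    ambiguous: int = 0

    @property
    def total(self) -> int:
        return self.placed + self.unplaced + self.ambiguous


@dataclass
class AlignmentBatch:
    """Gapless placements of a read batch: parallel arrays of 1-based
    starts, aligned lengths, and a view into the source sequences."""

    starts: np.ndarray
    lengths: np.ndarray
    seqs: np.ndarray
    offsets: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    def codes(self, i: int) -> np.ndarray:
        o = self.offsets[i]
        return self.seqs[i, o : o + self.lengths[i]]

    def to_aligned_reads(self, ids=None) -> list[AlignedRead]:
        return [
            AlignedRead(
                read_id=ids[i] if ids else f"read{i}",
                start=int(self.starts[i]),
                codes=self.codes(i).copy(),
            )
            for i in range(len(self))
        ]


class KmerIndex:
    """Sorted-hash index of all reference k-mers for seeded placement."""

    def __init__(self, ref: ReferenceSequence, k: int = 20):
        self.ref = ref
        self.k = k
        codes = ref.codes.astype(np.int64)
        hashes = _poly_hash(codes[None, :], k)[0]
        order = np.argsort(hashes, kind="stable")
        self.sorted_hashes = hashes[order]
        self.sorted_pos = order + 1  # 1-based k-mer start
        # a hash is ambiguous if it occurs at >= 2 reference loci
        left = np.searchsorted(self.sorted_hashes, self.sorted_hashes, side="left")
        right = np.searchsorted(self.sorted_hashes, self.sorted_hashes, side="right")
        self.multiplicity = right - left

    def lookup(self, query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (position, multiplicity) per query hash; position 0 and
        multiplicity 0 mean not found."""
        idx = np.searchsorted(self.sorted_hashes, query, side="left")
        idx_c = np.minimum(idx, self.sorted_hashes.size - 1)
        found = self.sorted_hashes[idx_c] == query
        pos = np.where(found, self.sorted_pos[idx_c], 0)
        mult = np.where(found, self.multiplicity[idx_c], 0)
        return pos, mult


def place_reads(
    batch: ReadBatch,
    ref: ReferenceSequence,
    seed_len: int = 20,
    max_mismatch_frac: float = 0.2,
    seed_offsets: tuple[int, ...] = (0, 20, 40),
    index: KmerIndex | None = None,
) -> tuple[AlignmentBatch, PlacementStats, np.ndarray]:
    """Vectorized seeded placement of a trimmed batch.

    For each read, k-mers at ``seed_offsets`` are tried in order; the first
    offset whose k-mer occurs in the reference anchors the read (a
    multi-locus anchor marks it ambiguous). The anchored placement is
    accepted if it lies within bounds and its mismatch fraction is at most
    ``max_mismatch_frac``. Returns the alignment batch, conservation
    statistics (placed + unplaced + ambiguous = total), and the index of
    each placed read in the input batch.
    """
    index = index or KmerIndex(ref, seed_len)
    n = len(batch)
    offs, lens = batch.offsets, batch.lengths

    cand_start = np.zeros(n, dtype=np.int64)
    ambiguous = np.zeros(n, dtype=bool)
    unresolved = np.ones(n, dtype=bool)

    powers = 4 ** np.arange(seed_len - 1, -1, -1, dtype=np.int64)
    for so in seed_offsets:
        rows = np.flatnonzero(unresolved & (lens >= so + seed_len))
        if rows.size == 0:
            continue
        cols = offs[rows, None] + so + np.arange(seed_len)[None, :]
        sub = batch.seqs[rows[:, None], cols].astype(np.int64)
        np.minimum(sub, 3, out=sub)  # N/padding cannot anchor but must hash
        query = (sub * powers[None, :]).sum(axis=1)
        pos, mult = index.lookup(query)
        unique = mult == 1
        multi = mult >= 2
        hit_rows = rows[unique]
        cand_start[hit_rows] = pos[unique] - so
        unresolved[hit_rows] = False
        # a multi-locus anchor is remembered; later offsets may still resolve
        ambiguous[rows[multi]] = True
    ambiguous &= unresolved  # resolved reads are not ambiguous

    has_cand = ~unresolved
    in_bounds = has_cand & (cand_start >= 1) & (cand_start + lens - 1 <= ref.length)

    placed_idx = np.flatnonzero(in_bounds)
    mism_frac = np.zeros(placed_idx.size)
    # verify mismatch fraction, grouped by read length for dense vector math
    for L in np.unique(lens[placed_idx]):
        sel = placed_idx[lens[placed_idx] == L]
        cols = offs[sel, None] + np.arange(L)[None, :]
        rpos = cand_start[sel, None] - 1 + np.arange(L)[None, :]
        mism = batch.seqs[sel[:, None], cols] != ref.codes[rpos]
        frac = mism.sum(axis=1) / L
        mism_frac[np.searchsorted(placed_idx, sel)] = frac
    accepted = placed_idx[mism_frac <= max_mismatch_frac]

    stats = PlacementStats(
        placed=int(accepted.size),
        ambiguous=int(ambiguous.sum()),
        unplaced=int(n - accepted.size - ambiguous.sum()),
    )
    aln = AlignmentBatch(
        starts=cand_start[accepted],
        lengths=lens[accepted],
        seqs=batch.seqs[accepted],
        offsets=offs[accepted],
    )
    return aln, stats, accepted


def place_read(
    read: Read,
    ref: ReferenceSequence,
    mode: str = "seeded",
    seed_len: int = 20,
    max_mismatch_frac: float = 0.2,
    seed_offsets: tuple[int, ...] = (0, 20, 40),
    stats: PlacementStats | None = None,
) -> AlignedRead | None:
    """Place a single trimmed read on the reference.

    ``mode='exact'`` requires a unique exact substring match; ``'seeded'``
    anchors the read with an error-free k-mer and extends gaplessly,
    accepting a mismatch fraction up to ``max_mismatch_frac``. Ambiguous
    placements (two or more loci) and failures return ``None`` and are
    tallied in ``stats`` when given.
    """
    stats = stats if stats is not None else PlacementStats()
    rcodes = encode_seq(read.sequence)
    if mode == "exact":
        hits = _find_all(ref.seq, read.sequence)
        if len(hits) == 1:
            stats.placed += 1
            return AlignedRead(read.id, hits[0], rcodes)
        if len(hits) >= 2:
            stats.ambiguous += 1
        else:
            stats.unplaced += 1
        return None
    if mode != "seeded":
        raise ValueError(f"unknown placement mode {mode!r}")

    saw_multi = False
    for so in seed_offsets:
        if len(read) < so + seed_len:
            continue
        seed = read.sequence[so : so + seed_len]
        hits = _find_all(ref.seq, seed)
        if len(hits) >= 2:
            saw_multi = True  # a later seed offset may still resolve the read
            continue
        if len(hits) == 1:
            start = hits[0] - so
            end = start + len(read) - 1
            if start < 1 or end > ref.length:
                stats.unplaced += 1
                return None
            mism = int((rcodes != ref.codes[start - 1 : end]).sum())
            if mism / len(read) <= max_mismatch_frac:
                stats.placed += 1
                return AlignedRead(read.id, start, rcodes)
            stats.unplaced += 1
            return None
    if saw_multi:
        stats.ambiguous += 1
    else:
        stats.unplaced += 1
    return None


def _find_all(haystack: str, needle: str) -> list[int]:
    """1-based start positions of all (possibly overlapping) occurrences."""
    hits = []
    start = haystack.find(needle)
    while start != -1:
        hits.append(start + 1)
        if len(hits) > 1:  # two is enough to declare ambiguity
            break
        start = haystack.find(needle, start + 1)
    return hits


# ---------------------------------------------------------------------------
# SAM interoperability
# ---------------------------------------------------------------------------


def read_sam(path, log=None):
    """Stream gapless primary alignments from a SAM file as AlignedReads.

    Secondary, supplementary and unmapped records are skipped silently;
    records with gapped CIGARs (I/D/N) are skipped with a warning since the
    mutation bookkeeping is defined for gapless placements only. Soft-clips
    are excluded from the aligned span. Coordinates stay 1-based.
    """
    import pysam

    warn = log.warning if log is not None else (lambda *a: None)
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            cigar = rec.cigartuples or []
            ops = {op for op, _ in cigar}
            if not ops <= {0, 4, 7, 8}:  # M, S, =, X only
                warn("skipping %s: gapped or unsupported CIGAR", rec.query_name)
                continue
            seq = rec.query_alignment_sequence
            if seq is None:
                warn("skipping %s: missing sequence", rec.query_name)
                continue
            yield AlignedRead(
                read_id=rec.query_name,
                start=rec.reference_start + 1,
                codes=encode_seq(seq),
            )


def write_sam(alignments, ref: ReferenceSequence, path) -> None:
    """Write gapless alignments as plain-text SAM with an @SQ header."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"},
              "SQ": [{"SN": ref.name, "LN": ref.length}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.query_sequence = decode_seq(aln.codes)
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = aln.start - 1
            rec.mapping_quality = 60
            rec.cigartuples = [(0, aln.length)]
            rec.query_qualities = pysam.qualitystring_to_array("I" * aln.length)
            out.write(rec)
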