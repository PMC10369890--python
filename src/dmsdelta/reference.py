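"""Reference sequences and base encoding.

Positions are 1-based and inclusive throughout the package, matching the
residue numbering used for rRNA (e.g. A1515). A ``numbering_offset`` maps
internal coordinates to reported residue numbers when the sequenced
molecule (e.g. a 20S precursor) differs from the numbering reference
(mature 18S): ``reported = position + numbering_offset``.

Bases are encoded as uint8 codes A=0, C=1, G=2, T=3 (U is accepted and
treated as T); anything else, including N, is code 4 and carries no
evidence downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

A, C, G, T = 0, 1, 2, 3
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_ENCODE[ord("U")] = T
_ENCODE[ord("u")] = T

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes (A=0, C=1, G=2, T/U=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode_seq(codes: np.ndarray) -> str:
    """Decode uint8 codes back into an uppercase DNA string (code 4 -> N)."""
    codes = np.asarray(codes, dtype=np.uint8)
    return _DECODE[np.minimum(codes, N_CODE)].tobytes().decode("ascii")


@dataclass
class ReferenceSequence:
    """An rRNA reference with 1-based position numbering.

    Parameters
    ----------
    name
        Sequence identifier (FASTA header).
    seq
        Nucleotide string over {A, C, G, T/U}; stored uppercase with U -> T.
    numbering_offset
        Added to internal 1-based positions to produce reported residue
        numbers.
    """

    name: str
    seq: str
    numbering_offset: int = 0
    codes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError("reference sequence must have length >= 1")
        self.seq = self.seq.upper().replace("U", "T")
        codes = encode_seq(self.seq)
        if (codes >= N_CODE).any():
            bad = sorted(set(self.seq) - set("ACGT"))
            raise ValueError(f"reference alphabet restricted to A/C/G/T/U; found {bad}")
        self.codes = codes

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def reported_position(self, position: int) -> int:
        """Map an internal 1-based position to the reported residue number."""
        return position + self.numbering_offset

    def ac_positions(self) -> np.ndarray:
        """1-based positions of all A and C residues (the DMS-reactive bases)."""
        return np.flatnonzero((self.codes == A) | (self.codes == C)) + 1

    def base_at(self, position: int) -> str:
        return self.seq[position - 1]


def make_reference(
    length: int,
    composition=None,
    seed: int = 0,
    name: str = "synthetic_rRNA",
    numbering_offset: int = 0,
    min_fragment_span: int = 80,
) -> ReferenceSequence:
    """Draw a random reference sequence with the given base composition.

    ``composition`` is the (A, C, G, T) frequency vector (default uniform);
    it must sum to 1. ``length`` must accommodate the largest simulated
    fragment (``min_fragment_span``), otherwise no read can be placed.
    Deterministic for a fixed ``seed``.
    """
    if composition is None:
        composition = np.full(4, 0.25)
    composition = np.asarray(composition, dtype=float)
    if composition.shape != (4,) or not np.isclose(composition.sum(), 1.0):
        raise ValueError("composition must be a length-4 vector summing to 1")
    if (composition < 0).any():
        raise ValueError("composition frequencies must be non-negative")
    if length < min_fragment_span:
        raise ValueError(
            f"reference length {length} is shorter than the maximum fragment "
            f"size {min_fragment_span}"
        )
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=composition).astype(np.uint8)
    return ReferenceSequence(name=name, seq=decode_seq(codes), numbering_offset=numbering_offset)


def read_fasta(path, numbering_offset: int = 0) -> ReferenceSequence:
    """Read the first record of a FASTA file as the reference."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceSequence(
        name=record.id, seq=str(record.seq), numbering_offset=numbering_offset
    )


def write_fasta(ref: ReferenceSequence, path) -> None:
    record = SeqRecord(Seq(ref.seq), id=ref.name, description="")
    SeqIO.write([record], str(path), "fasta")
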