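"""Synthetic DMS-MaPseq libraries and spectral-count tables with known truth.

The generator emulates the raw inputs of a mutational-profiling probing
experiment on an rRNA: the molecule is fragmented, 50-80 nt fragments are
size-selected and ligated to a 3' adaptor, and reverse transcription reads
through DMS-methylated A/C bases leaving a point misincorporation in the
cDNA. A treated library therefore mutates each covered position
independently with probability

    p_eff = p_mod * rt_detect_prob + (1 - p_mod * rt_detect_prob) * seq_error_rate

while a mock (no-DMS) library carries background error only
(``p_eff = seq_error_rate``). The latent per-position modification
probability ``p_mod`` is zero at G/U and at protected A/C residues.

Ground truth (fragment origins in read names, planted differential
positions, expected accessibility levels) is recorded so every downstream
stage can be tested against what was simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .reference import (
    A,
    C,
    G,
    T,
    ReferenceSequence,
    decode_seq,
    encode_seq,
    make_reference,
)

#: Illumina TruSeq-style 3' adaptor ligated to the RNA fragments.
DEFAULT_ADAPTOR = "GATCGGAAGAGCACACGTCTGAACTCCAGTCA"

#: Constant Phred quality emitted for simulated bases.
DEFAULT_QUALITY = 37


@dataclass
class SimulationConfig:
    """Parameters of one simulated sequencing library.

    read_depth
        Expected number of reads per library.
    fragment_length_range
        Inclusive (min, max) size-selection window, default (50, 80) nt.
    rt_detect_prob
        Probability that a modified template position yields a cDNA
        misincorporation (RT read-through detection efficiency).
    seq_error_rate
        Per-base background mutation probability (RT + sequencing error),
        the only signal in mock libraries.
    adaptor
        Adaptor appended at the 3' end of every fragment.
    n_replicates
        Biological replicates per condition.
    rng_seed
        Mandatory seed; identical config + seed gives byte-identical output.
    """

    read_depth: int = 250_000
    fragment_length_range: tuple[int, int] = (50, 80)
    rt_detect_prob: float = 0.5
    seq_error_rate: float = 0.01
    adaptor: str = DEFAULT_ADAPTOR
    n_replicates: int = 2
    rng_seed: int = 42

    def validate(self, ref_length: int | None = None) -> None:
        lo, hi = self.fragment_length_range
        if not (1 <= lo <= hi):
            raise ValueError("fragment_length_range must satisfy 1 <= min <= max")
        for name in ("rt_detect_prob", "seq_error_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.rng_seed is None:
            raise ValueError("rng_seed is mandatory for reproducibility")
        if ref_length is not None and hi > ref_length:
            raise ValueError(
                f"max fragment size {hi} exceeds reference length {ref_length}"
            )


@dataclass
class ModificationProfile:
    """Latent per-position DMS modification probability for one condition."""

    condition: str
    p_mod: np.ndarray

    def validate(self, ref: ReferenceSequence) -> None:
        p = np.asarray(self.p_mod, dtype=float)
        if p.shape != (ref.length,):
            raise ValueError("p_mod length must equal reference length")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p_mod must lie in [0, 1]")
        unreactive = (ref.codes == G) | (ref.codes == T)
        if (p[unreactive] != 0).any():
            raise ValueError("p_mod must be 0 at unreactive (G/U) positions")


def effective_mutation_rate(
    p_mod: np.ndarray | float, cfg: SimulationConfig, treated: bool = True
) -> np.ndarray | float:
    """Closed-form per-position mutation probability of a simulated library."""
    if not treated:
        return np.broadcast_to(cfg.seq_error_rate, np.shape(p_mod)).copy() if np.ndim(p_mod) else cfg.seq_error_rate
    detected = np.asarray(p_mod, dtype=float) * cfg.rt_detect_prob
    out = detected + (1.0 - detected) * cfg.seq_error_rate
    return out if np.ndim(p_mod) else float(out)


def expected_net_accessibility(p_mod, cfg: SimulationConfig):
    """Expected net accessibility score of a position with modification
    probability ``p_mod``: treated rate scaled by the untreated class mean
    (= seq_error_rate in expectation) minus the equally scaled untreated rate.
    """
    p_eff = effective_mutation_rate(p_mod, cfg, treated=True)
    return p_eff / cfg.seq_error_rate - 1.0


def p_mod_for_net(net, cfg: SimulationConfig):
    """Invert :func:`expected_net_accessibility`: the ``p_mod`` whose expected
    net accessibility equals ``net``."""
    p = np.asarray(net, dtype=float) * cfg.seq_error_rate / (
        cfg.rt_detect_prob * (1.0 - cfg.seq_error_rate)
    )
    return p if np.ndim(net) else float(p)


# ---------------------------------------------------------------------------
# Baseline accessibility and planted differential effects
# ---------------------------------------------------------------------------


@dataclass
class BaselineSpec:
    """Mixture of accessibility levels assigned to A/C positions.

    ``levels`` maps an expected net-accessibility value to its mixture
    weight. The default emulates the roughly bimodal reactivity of a folded,
    protein-bound rRNA: 70% protected (no signal), 20% moderately
    accessible, 10% highly accessible.
    """

    levels: tuple[tuple[float, float], ...] = ((0.0, 0.70), (1.5, 0.20), (3.0, 0.10))

    def validate(self) -> None:
        weights = np.array([w for _, w in self.levels])
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("baseline level weights must sum to 1")
        if (weights < 0).any():
            raise ValueError("baseline level weights must be non-negative")


@dataclass
class PlantedChange:
    """One planted differential position.

    Exactly one of ``net_to`` (target expected net accessibility in
    condition 2) or ``fold`` (multiplier on ``p_mod``) defines the effect.
    """

    position: int
    direction: str  # "up" | "down"
    net_from: float | None = None
    net_to: float | None = None
    fold: float | None = None


@dataclass
class GroundTruth:
    """Planted truth behind a simulated two-condition comparison."""

    changes: list[PlantedChange]
    condition1: str
    condition2: str

    @property
    def up_positions(self) -> list[int]:
        return [c.position for c in self.changes if c.direction == "up"]

    @property
    def down_positions(self) -> list[int]:
        return [c.position for c in self.changes if c.direction == "down"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "condition1": self.condition1,
                "condition2": self.condition2,
                "changes": [asdict(c) for c in self.changes],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            changes=[PlantedChange(**c) for c in obj["changes"]],
            condition1=obj["condition1"],
            condition2=obj["condition2"],
        )


def plant_profile(
    ref: ReferenceSequence,
    cfg: SimulationConfig,
    baseline: BaselineSpec | None = None,
    changes: Sequence[PlantedChange] | None = None,
    n_up: int = 0,
    n_down: int = 0,
    seed: int | None = None,
    conditions: tuple[str, str] = ("wt", "mutant"),
    edge_exclude: int | None = None,
) -> tuple[ModificationProfile, ModificationProfile, GroundTruth]:
    """Draw a baseline modification profile and plant differential positions.

    Baseline accessibility levels are assigned at random to every A/C
    position. Differential positions are then either taken from an explicit
    ``changes`` list or auto-selected (``n_up`` increases, ``n_down``
    decreases), each sized so the expected net accessibility crosses at
    least one bin boundary: protected positions are raised to net 1.5
    (bin 0 -> 2) or moderate ones to 3.0 (bin 2 -> 3); decreases drop a
    moderate position to net 0.1 (bin 2 -> 0). Auto-selected positions are
    restricted to the interior at least ``edge_exclude`` (default: the
    maximum fragment length) from either end, where fragment geometry
    gives full, even coverage. The two returned profiles are identical
    everywhere except at the planted positions.
    """
    baseline = baseline or BaselineSpec()
    baseline.validate()
    cfg.validate(ref.length)
    rng = np.random.default_rng(seed if seed is not None else cfg.rng_seed)

    ac = ref.ac_positions()
    nets = np.array([lv for lv, _ in baseline.levels])
    weights = np.array([w for _, w in baseline.levels])
    level_idx = rng.choice(len(nets), size=ac.size, p=weights)
    baseline_net = dict(zip(ac.tolist(), nets[level_idx].tolist()))

    p1 = np.zeros(ref.length)
    p1[ac - 1] = p_mod_for_net(nets[level_idx], cfg)

    if changes is None:
        if edge_exclude is None:
            edge_exclude = cfg.fragment_length_range[1]
        interior = (ac > edge_exclude) & (ac <= ref.length - edge_exclude)
        changes = _auto_changes(ac[interior], nets, level_idx[interior], n_up, n_down, rng)
    resolved: list[PlantedChange] = []
    p2 = p1.copy()
    for ch in changes:
        pos = int(ch.position)
        if ref.base_at(pos) not in "AC":
            raise ValueError(
                f"planted position {pos} is {ref.base_at(pos)}; only A/C can be planted"
            )
        if ch.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {ch.direction!r}")
        if (ch.net_to is None) == (ch.fold is None):
            raise ValueError("exactly one of net_to or fold must be given")
        if ch.fold is not None:
            p2[pos - 1] = min(1.0, p1[pos - 1] * ch.fold)
            net_to = expected_net_accessibility(p2[pos - 1], cfg)
        else:
            net_to = ch.net_to
            p2[pos - 1] = p_mod_for_net(net_to, cfg)
        net_from = baseline_net.get(pos, expected_net_accessibility(p1[pos - 1], cfg))
        delta = net_to - net_from
        if (ch.direction == "up") != (delta > 0):
            raise ValueError(
                f"planted position {pos}: direction {ch.direction} inconsistent "
                f"with net change {net_from} -> {net_to}"
            )
        resolved.append(
            PlantedChange(
                position=pos,
                direction=ch.direction,
                net_from=float(net_from),
                net_to=float(net_to),
                fold=ch.fold,
            )
        )

    prof1 = ModificationProfile(condition=conditions[0], p_mod=p1)
    prof2 = ModificationProfile(condition=conditions[1], p_mod=p2)
    truth = GroundTruth(changes=resolved, condition1=conditions[0], condition2=conditions[1])
    return prof1, prof2, truth


def _auto_changes(ac, nets, level_idx, n_up, n_down, rng) -> list[PlantedChange]:
    """Pick planted positions among A/C residues, alternating effect shapes."""
    protected = ac[nets[level_idx] == 0.0]
    moderate = ac[nets[level_idx] == 1.5]
    protected = rng.permutation(protected)
    moderate = rng.permutation(moderate)
    need_mod = (n_up + 1) // 2 + n_down
    if len(moderate) < need_mod or len(protected) < n_up - (n_up + 1) // 2 + 1:
        raise ValueError("reference too small for the requested planted changes")
    changes: list[PlantedChange] = []
    pi = mi = 0
    for k in range(n_up):
        if k % 2 == 0:  # protected -> moderately accessible (bin 0 -> 2)
            changes.append(PlantedChange(int(protected[pi]), "up", net_to=1.5))
            pi += 1
        else:  # moderate -> highly accessible (bin 2 -> 3)
            changes.append(PlantedChange(int(moderate[mi]), "up", net_to=3.0))
            mi += 1
    for _ in range(n_down):  # moderate -> protected (bin 2 -> 0)
        changes.append(PlantedChange(int(moderate[mi]), "down", net_to=0.1))
        mi += 1
    return changes


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadBatch:
    """A set of simulated (or parsed) reads in columnar form.

    ``seqs`` is a padded (n_reads, width) uint8 code matrix; only the first
    ``lengths[i]`` columns starting at ``offsets[i]`` are live for read
    ``i``. ``origins`` records the true 1-based reference start of the
    *currently live* first base (-1 when unknown), which survives trimming
    so placement can be checked against the truth without alignment.
    """

    seqs: np.ndarray
    lengths: np.ndarray
    origins: np.ndarray
    offsets: np.ndarray | None = None
    quality: int = DEFAULT_QUALITY
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.offsets is None:
            self.offsets = np.zeros(len(self.lengths), dtype=np.int64)

    def __len__(self) -> int:
        return len(self.lengths)

    def sequence(self, i: int) -> str:
        o = self.offsets[i]
        return decode_seq(self.seqs[i, o : o + self.lengths[i]])

    def read_id(self, i: int) -> str:
        if self.ids is not None:
            return self.ids[i]
        return f"read{i}|origin={self.origins[i]}|len={self.lengths[i]}"


def simulate_library(
    ref: ReferenceSequence,
    profile: ModificationProfile,
    cfg: SimulationConfig,
    treated: bool,
    seed: int | None = None,
) -> ReadBatch:
    """Simulate one sequencing library as a :class:`ReadBatch`.

    Fragments are placed uniformly over valid start positions with lengths
    uniform over the size-selection window; each fragment base mutates
    independently with the effective rate for its position (background only
    when ``treated`` is False); the adaptor is appended error-free at the
    3' end. Deterministic for a fixed seed.
    """
    cfg.validate(ref.length)
    profile.validate(ref)
    rng = np.random.default_rng(seed if seed is not None else cfg.rng_seed)

    n = cfg.read_depth
    lo, hi = cfg.fragment_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    starts = 1 + rng.integers(0, ref.length - lengths + 1)  # 1-based, vector bound

    adaptor = encode_seq(cfg.adaptor)
    alen = adaptor.size
    width = hi + alen

    # template bases over the widest possible fragment; columns past each
    # read's fragment are overwritten by the adaptor/padding below
    pos0 = starts.astype(np.int32)[:, None] - 1 + np.arange(hi, dtype=np.int32)
    np.minimum(pos0, ref.length - 1, out=pos0)
    frag = ref.codes[pos0]

    p_eff = effective_mutation_rate(profile.p_mod, cfg, treated=treated)
    p_eff = np.broadcast_to(np.asarray(p_eff, dtype=np.float32), (ref.length,))
    u = rng.random(size=frag.shape, dtype=np.float32)
    idx = np.nonzero(u < p_eff[pos0])
    if idx[0].size:
        shift = rng.integers(1, 4, size=idx[0].size).astype(np.uint8)
        frag[idx] = (frag[idx] + shift) % 4

    seqs = np.empty((n, width), dtype=np.uint8)
    seqs[:, :hi] = frag
    seqs[:, hi:] = 255
    # adaptor appended error-free at the 3' end, grouped by fragment length
    for L in range(lo, hi + 1):
        rows = lengths == L
        if rows.any():
            seqs[rows, L : L + alen] = adaptor
            seqs[rows, L + alen : hi + alen] = 255
    return ReadBatch(
        seqs=seqs,
        lengths=(lengths + alen).astype(np.int64),
        origins=starts.astype(np.int64),
    )


def write_fastq(batch: ReadBatch, path) -> None:
    """Write a batch as Sanger/Phred+33 FASTQ, origins encoded in read names."""
    qchar = chr(batch.quality + 33)
    with open(path, "w") as fh:
        for i in range(len(batch)):
            seq = batch.sequence(i)
            fh.write(f"@{batch.read_id(i)}\n{seq}\n+\n{qchar * len(seq)}\n")


def read_fastq(path) -> ReadBatch:
    """Read a FASTQ file (as written by :func:`write_fastq` or external) into
    a batch; ``origin=`` tags in read names are recovered when present."""
    ids: list[str] = []
    seq_strings: list[str] = []
    origins: list[int] = []
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seq_strings.append(str(rec.seq))
        origin = -1
        for tok in rec.id.split("|"):
            if tok.startswith("origin="):
                origin = int(tok.split("=", 1)[1])
        origins.append(origin)
    if not ids:
        raise ValueError(f"no reads in {path}")
    lengths = np.array([len(s) for s in seq_strings], dtype=np.int64)
    width = int(lengths.max())
    seqs = np.full((len(ids), width), 255, dtype=np.uint8)
    for i, s in enumerate(seq_strings):
        seqs[i, : len(s)] = encode_seq(s)
    return ReadBatch(
        seqs=seqs,
        lengths=lengths,
        origins=np.array(origins, dtype=np.int64),
        ids=ids,
    )


# ---------------------------------------------------------------------------
# Spectral counts
# ---------------------------------------------------------------------------


def simulate_spectral_counts(
    abundance: Sequence[float] | np.ndarray,
    total_spectra: int,
    n_replicates: int,
    seed: int,
    proteins: Sequence[str] | None = None,
    condition: str = "cond",
):
    """Multinomial spectral-count table for one condition.

    Each replicate draws ``total_spectra`` spectra over proteins with
    probabilities proportional to ``abundance``; column sums equal
    ``total_spectra`` exactly. Returns a protein x sample DataFrame with
    columns ``{condition}_rep{r}``.
    """
    import pandas as pd

    abundance = np.asarray(abundance, dtype=float)
    if (abundance < 0).any() or abundance.sum() <= 0:
        raise ValueError("abundances must be non-negative and not all zero")
    if total_spectra <= 0:
        raise ValueError("total_spectra must be positive")
    if proteins is None:
        proteins = [f"protein{i + 1}" for i in range(abundance.size)]
    rng = np.random.default_rng(seed)
    probs = abundance / abundance.sum()
    counts = rng.multinomial(total_spectra, probs, size=n_replicates).T
    cols = [f"{condition}_rep{r + 1}" for r in range(n_replicates)]
    return pd.DataFrame(counts, index=list(proteins), columns=cols)


@dataclass
class OccupancyScenario:
    """Planted protein-occupancy scenario behind a mutant-vs-wt MS comparison.

    Defaults emulate a 40S-subunit protein table: 50 proteins of comparable
    abundance, three biological replicates of 100,000 spectra each, and a
    few proteins depleted in the mutant (factors 0.8 / 0.5 / 0.2, the rest
    unchanged).
    """

    n_proteins: int = 50
    total_spectra: int = 100_000
    n_replicates: int = 3
    depleted_factors: tuple[float, ...] = (0.8, 0.5, 0.2)

    def planted_factors(self) -> np.ndarray:
        f = np.ones(self.n_proteins)
        f[: len(self.depleted_factors)] = self.depleted_factors
        return f

    def expected_measured_ratio(self, base_abundance: np.ndarray) -> np.ndarray:
        """Expected mutant/wt fraction ratio after per-sample total
        normalization (planted factor rescaled by the compositional mean)."""
        f = self.planted_factors()
        scale = (base_abundance * f).sum() / base_abundance.sum()
        return f / scale


def simulate_occupancy_tables(scn: OccupancyScenario, seed: int):
    """Simulate paired wt and mutant spectral-count tables plus planted truth.

    Returns ``(counts, sample_sheet, truth)`` where ``counts`` joins both
    conditions column-wise, ``sample_sheet`` maps columns to
    (condition, replicate), and ``truth`` holds the planted and expected
    measured occupancy factors per protein.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    s_wt, s_mut = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    # comparable but not identical protein abundances (detectability spread)
    base = rng.lognormal(mean=0.0, sigma=0.25, size=scn.n_proteins)
    proteins = [f"Rp{i + 1:02d}" for i in range(scn.n_proteins)]
    wt = simulate_spectral_counts(
        base, scn.total_spectra, scn.n_replicates, s_wt, proteins, condition="wt"
    )
    factors = scn.planted_factors()
    mut = simulate_spectral_counts(
        base * factors, scn.total_spectra, scn.n_replicates, s_mut, proteins, condition="mutant"
    )
    counts = pd.concat([wt, mut], axis=1)
    sheet = pd.DataFrame(
        {
            "sample": list(counts.columns),
            "condition": ["wt"] * scn.n_replicates + ["mutant"] * scn.n_replicates,
            "replicate": list(range(1, scn.n_replicates + 1)) * 2,
        }
    )
    truth = pd.DataFrame(
        {
            "protein": proteins,
            "planted_factor": factors,
            "expected_ratio": scn.expected_measured_ratio(base),
        }
    ).set_index("protein")
    return counts, sheet, truth
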