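"""Trimming and placement: per-read contracts, batch/single-read agreement,
ground-truth recovery on simulated reads, SAM interoperability."""

import numpy as np
import pytest

from dmsdelta import (
    DEFAULT_ADAPTOR,
    Read,
    SimulationConfig,
    make_reference,
    place_read,
    place_reads,
    read_sam,
    simulate_library,
    trim_adaptor,
    trim_adaptor_batch,
    trim_ends_and_quality,
    trim_ends_batch,
    write_sam,
)
from dmsdelta.reads import AlignedRead, PlacementStats
from dmsdelta.reference import encode_seq
from dmsdelta.simulate import ModificationProfile


def _read(seq, q=37, rid="r"):
    return Read(rid, seq, np.full(len(seq), q))


def _mock_batch(ref, cfg, seed=1, p=0.0, treated=False):
    p_mod = np.zeros(ref.length)
    p_mod[ref.ac_positions() - 1] = p
    return simulate_library(
        ref, ModificationProfile("c", p_mod), cfg, treated=treated, seed=seed
    )


class TestTrimAdaptor:
    def test_full_adaptor_removed_exactly(self):
        frag = "ACGTACGTACGTACGTACGTACGT"
        read = _read(frag + DEFAULT_ADAPTOR)
        out = trim_adaptor(read, DEFAULT_ADAPTOR)
        assert out.sequence == frag
        assert len(out.qualities) == len(frag)

    def test_no_adaptor_read_unchanged(self):
        read = _read("ACGTACGTACGTACGTACGTACGTACGTACGT")
        out = trim_adaptor(read, DEFAULT_ADAPTOR)
        assert out.sequence == read.sequence

    def test_partial_adaptor_at_end_with_tolerated_mismatch(self):
        frag = "ACGTACGTACGTACGTACGT"
        partial = DEFAULT_ADAPTOR[:14]
        mutated = partial[:5] + ("A" if partial[5] != "A" else "C") + partial[6:]
        out = trim_adaptor(_read(frag + mutated), DEFAULT_ADAPTOR)
        assert out.sequence == frag  # 1 mismatch allowed per 10 bases

    def test_everything_three_prime_of_match_removed(self):
        frag = "ACGTACGTACGTACGTACGT"
        read = _read(frag + DEFAULT_ADAPTOR + "TTTT")
        out = trim_adaptor(read, DEFAULT_ADAPTOR)
        assert out.sequence == frag

    def test_trimming_never_lengthens(self, rng):
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            out = trim_adaptor(_read(seq), DEFAULT_ADAPTOR)
            assert len(out) <= 60

    def test_simulated_reads_recover_fragment_exactly(self, small_ref):
        # simulator ground truth as oracle: with no sequencing error, the
        # pre-adaptor fragment is recovered for every read
        cfg = SimulationConfig(read_depth=1000, seq_error_rate=0.0, rng_seed=1)
        batch = _mock_batch(small_ref, cfg, seed=2)
        trimmed = trim_adaptor_batch(batch, cfg.adaptor)
        frag_lens = batch.lengths - len(cfg.adaptor)
        assert np.array_equal(trimmed.lengths, frag_lens)
        for i in range(0, 1000, 97):
            frag = trimmed.sequence(i)
            start = trimmed.origins[i]
            assert small_ref.seq[start - 1 : start - 1 + len(frag)] == frag

    def test_batch_agrees_with_per_read_function(self, small_ref):
        cfg = SimulationConfig(read_depth=300, seq_error_rate=0.004, rng_seed=1)
        batch = _mock_batch(small_ref, cfg, seed=3)
        trimmed = trim_adaptor_batch(batch, cfg.adaptor)
        for i in range(0, 300, 13):
            single = trim_adaptor(_read(batch.sequence(i)), cfg.adaptor)
            assert single.sequence == trimmed.sequence(i)


class TestTrimEndsAndQuality:
    def test_fixed_end_trim_arithmetic(self):
        read = _read("A" * 60)
        out = trim_ends_and_quality(read)
        assert len(out) == 50  # positions 6-55 of the input

    def test_short_read_discarded(self):
        assert trim_ends_and_quality(_read("ACGTACGTAC")) is None

    def test_low_quality_tail_trimmed(self):
        q = np.full(60, 37)
        q[-9:] = 10  # 5 removed by end trim, 4 more by quality
        read = Read("r", "A" * 60, q)
        out = trim_ends_and_quality(read)
        assert len(out) == 46

    def test_idempotent_on_trimmed_reads(self):
        read = _read("ACGT" * 20)
        once = trim_ends_and_quality(read, n5=0, n3=0, qmin=20)
        twice = trim_ends_and_quality(once, n5=0, n3=0, qmin=20)
        assert twice.sequence == once.sequence

    def test_batch_matches_single(self, small_ref):
        cfg = SimulationConfig(read_depth=100, rng_seed=1)
        batch = trim_adaptor_batch(_mock_batch(small_ref, cfg, seed=4), cfg.adaptor)
        out, n_discarded = trim_ends_batch(batch)
        assert n_discarded == 0  # fragments >= 50 nt survive 10 nt of trims
        for i in range(0, len(out), 11):
            single = trim_ends_and_quality(_read(batch.sequence(i)))
            assert single.sequence == out.sequence(i)
        # origins shifted by the 5' trim
        assert np.array_equal(out.origins, batch.origins + 5)


class TestPlacement:
    def test_exact_mode_places_error_free_read(self, small_ref):
        start = 101
        seq = small_ref.seq[start - 1 : start - 1 + 40]
        aln = place_read(_read(seq), small_ref, mode="exact")
        assert aln.start == start and aln.length == 40
        assert aln.matches(small_ref).all()

    def test_ambiguous_read_dropped_and_counted(self):
        ref = make_reference(200, composition=[1, 0, 0, 0], seed=1)
        stats = PlacementStats()
        aln = place_read(_read("A" * 30), ref, mode="exact", stats=stats)
        assert aln is None and stats.ambiguous == 1
        stats2 = PlacementStats()
        aln2 = place_read(_read("A" * 30), ref, mode="seeded", stats=stats2)
        assert aln2 is None and stats2.ambiguous == 1

    def test_seeded_mode_tolerates_mismatches(self, small_ref):
        start = 50
        seq = list(small_ref.seq[start - 1 : start - 1 + 40])
        seq[25] = "A" if seq[25] != "A" else "C"  # one error outside the seed
        aln = place_read(_read("".join(seq)), small_ref, mode="seeded")
        assert aln.start == start
        assert (~aln.matches(small_ref)).sum() == 1

    def test_high_mismatch_read_rejected(self, small_ref):
        start = 50
        seq = list(small_ref.seq[start - 1 : start - 1 + 40])
        for i in range(20, 40):  # 50% mismatches, seed region intact
            seq[i] = "ACGT"[("ACGT".index(seq[i]) + 1) % 4]
        stats = PlacementStats()
        aln = place_read(_read("".join(seq)), small_ref, stats=stats)
        assert aln is None and stats.unplaced == 1

    def test_simulated_reads_place_at_true_origin(self):
        # ground-truth oracle: >= 99% of reads placed at the origin recorded
        # in the batch at a realistic sequencing error rate
        ref = make_reference(1000, seed=5)
        cfg = SimulationConfig(read_depth=10_000, seq_error_rate=0.001, rng_seed=1)
        batch = _mock_batch(ref, cfg, seed=6)
        trimmed = trim_adaptor_batch(batch, cfg.adaptor)
        trimmed, _ = trim_ends_batch(trimmed)
        aln, stats, placed_idx = place_reads(trimmed, ref)
        assert stats.placed + stats.unplaced + stats.ambiguous == len(trimmed)
        correct = aln.starts == trimmed.origins[placed_idx]
        assert correct.sum() / len(trimmed) >= 0.99

    def test_batch_agrees_with_single_read_placement(self, small_ref):
        cfg = SimulationConfig(read_depth=200, seq_error_rate=0.01, rng_seed=1)
        batch = _mock_batch(small_ref, cfg, seed=7, p=0.02, treated=True)
        trimmed = trim_adaptor_batch(batch, cfg.adaptor)
        trimmed, _ = trim_ends_batch(trimmed)
        aln, stats, placed_idx = place_reads(trimmed, small_ref)
        batch_starts = dict(zip(placed_idx.tolist(), aln.starts.tolist()))
        for i in range(len(trimmed)):
            single = place_read(_read(trimmed.sequence(i)), small_ref)
            if single is None:
                assert i not in batch_starts
            else:
                assert batch_starts[i] == single.start

    def test_placement_within_reference_bounds(self, small_ref):
        with pytest.raises(ValueError, match="start"):
            AlignedRead("r", 0, encode_seq("ACGT"))
        aln = AlignedRead("r", small_ref.length - 1, encode_seq("ACGT"))
        with pytest.raises(ValueError, match="exceeds"):
            aln.matches(small_ref)


class TestSamIO:
    def test_perfect_record_semantics(self, tmp_path, small_ref):
        sam = tmp_path / "one.sam"
        seq = small_ref.seq[100:150]
        sam.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{small_ref.name}\tLN:{small_ref.length}\n"
            f"r1\t0\t{small_ref.name}\t101\t60\t50M\t*\t0\t0\t{seq}\t{'I' * 50}\n"
        )
        alns = list(read_sam(sam))
        assert len(alns) == 1
        assert alns[0].start == 101 and alns[0].length == 50
        assert alns[0].matches(small_ref).all()

    def test_unmapped_and_gapped_records_skipped(self, tmp_path, small_ref):
        sam = tmp_path / "skip.sam"
        sam.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{small_ref.name}\tLN:{small_ref.length}\n"
            f"un\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"
            f"gap\t0\t{small_ref.name}\t10\t60\t10M2D10M\t*\t0\t0\t{'A' * 20}\t{'I' * 20}\n"
        )
        assert list(read_sam(sam)) == []

    def test_soft_clips_excluded_from_span(self, tmp_path, small_ref):
        sam = tmp_path / "clip.sam"
        seq = "TTTT" + small_ref.seq[200:240]
        sam.write_text(
            f"@HD\tVN:1.6\n@SQ\tSN:{small_ref.name}\tLN:{small_ref.length}\n"
            f"r1\t0\t{small_ref.name}\t201\t60\t4S40M\t*\t0\t0\t{seq}\t{'I' * 44}\n"
        )
        (aln,) = list(read_sam(sam))
        assert aln.start == 201 and aln.length == 40
        assert aln.matches(small_ref).all()

    def test_roundtrip_preserves_placements(self, tmp_path, small_ref):
        cfg = SimulationConfig(read_depth=100, seq_error_rate=0.01, rng_seed=1)
        batch = _mock_batch(small_ref, cfg, seed=8)
        trimmed = trim_adaptor_batch(batch, cfg.adaptor)
        trimmed, _ = trim_ends_batch(trimmed)
        aln, _, placed_idx = place_reads(trimmed, small_ref)
        originals = aln.to_aligned_reads()
        path = tmp_path / "round.sam"
        write_sam(originals, small_ref, path)
        back = list(read_sam(path))
        assert len(back) == len(originals)
        for a, b in zip(originals, back):
            assert a.start == b.start
            assert np.array_equal(a.codes, b.codes)
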