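"""Simulator behavior: determinism, planted effects, read statistics,
fragment geometry, and spectral-count sampling."""

import numpy as np
import pytest
from scipy import stats as sps

from dmsdelta import (
    BaselineSpec,
    PlantedChange,
    SimulationConfig,
    effective_mutation_rate,
    expected_net_accessibility,
    make_reference,
    p_mod_for_net,
    plant_profile,
    simulate_library,
    simulate_spectral_counts,
)
from dmsdelta.profile import expected_coverage_profile
from dmsdelta.simulate import ModificationProfile, read_fastq, write_fastq


def _uniform_profile(ref, p, condition="c"):
    p_mod = np.zeros(ref.length)
    p_mod[ref.ac_positions() - 1] = p
    return ModificationProfile(condition=condition, p_mod=p_mod)


class TestPlantProfile:
    def test_no_effect_profiles_identical(self, small_ref, small_cfg):
        p1, p2, truth = plant_profile(small_ref, small_cfg, changes=[], seed=5)
        assert np.array_equal(p1.p_mod, p2.p_mod)
        assert truth.changes == []

    def test_fourteen_up_one_down_scenario_shape(self, small_cfg):
        ref = make_reference(1800, seed=2)
        _, _, truth = plant_profile(ref, small_cfg, n_up=14, n_down=1, seed=5)
        assert len(truth.changes) == 15
        assert len(truth.up_positions) == 14
        assert len(truth.down_positions) == 1
        # planted positions are A/C and the profiles differ only there
        for c in truth.changes:
            assert ref.base_at(c.position) in "AC"

    def test_profiles_differ_only_at_planted_positions(self, small_ref, small_cfg):
        p1, p2, truth = plant_profile(small_ref, small_cfg, n_up=2, n_down=1, seed=5)
        diff = np.flatnonzero(p1.p_mod != p2.p_mod) + 1
        assert sorted(diff) == sorted(c.position for c in truth.changes)

    def test_directions_honored(self, small_ref, small_cfg):
        p1, p2, truth = plant_profile(small_ref, small_cfg, n_up=2, n_down=1, seed=5)
        for c in truth.changes:
            if c.direction == "up":
                assert p2.p_mod[c.position - 1] > p1.p_mod[c.position - 1]
            else:
                assert p2.p_mod[c.position - 1] < p1.p_mod[c.position - 1]

    def test_fold_effect_is_exact(self, small_ref, small_cfg):
        p1, _, _ = plant_profile(small_ref, small_cfg, changes=[], seed=5)
        # pick an A/C position with nonzero baseline to double
        pos = int(np.flatnonzero(p1.p_mod > 0)[0]) + 1
        _, p2b, _ = plant_profile(
            small_ref, small_cfg,
            changes=[PlantedChange(position=pos, direction="up", fold=2.0)], seed=5,
        )
        assert p2b.p_mod[pos - 1] == pytest.approx(2.0 * p1.p_mod[pos - 1])

    def test_planting_on_gu_rejected(self, small_ref, small_cfg):
        gu = next(
            i + 1 for i, b in enumerate(small_ref.seq) if b in "GT"
        )
        with pytest.raises(ValueError, match="A/C"):
            plant_profile(
                small_ref, small_cfg,
                changes=[PlantedChange(position=gu, direction="up", net_to=2.0)],
            )

    def test_net_pmod_conversion_roundtrip(self, small_cfg):
        for net in (0.1, 0.5, 1.5, 3.0, 6.0):
            p = p_mod_for_net(net, small_cfg)
            assert expected_net_accessibility(p, small_cfg) == pytest.approx(net)


class TestSimulateLibrary:
    def test_deterministic_for_fixed_seed(self, small_ref, small_cfg):
        prof = _uniform_profile(small_ref, 0.02)
        a = simulate_library(small_ref, prof, small_cfg, treated=True, seed=9)
        b = simulate_library(small_ref, prof, small_cfg, treated=True, seed=9)
        assert np.array_equal(a.seqs, b.seqs)
        assert np.array_equal(a.origins, b.origins)

    def test_zero_noise_reads_are_reference_substrings(self, small_ref):
        cfg = SimulationConfig(read_depth=200, seq_error_rate=0.0, rng_seed=1)
        prof = _uniform_profile(small_ref, 0.0)
        batch = simulate_library(small_ref, prof, cfg, treated=False, seed=1)
        adaptor_len = len(cfg.adaptor)
        for i in range(len(batch)):
            frag = batch.sequence(i)[: batch.lengths[i] - adaptor_len]
            assert frag in small_ref.seq
            start = batch.origins[i]
            assert small_ref.seq[start - 1 : start - 1 + len(frag)] == frag

    def test_fragment_lengths_within_size_selection(self, small_ref, small_cfg):
        prof = _uniform_profile(small_ref, 0.02)
        batch = simulate_library(small_ref, prof, small_cfg, treated=True, seed=3)
        lo, hi = small_cfg.fragment_length_range
        frag_lens = batch.lengths - len(small_cfg.adaptor)
        assert frag_lens.min() >= lo and frag_lens.max() <= hi

    def test_adaptor_appended_at_three_prime_end(self, small_ref, small_cfg):
        prof = _uniform_profile(small_ref, 0.02)
        batch = simulate_library(small_ref, prof, small_cfg, treated=True, seed=3)
        for i in range(0, len(batch), 500):
            assert batch.sequence(i).endswith(small_cfg.adaptor)

    def test_empirical_rate_matches_closed_form(self):
        # Monte-Carlo vs p_eff = p_mod*rt + (1 - p_mod*rt)*err at one position
        ref = make_reference(120, seed=4, min_fragment_span=80)
        cfg = SimulationConfig(
            read_depth=30_000, rt_detect_prob=0.5, seq_error_rate=0.001, rng_seed=1
        )
        pos = int(ref.ac_positions()[ref.ac_positions() > 60][0])
        p_mod = np.zeros(ref.length)
        p_mod[pos - 1] = 0.2
        prof = ModificationProfile("c", p_mod)
        batch = simulate_library(ref, prof, cfg, treated=True, seed=2)
        covered = (batch.origins <= pos) & (
            batch.origins + batch.lengths - len(cfg.adaptor) - 1 >= pos
        )
        col = pos - batch.origins[covered]
        bases = batch.seqs[np.flatnonzero(covered), col]
        mutated = bases != ref.codes[pos - 1]
        p_eff = 0.2 * 0.5 + (1 - 0.2 * 0.5) * 0.001
        assert p_eff == pytest.approx(0.1009)
        n = covered.sum()
        se = np.sqrt(p_eff * (1 - p_eff) / n)
        assert abs(mutated.mean() - p_eff) < 3 * se

    def test_mock_libraries_carry_no_positional_signal(self, small_ref):
        # per-position mock rates consistent with the background error rate
        # (binomial test, Bonferroni across positions)
        cfg = SimulationConfig(read_depth=20_000, rng_seed=1)
        prof = _uniform_profile(small_ref, 0.3)  # ignored when mock
        batch = simulate_library(small_ref, prof, cfg, treated=False, seed=6)
        adaptor_len = len(cfg.adaptor)
        cov = np.zeros(small_ref.length, dtype=int)
        mut = np.zeros(small_ref.length, dtype=int)
        frag_lens = batch.lengths - adaptor_len
        for i in range(len(batch)):
            s, L = batch.origins[i] - 1, frag_lens[i]
            cov[s : s + L] += 1
            mut[s : s + L] += batch.seqs[i, :L] != small_ref.codes[s : s + L]
        alpha = 0.01 / small_ref.length
        n_reject = sum(
            sps.binomtest(int(m), int(c), cfg.seq_error_rate).pvalue < alpha
            for m, c in zip(mut, cov)
            if c > 0
        )
        assert n_reject == 0

    def test_coverage_geometry_matches_enumeration_oracle(self, small_ref):
        cfg = SimulationConfig(read_depth=60_000, rng_seed=1)
        prof = _uniform_profile(small_ref, 0.0)
        batch = simulate_library(small_ref, prof, cfg, treated=False, seed=8)
        frag_lens = batch.lengths - len(cfg.adaptor)
        cov = np.zeros(small_ref.length)
        np.add.at(cov, batch.origins - 1, 1)
        ends = batch.origins - 1 + frag_lens
        np.add.at(cov, ends[ends < small_ref.length], -1)
        cov = np.cumsum(cov)
        expected = expected_coverage_profile(
            small_ref.length, cfg.fragment_length_range, len(batch)
        )
        # interior flat, edges proportionally reduced; 4 SE Poisson slack
        resid = np.abs(cov - expected) / np.sqrt(np.maximum(expected, 1))
        assert (resid < 4).mean() > 0.99
        assert expected[0] < 0.1 * expected[small_ref.length // 2]

    def test_fastq_roundtrip(self, tmp_path, small_ref):
        cfg = SimulationConfig(read_depth=50, rng_seed=1)
        prof = _uniform_profile(small_ref, 0.05)
        batch = simulate_library(small_ref, prof, cfg, treated=True, seed=4)
        path = tmp_path / "reads.fastq"
        write_fastq(batch, path)
        back = read_fastq(path)
        assert len(back) == len(batch)
        assert np.array_equal(back.origins, batch.origins)
        for i in range(len(batch)):
            assert back.sequence(i) == batch.sequence(i)

    def test_invalid_config_rejected(self, small_ref):
        with pytest.raises(ValueError):
            SimulationConfig(seq_error_rate=1.5).validate()
        with pytest.raises(ValueError, match="fragment"):
            SimulationConfig(fragment_length_range=(80, 50)).validate()
        with pytest.raises(ValueError, match="exceeds reference"):
            SimulationConfig().validate(ref_length=60)


class TestSpectralCounts:
    def test_single_protein_receives_all_spectra(self):
        table = simulate_spectral_counts([5.0], 1000, 2, seed=1)
        assert (table.values == 1000).all()

    def test_column_sums_equal_total(self):
        table = simulate_spectral_counts([3.0, 1.0, 2.0], 10_000, 3, seed=2)
        assert (table.sum(axis=0) == 10_000).all()

    def test_count_ratio_matches_multinomial_oracle(self):
        table = simulate_spectral_counts([3.0, 1.0], 100_000, 1, seed=3)
        c = table.iloc[:, 0].to_numpy()
        p = 0.75
        se = np.sqrt(p * (1 - p) * 100_000)
        # counts of the 3x protein within 3 SE of 75,000 implies ratio ~ 3
        assert abs(c[0] - 75_000) < 3 * se

    def test_deterministic_for_fixed_seed(self):
        a = simulate_spectral_counts([1, 2, 3], 5000, 2, seed=9)
        b = simulate_spectral_counts([1, 2, 3], 5000, 2, seed=9)
        assert a.equals(b)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="total_spectra"):
            simulate_spectral_counts([1.0], 0, 1, seed=1)
        with pytest.raises(ValueError, match="abundance"):
            simulate_spectral_counts([0.0, 0.0], 100, 1, seed=1)


def test_baseline_spec_weights_validated():
    with pytest.raises(ValueError, match="sum to 1"):
        BaselineSpec(levels=((0.0, 0.5), (2.0, 0.2))).validate()
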