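"""End-to-end orchestration: simulate -> trim -> place -> count -> normalize
-> call (and the spectral-count occupancy branch), as one configured,
logged, reproducible run.

Two input modes exist. *Synthetic* mode generates the whole two-condition
probing experiment in memory from a scenario description and known seeds —
this is how the package exercises itself at full depth. *File* mode
consumes a sample sheet pointing at FASTQ or SAM files (one treated and
one mock library per condition and replicate) plus a reference FASTA.
Every stochastic stage derives its seed deterministically from the single
run seed, so re-running a config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accessibility as acc
from . import diffcall, msoccupancy, profile as prof
from . import reads as readsmod
from . import simulate as sims
from .reference import ReferenceSequence, make_reference, read_fasta, write_fasta


@dataclass
class ScenarioConfig:
    """The synthetic two-condition probing study.

    Defaults describe the emulated experiment: an 1,800-nt rRNA-sized
    reference probed in two conditions (wt and mutant) with two biological
    replicates of paired treated/mock libraries, and 14 planted
    accessibility increases plus 1 decrease, each sized to shift at least
    one bin in expectation.
    """

    ref_length: int = 1800
    n_up: int = 14
    n_down: int = 1
    conditions: tuple[str, str] = ("wt", "mutant")
    sim: sims.SimulationConfig = field(default_factory=sims.SimulationConfig)
    baseline: sims.BaselineSpec = field(default_factory=sims.BaselineSpec)
    coverage_floor: int = prof.DEFAULT_COVERAGE_FLOOR
    #: rates are additionally undefined below this fraction of the library's
    #: median coverage, excluding the thin fragment-geometry edges
    min_relative_coverage: float = 0.5
    numbering_offset: int = 0


@dataclass
class ScenarioResult:
    """Everything a scenario run produced, kept in memory."""

    ref: ReferenceSequence
    truth: sims.GroundTruth
    profiles: dict  # (condition, replicate, treatment) -> MutationProfile
    accessibility: dict  # (condition, replicate) -> AccessibilityProfile
    averages: dict  # condition -> AccessibilityProfile
    calls: list
    skipped_positions: list[int]
    call_summary: dict
    call_table: pd.DataFrame
    placement: dict  # (condition, replicate, treatment) -> PlacementStats


def run_scenario(scn: ScenarioConfig, seed: int | None = None) -> ScenarioResult:
    """Run the full probing pipeline on a freshly simulated scenario.

    The run seed (default: the scenario's simulator seed) is split into
    independent child seeds for the reference, the planted profiles, and
    each library, so libraries are independent but jointly reproducible.
    """
    seed = seed if seed is not None else scn.sim.rng_seed
    ss = np.random.SeedSequence(seed)
    n_libs = 2 * scn.sim.n_replicates * 2  # conditions x replicates x (DMS, mock)
    children = ss.spawn(2 + n_libs)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    ref = make_reference(
        scn.ref_length,
        seed=child_seeds[0],
        numbering_offset=scn.numbering_offset,
        min_fragment_span=scn.sim.fragment_length_range[1],
    )
    prof1, prof2, truth = sims.plant_profile(
        ref,
        scn.sim,
        baseline=scn.baseline,
        n_up=scn.n_up,
        n_down=scn.n_down,
        seed=child_seeds[1],
        conditions=scn.conditions,
    )

    index = readsmod.KmerIndex(ref)
    profiles: dict = {}
    placement: dict = {}
    access: dict = {}
    lib = 2
    for condition, mod_profile in zip(scn.conditions, (prof1, prof2)):
        for rep in range(1, scn.sim.n_replicates + 1):
            pair = {}
            for treatment in ("DMS", "mock"):
                label = prof.SampleLabel(condition, rep, treatment)
                batch = sims.simulate_library(
                    ref, mod_profile, scn.sim, treated=(treatment == "DMS"),
                    seed=child_seeds[lib],
                )
                lib += 1
                mp, stats = process_library(batch, ref, scn, label, index=index)
                profiles[(condition, rep, treatment)] = mp
                placement[(condition, rep, treatment)] = stats
                pair[treatment] = mp
            ap = acc.normalize_by_untreated_mean(
                pair["DMS"], pair["mock"], ref, condition=condition, replicate=rep
            )
            access[(condition, rep)] = acc.subtract_background(ap)

    averages = {
        c: acc.average_replicates(
            [access[(c, r)] for r in range(1, scn.sim.n_replicates + 1)]
        )
        for c in scn.conditions
    }
    c1, c2 = scn.conditions
    calls, skipped = diffcall.call_changes(
        [access[(c1, r)] for r in range(1, scn.sim.n_replicates + 1)],
        [access[(c2, r)] for r in range(1, scn.sim.n_replicates + 1)],
        cond1_avg=averages[c1],
        cond2_avg=averages[c2],
        ref=ref,
    )
    counts, table = diffcall.summarize(calls)
    return ScenarioResult(
        ref=ref,
        truth=truth,
        profiles=profiles,
        accessibility=access,
        averages=averages,
        calls=calls,
        skipped_positions=skipped,
        call_summary=counts,
        call_table=table,
        placement=placement,
    )


def process_library(
    batch: sims.ReadBatch,
    ref: ReferenceSequence,
    scn: ScenarioConfig,
    label: prof.SampleLabel,
    index: readsmod.KmerIndex | None = None,
):
    """Trim, place and count one library (the per-library pipeline)."""
    trimmed = readsmod.trim_adaptor_batch(batch, scn.sim.adaptor)
    trimmed, _ = readsmod.trim_ends_batch(trimmed)
    aln, stats, _ = readsmod.place_reads(trimmed, ref, index=index)
    mp = prof.count_mutations(aln, ref, sample=label)
    floor = effective_floor(mp, scn.coverage_floor, scn.min_relative_coverage)
    return prof.rate(mp, floor), stats


def effective_floor(
    mp: prof.MutationProfile, absolute_floor: int, min_relative: float
) -> int:
    """Coverage floor for one library: the absolute floor or ``min_relative``
    times the library's median coverage, whichever is larger. The relative
    part excludes reference edges where fragment-placement geometry leaves
    coverage too thin for a stable rate."""
    if min_relative <= 0:
        return absolute_floor
    return max(absolute_floor, int(np.ceil(min_relative * np.median(mp.coverage))))


def evaluate_against_truth(result: ScenarioResult) -> dict:
    """Sensitivity and false calls of a scenario run versus its planted truth."""
    called = {c.position: c for c in result.calls}
    planted = {c.position: c for c in result.truth.changes}
    hits = [
        p for p, t in planted.items()
        if p in called
        and called[p].direction
        == ("more_accessible" if t.direction == "up" else "more_protected")
    ]
    false_calls = [p for p in called if p not in planted]
    return {
        "n_planted": len(planted),
        "n_recovered": len(hits),
        "sensitivity": len(hits) / len(planted) if planted else float("nan"),
        "n_false_calls": len(false_calls),
        "false_positions": sorted(false_calls),
        "missed_positions": sorted(set(planted) - set(hits)),
    }


# ---------------------------------------------------------------------------
# Configured file-based runs
# ---------------------------------------------------------------------------


@dataclass
class SampleSheet:
    """Library inventory: one DMS and one mock entry per (condition,
    replicate), each naming its reads file (FASTQ or SAM)."""

    rows: pd.DataFrame  # sample, condition, replicate, treatment, path

    REQUIRED = ("sample", "condition", "replicate", "treatment", "path")

    def validate(self) -> list[str]:
        problems = []
        for col in self.REQUIRED:
            if col not in self.rows.columns:
                problems.append(f"sample sheet missing column {col!r}")
        if problems:
            return problems
        bad = set(self.rows["treatment"]) - {"DMS", "mock"}
        if bad:
            problems.append(f"unknown treatment values: {sorted(bad)}")
        for (cond, rep), grp in self.rows.groupby(["condition", "replicate"]):
            treatments = sorted(grp["treatment"])
            if treatments != ["DMS", "mock"]:
                problems.append(
                    f"({cond}, replicate {rep}) needs exactly one DMS and one "
                    f"mock library, found {treatments}"
                )
        return problems

    @classmethod
    def from_csv(cls, path) -> "SampleSheet":
        return cls(rows=pd.read_csv(path, sep=None, engine="python"))


@dataclass
class RunConfig:
    """A full run: either a synthetic scenario or file inputs, plus the
    parameters of every stage and an output directory."""

    output_dir: str
    seed: int = 42
    scenario: ScenarioConfig | None = None
    reference_path: str | None = None
    sample_sheet_path: str | None = None
    spectral_counts_path: str | None = None
    ms_sample_sheet_path: str | None = None
    coverage_floor: int = prof.DEFAULT_COVERAGE_FLOOR
    min_relative_coverage: float = 0.5
    qmin: int = 20
    min_read_length: int = 20
    adaptor: str = sims.DEFAULT_ADAPTOR
    bin_boundaries: tuple[float, ...] = diffcall.BinScale().boundaries
    min_spectra: int = msoccupancy.DEFAULT_MIN_SPECTRA
    conditions: tuple[str, str] = ("wt", "mutant")
    numbering_offset: int = 0
    mask_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scenario = raw.pop("scenario", None)
        if scenario is not None:
            sim_cfg = sims.SimulationConfig(**scenario.pop("sim", {}))
            baseline = scenario.pop("baseline", None)
            if baseline is not None:
                baseline = sims.BaselineSpec(
                    levels=tuple((float(a), float(b)) for a, b in baseline)
                )
            scenario = ScenarioConfig(
                sim=sim_cfg,
                **({"baseline": baseline} if baseline else {}),
                **{k: tuple(v) if k == "conditions" else v for k, v in scenario.items()},
            )
        cfg = cls(scenario=scenario, **raw)
        if cfg.scenario is not None:
            cfg.scenario.sim.rng_seed = cfg.seed
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """All violations at once; an empty list means the config is runnable."""
    problems: list[str] = []
    if config.coverage_floor < 0:
        problems.append(f"coverage_floor must be >= 0, got {config.coverage_floor}")
    if config.min_spectra < 0:
        problems.append(f"min_spectra must be >= 0, got {config.min_spectra}")
    b = np.asarray(config.bin_boundaries)
    if b.size != 5 or (np.diff(b) <= 0).any():
        problems.append(f"bin boundaries must be 5 strictly increasing values, got {list(b)}")
    if config.scenario is None:
        if config.reference_path is None or config.sample_sheet_path is None:
            if config.spectral_counts_path is None:
                problems.append(
                    "config needs either a synthetic scenario, or reference + "
                    "sample sheet paths, or spectral-count input"
                )
        for name in ("reference_path", "sample_sheet_path", "mask_path",
                     "spectral_counts_path", "ms_sample_sheet_path"):
            p = getattr(config, name)
            if p is not None and not Path(p).exists():
                problems.append(f"{name} does not exist: {p}")
        if config.sample_sheet_path and Path(config.sample_sheet_path).exists():
            problems.extend(SampleSheet.from_csv(config.sample_sheet_path).validate())
            sheet = SampleSheet.from_csv(config.sample_sheet_path)
            if set(sheet.rows.columns) >= set(SampleSheet.REQUIRED):
                base = Path(config.sample_sheet_path).parent
                for p in sheet.rows["path"]:
                    if not (base / p).exists() and not Path(p).exists():
                        problems.append(f"reads file does not exist: {p}")
    else:
        try:
            config.scenario.sim.validate(config.scenario.ref_length)
            config.scenario.baseline.validate()
        except ValueError as exc:
            problems.append(str(exc))
    return problems


def _setup_logging(outdir: Path) -> logging.Logger:
    log = logging.getLogger(f"dmsdelta.run.{outdir}")
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(message)s")
    for handler in (logging.StreamHandler(), logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)
    return log


def _read_mask(path) -> set[int]:
    """BED-like mask, 1-based inclusive start/end per line (chrom start end)."""
    masked: set[int] = set()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            start, end = int(parts[1]), int(parts[2])
            masked.update(range(start, end + 1))
    return masked


def run_all(config: RunConfig) -> dict:
    """Execute every configured stage and write the run directory.

    Outputs: per-sample mutation-profile TSVs, accessibility TSV, call
    table TSV, occupancy TSV (when MS input is present), a machine-readable
    ``summary.json``, a parameter ``manifest.json``, and ``run.log``. Any
    stage failure raises with a diagnostic naming the stage.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config:\n  " + "\n  ".join(problems))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _setup_logging(outdir)
    summary: dict = {"seed": config.seed}
    _write_manifest(config, outdir)

    try:
        if config.scenario is not None:
            summary.update(_run_dms_synthetic(config, outdir, log))
        elif config.reference_path and config.sample_sheet_path:
            summary.update(_run_dms_files(config, outdir, log))
    except Exception as exc:
        log.error("probing stage failed: %s", exc)
        raise RuntimeError(f"probing stage failed: {exc}") from exc

    if config.spectral_counts_path:
        try:
            summary.update(_run_ms(config, outdir, log))
        except Exception as exc:
            log.error("occupancy stage failed: %s", exc)
            raise RuntimeError(f"occupancy stage failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run complete: %s", outdir)
    return summary


def _write_manifest(config: RunConfig, outdir: Path) -> None:
    manifest = dataclasses.asdict(config)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _float_fmt(x) -> str:
    return f"{x:.6g}"


def _write_dms_outputs(config: RunConfig, result: ScenarioResult, outdir: Path, log) -> dict:
    write_fasta(result.ref, outdir / "reference.fasta")
    prof_frames = [
        mp.to_frame(result.ref) for mp in result.profiles.values()
    ]
    pd.concat(prof_frames).to_csv(
        outdir / "mutation_profiles.tsv", sep="\t", index=False, float_format=_float_fmt
    )
    acc_frames = [ap.to_frame() for ap in result.accessibility.values()]
    acc_frames += [ap.to_frame() for ap in result.averages.values()]
    pd.concat(acc_frames).to_csv(
        outdir / "accessibility.tsv", sep="\t", index=False, float_format=_float_fmt
    )
    result.call_table.to_csv(
        outdir / "differential_calls.tsv", sep="\t", index=False, float_format=_float_fmt
    )
    diffcall.structure_colors(result.calls).to_csv(
        outdir / "structure_colors.tsv", sep="\t", index=False
    )
    qc = {}
    for key, mp in result.profiles.items():
        _, s = prof.coverage_report(mp)
        stats = result.placement.get(key)
        if stats is not None:
            s.update(placed=stats.placed, unplaced=stats.unplaced, ambiguous=stats.ambiguous)
        qc[str(mp.sample)] = s
    counts = result.call_summary
    log.info(
        "differential calls: %d (%d more accessible, %d more protected)",
        counts["total"], counts["more_accessible"], counts["more_protected"],
    )
    return {
        "differential_calls": counts,
        "skipped_positions": result.skipped_positions,
        "coverage_qc": qc,
        "n_call_rows": int(len(result.call_table)),
    }


def _run_dms_synthetic(config: RunConfig, outdir: Path, log) -> dict:
    scn = config.scenario
    log.info(
        "synthetic scenario: %d nt reference, %d up + %d down planted, seed %d",
        scn.ref_length, scn.n_up, scn.n_down, config.seed,
    )
    result = run_scenario(scn, seed=config.seed)
    (outdir / "ground_truth.json").write_text(result.truth.to_json() + "\n")
    summary = _write_dms_outputs(config, result, outdir, log)
    summary["truth_evaluation"] = evaluate_against_truth(result)
    return summary


def _run_dms_files(config: RunConfig, outdir: Path, log) -> dict:
    ref = read_fasta(config.reference_path, numbering_offset=config.numbering_offset)
    sheet = SampleSheet.from_csv(config.sample_sheet_path)
    base = Path(config.sample_sheet_path).parent
    masked = _read_mask(config.mask_path) if config.mask_path else set()
    scale = diffcall.BinScale(boundaries=tuple(config.bin_boundaries))
    index = readsmod.KmerIndex(ref)

    profiles: dict = {}
    placement: dict = {}
    for _, row in sheet.rows.iterrows():
        path = base / row["path"] if (base / row["path"]).exists() else Path(row["path"])
        label = prof.SampleLabel(row["condition"], int(row["replicate"]), row["treatment"])
        log.info("processing %s from %s", label, path)
        if str(path).endswith(".sam"):
            alignments = list(readsmod.read_sam(path, log=log))
            mp = prof.count_mutations(alignments, ref, sample=label)
            stats = readsmod.PlacementStats(placed=len(alignments))
        else:
            batch = sims.read_fastq(path)
            trimmed = readsmod.trim_adaptor_batch(batch, config.adaptor)
            trimmed, _ = readsmod.trim_ends_batch(
                trimmed, qmin=config.qmin, min_length=config.min_read_length
            )
            aln, stats, _ = readsmod.place_reads(trimmed, ref, index=index)
            mp = prof.count_mutations(aln, ref, sample=label)
        if masked:
            mask_idx = np.array(sorted(masked), dtype=int) - 1
            mask_idx = mask_idx[(mask_idx >= 0) & (mask_idx < ref.length)]
            mp.coverage[mask_idx] = 0
            mp.mutations[mask_idx] = 0
        floor = effective_floor(mp, config.coverage_floor, config.min_relative_coverage)
        profiles[(row["condition"], int(row["replicate"]), row["treatment"])] = prof.rate(
            mp, floor
        )
        placement[(row["condition"], int(row["replicate"]), row["treatment"])] = stats

    conditions = list(dict.fromkeys(sheet.rows["condition"]))
    if len(conditions) != 2:
        raise ValueError(f"need exactly 2 conditions, found {conditions}")
    access: dict = {}
    for cond in conditions:
        reps = sorted(
            {r for (c, r, _t) in profiles if c == cond}
        )
        for rep in reps:
            ap = acc.normalize_by_untreated_mean(
                profiles[(cond, rep, "DMS")], profiles[(cond, rep, "mock")], ref,
                condition=cond, replicate=rep,
            )
            access[(cond, rep)] = acc.subtract_background(ap)
    c1, c2 = conditions
    reps1 = sorted(r for (c, r) in access if c == c1)
    reps2 = sorted(r for (c, r) in access if c == c2)
    averages = {
        c1: acc.average_replicates([access[(c1, r)] for r in reps1]),
        c2: acc.average_replicates([access[(c2, r)] for r in reps2]),
    }
    calls, skipped = diffcall.call_changes(
        [access[(c1, r)] for r in reps1],
        [access[(c2, r)] for r in reps2],
        cond1_avg=averages[c1], cond2_avg=averages[c2], scale=scale, ref=ref,
    )
    counts, table = diffcall.summarize(calls)
    result = ScenarioResult(
        ref=ref, truth=sims.GroundTruth([], c1, c2), profiles=profiles,
        accessibility=access, averages=averages, calls=calls,
        skipped_positions=skipped, call_summary=counts, call_table=table,
        placement=placement,
    )
    return _write_dms_outputs(config, result, outdir, log)


def _run_ms(config: RunConfig, outdir: Path, log) -> dict:
    counts = pd.read_csv(config.spectral_counts_path, sep="\t", index_col=0)
    if config.ms_sample_sheet_path:
        sheet = pd.read_csv(config.ms_sample_sheet_path, sep=None, engine="python")
    else:  # infer condition_repN sample names
        sheet = pd.DataFrame(
            {
                "sample": counts.columns,
                "condition": [c.rsplit("_rep", 1)[0] for c in counts.columns],
                "replicate": [int(c.rsplit("_rep", 1)[1]) for c in counts.columns],
            }
        )
    wt_cond, mut_cond = config.conditions
    result = msoccupancy.occupancy_analysis(
        counts, sheet, mutant_condition=mut_cond, wt_condition=wt_cond,
        min_spectra=config.min_spectra,
    )
    result.to_csv(outdir / "occupancy.tsv", sep="\t", float_format=_float_fmt)
    log.info("occupancy computed for %d proteins", len(result))
    return {
        "occupancy": {
            "n_proteins": int(len(result)),
            "n_low_evidence": int(result["low_evidence"].sum()),
            "min_mean_ratio": float(result["mean_ratio"].min()),
            "max_mean_ratio": float(result["mean_ratio"].max()),
        }
    }
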