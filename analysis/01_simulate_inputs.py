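#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the two-condition probing experiment (an rRNA-sized reference with
14 planted accessibility increases and 1 decrease, two replicates of
paired DMS/mock libraries per condition) and the mutant-vs-wt
spectral-count tables (three replicates, three depleted proteins), and
writes them under results/inputs/. The FASTQ libraries written here are
down-sampled (5,000 reads each) so the directory stays small; the
full-depth analysis in 02_differential_accessibility.py regenerates its
libraries in memory at the default depth from the same seeds.
"""

from pathlib import Path

import pandas as pd

import dmsdelta as dd
from dmsdelta import simulate as sims

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scn = dd.ScenarioConfig()
    scn.sim.read_depth = 5_000  # illustration-scale FASTQ on disk

    import numpy as np

    ss = np.random.SeedSequence(SEED)
    n_libs = 2 * scn.sim.n_replicates * 2
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2 + n_libs + 1)]

    ref = dd.make_reference(scn.ref_length, seed=seeds[0])
    dd.write_fasta(ref, OUT / "reference.fasta")
    p1, p2, truth = dd.plant_profile(
        ref, scn.sim, baseline=scn.baseline, n_up=scn.n_up, n_down=scn.n_down,
        seed=seeds[1], conditions=scn.conditions,
    )
    (OUT / "ground_truth.json").write_text(truth.to_json() + "\n")
    print(f"reference: {scn.ref_length} nt, planted {scn.n_up} up + {scn.n_down} down")

    rows, i = [], 2
    for cond, mod in zip(scn.conditions, (p1, p2)):
        for rep in range(1, scn.sim.n_replicates + 1):
            for treatment in ("DMS", "mock"):
                batch = dd.simulate_library(
                    ref, mod, scn.sim, treated=(treatment == "DMS"), seed=seeds[i]
                )
                i += 1
                name = f"{cond}_rep{rep}_{treatment}.fastq"
                sims.write_fastq(batch, OUT / name)
                rows.append(dict(sample=name[:-6], condition=cond, replicate=rep,
                                 treatment=treatment, path=name))
    pd.DataFrame(rows).to_csv(OUT / "samples.tsv", sep="\t", index=False)
    print(f"wrote {len(rows)} libraries of {scn.sim.read_depth} reads each")

    counts, sheet, ms_truth = dd.simulate_occupancy_tables(
        dd.OccupancyScenario(), seed=seeds[-1]
    )
    counts.to_csv(OUT / "spectral_counts.tsv", sep="\t")
    sheet.to_csv(OUT / "ms_samples.tsv", sep="\t", index=False)
    ms_truth.to_csv(OUT / "ms_ground_truth.tsv", sep="\t")
    print(f"wrote spectral counts: {counts.shape[0]} proteins x {counts.shape[1]} samples")
    print(f"outputs under {OUT}")


if __name__ == "__main__":
    main()
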