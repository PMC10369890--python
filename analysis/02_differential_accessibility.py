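#!/usr/bin/env python
"""Differential DMS accessibility between wild-type and mutant particles.

Runs the full probing pipeline at the default depth (250,000 reads per
library, in memory) on the planted scenario: trims adaptors and read ends,
places reads, counts per-position mutation rates, normalizes each A/C rate
by the untreated class mean, subtracts the untreated background, averages
the two replicates, bins the scores, and calls every residue whose bin
changes between conditions. Writes the call table and a summary under
results/dms/ and reports recovery against the planted ground truth.
"""

import json
from pathlib import Path

import dmsdelta as dd
from dmsdelta.diffcall import structure_colors

OUT = Path(__file__).resolve().parent.parent / "results" / "dms"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scn = dd.ScenarioConfig()
    result = dd.run_scenario(scn, seed=SEED)

    result.call_table.to_csv(OUT / "differential_calls.tsv", sep="\t", index=False,
                             float_format="%.6g")
    structure_colors(result.calls).to_csv(OUT / "structure_colors.tsv", sep="\t",
                                          index=False)
    evaluation = dd.evaluate_against_truth(result)
    summary = {"call_summary": result.call_summary, "evaluation": evaluation}
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    c = result.call_summary
    print(f"differential calls: {c['total']} "
          f"({c['more_accessible']} more accessible, {c['more_protected']} more protected)")
    print(f"severity tiers: {c['low']} low / {c['medium']} medium / {c['high']} high")
    print(f"planted-effect recovery: {evaluation['n_recovered']}/{evaluation['n_planted']} "
          f"(sensitivity {evaluation['sensitivity']:.2f}), "
          f"{evaluation['n_false_calls']} false call(s)")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
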