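"""Semi-quantitative spectral-count protein occupancy analysis.

Spectral counts are a proxy for protein abundance in a purified complex.
Each sample's counts are first normalized by the sample's total (removing
differences in overall sample abundance), mutant and wild-type fractions
are then compared per replicate pair, and the per-pair ratios are averaged
— giving each protein's occupancy in mutant relative to wild-type
particles. Proteins supported by few spectra across all samples are
flagged as low-evidence rather than filtered: a depletion measured from a
handful of spectra is unreliable but still worth reporting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .accessibility import DataError

DEFAULT_MIN_SPECTRA = 10


def normalize_total(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample fractional abundances: count / sample total.

    ``table`` is proteins x samples with non-negative integer counts.
    Fractions sum to 1 in every column. A zero-total sample is fatal.
    """
    if (table.values < 0).any():
        raise ValueError("spectral counts must be non-negative")
    totals = table.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DataError(f"sample(s) with zero total spectra: {list(zero.index)}")
    return table / totals


def relative_occupancy(
    mutant_fractions: pd.DataFrame,
    wt_fractions: pd.DataFrame,
    pairing: list[tuple[str, str]] | None = None,
    mode: str = "ratio_then_average",
) -> pd.DataFrame:
    """Mutant/wild-type relative occupancy per protein.

    ``pairing`` lists (mutant_sample, wt_sample) column pairs; by default
    columns are paired by order. The default mode computes the ratio per
    replicate pair and averages the ratios; ``average_then_ratio`` averages
    fractions across replicates first (sensitivity-analysis mode). A zero
    wild-type fraction makes that pair's ratio undefined (NaN); undefined
    pairs are excluded from the mean, not imputed.

    Returns a DataFrame indexed by protein with one ``ratio_rep*`` column
    per pair, the ``mean_ratio``, and ``n_defined_pairs``.
    """
    if set(mutant_fractions.index) != set(wt_fractions.index):
        raise ValueError("mutant and wt tables must cover the same proteins")
    wt_fractions = wt_fractions.loc[mutant_fractions.index]
    if pairing is None:
        if mutant_fractions.shape[1] != wt_fractions.shape[1]:
            raise ValueError(
                "replicate count mismatch: "
                f"{mutant_fractions.shape[1]} mutant vs {wt_fractions.shape[1]} wt samples"
            )
        pairing = list(zip(mutant_fractions.columns, wt_fractions.columns))
    for mcol, wcol in pairing:
        if mcol not in mutant_fractions.columns or wcol not in wt_fractions.columns:
            raise ValueError(f"pairing references unknown sample: {(mcol, wcol)}")

    out = pd.DataFrame(index=mutant_fractions.index)
    ratio_cols = []
    for r, (mcol, wcol) in enumerate(pairing, start=1):
        wt = wt_fractions[wcol]
        ratio = mutant_fractions[mcol] / wt.where(wt > 0)
        col = f"ratio_rep{r}"
        out[col] = ratio
        ratio_cols.append(col)

    if mode == "ratio_then_average":
        out["mean_ratio"] = out[ratio_cols].mean(axis=1, skipna=True)
    elif mode == "average_then_ratio":
        m = mutant_fractions[[p[0] for p in pairing]].mean(axis=1)
        w = wt_fractions[[p[1] for p in pairing]].mean(axis=1)
        out["mean_ratio"] = m / w.where(w > 0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["n_defined_pairs"] = out[ratio_cols].notna().sum(axis=1)
    return out


def flag_low_evidence(
    results: pd.DataFrame,
    counts: pd.DataFrame,
    min_spectra: int = DEFAULT_MIN_SPECTRA,
) -> pd.DataFrame:
    """Flag proteins whose summed spectra across all samples fall below
    ``min_spectra``. Raising the threshold never unflags a protein."""
    total = counts.sum(axis=1).reindex(results.index).fillna(0)
    out = results.copy()
    out["total_spectra"] = total.astype(int)
    out["low_evidence"] = total < min_spectra
    return out


def occupancy_analysis(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    mutant_condition: str = "mutant",
    wt_condition: str = "wt",
    min_spectra: int = DEFAULT_MIN_SPECTRA,
    mode: str = "ratio_then_average",
) -> pd.DataFrame:
    """Full occupancy pipeline: normalize, ratio per paired replicate,
    average, flag. ``sample_sheet`` maps ``sample`` columns of ``counts``
    to ``condition`` and ``replicate``; replicates are paired by number."""
    for col in ("sample", "condition", "replicate"):
        if col not in sample_sheet.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    substructure = None
    if "substructure" in counts.columns:  # head | platform | body annotation
        substructure = counts["substructure"]
        counts = counts.drop(columns=["substructure"])
    fractions = normalize_total(counts)

    def cols_for(cond: str) -> dict[int, str]:
        rows = sample_sheet[sample_sheet["condition"] == cond]
        return dict(zip(rows["replicate"].astype(int), rows["sample"]))

    mut, wt = cols_for(mutant_condition), cols_for(wt_condition)
    if set(mut) != set(wt):
        raise ValueError(
            f"replicates of {mutant_condition} {sorted(mut)} do not pair with "
            f"{wt_condition} {sorted(wt)}"
        )
    pairing = [(mut[r], wt[r]) for r in sorted(mut)]
    result = relative_occupancy(
        fractions[[p[0] for p in pairing]],
        fractions[[p[1] for p in pairing]],
        pairing=pairing,
        mode=mode,
    )
    result = flag_low_evidence(result, counts, min_spectra=min_spectra)
    if substructure is not None:
        result.insert(0, "substructure", substructure)
    return result
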