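# Methods

## The measurement being modeled

DMS (dimethyl sulfate) methylates the Watson–Crick face of accessible
adenines (N1) and cytosines (N3) in RNA; bases that are paired or buried
under protein react poorly. In mutational profiling (MaPseq), a
thermostable reverse transcriptase reads through the methylated base and
leaves a misincorporation in the cDNA, so the per-position **mutational
rate** — mutation events over read coverage — measures the propensity of
each nucleotide to be modified. A mock-treated library measures the
background (RT + sequencing error) that must be scaled out and
subtracted.

The package implements the downstream arithmetic of this assay as a
reusable pipeline, together with a generator that simulates the raw
inputs with known truth, and a parallel spectral-count analysis that
quantifies ribosomal-protein occupancy in purified subunits.

## Simulator

A library is simulated as uniformly placed fragments with lengths uniform
on the size-selection window (default 50–80 nt, the gel cut used in this
kind of library prep), each base mutating independently with probability

    p_eff = p_mod · rt_detect + (1 − p_mod · rt_detect) · err        (treated)
    p_eff = err                                                      (mock)

where `p_mod` is the latent modification probability (zero at G/U and at
protected A/C), `rt_detect` the probability that a modification is read
out as a misincorporation, and `err` the background per-base error. The
3′ adaptor (`GATCGGAAGAGCACACGTCTGAACTCCAGTCA`) is appended error-free;
qualities are constant Q37 so that quality trimming is a no-op unless a
test injects low-quality bases; the true fragment origin is carried in
the read name / batch metadata, giving every downstream stage an
alignment-free oracle.

Modification is a single Bernoulli per position: no RT stops, deletions,
ligation bias, PCR duplicates, or TGIRT-specific error spectra are
modeled — the analysis scores point mutations only, so these would add
realism without exercising any additional code path. Passing tests
therefore show that the arithmetic chain is correct under the stated
error model, not that it is robust to every artifact of real libraries.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| reference length | 1,800 nt | the size of a small-subunit rRNA |
| read depth | 250,000 reads/library | ≈7,600× interior coverage; rRNA probing runs are routinely in the 10³–10⁵× range |
| fragment length | 50–80 nt | the gel size selection |
| `rt_detect` | 0.5 | read-through detection efficiencies of thermostable RTs are well below 1 |
| `err` | 0.01 | background (RT + sequencing) mutation rate of the mock |
| replicates | 2 (probing), 3 (MS) | the experimental designs being emulated |
| coverage floor | 50 absolute, plus ½ × library median | see below |

The statistical resolution of a net-accessibility score is governed by
the product coverage × `err` (the score is a rate *ratio*, so deeper
coverage and stronger background both shrink its sampling error:
sd(net) ≈ √((net + 2) / (N·err))). The defaults give N·err ≈ 76, i.e.
roughly ±0.15 (1 sd) on a replicate-averaged score near zero — enough to
keep the deterministic bin rule stable. Problem sizes in the test suite
(shorter references, shallower depths) are reduced where calling accuracy
is not the property under test.

### Baseline accessibility and planted effects

Baseline A/C reactivity is a three-level mixture: 70% protected
(net ≈ 0), 20% moderately accessible (net ≈ 1.5), 10% highly accessible
(net ≈ 3.0) — a discretized form of the roughly bimodal reactivity
distribution of a folded, protein-covered rRNA, with levels placed in bin
interiors because the bin-change rule is deterministic and has no noise
test. Planted differential positions convert one level to another so the
expected score crosses at least one boundary (protected → 1.5,
moderate → 3.0, or moderate → 0.1 for protections); they are chosen at
least one maximum fragment length from the reference ends, where fragment
placement geometry gives full and even coverage. `p_mod` for a target net
score x is the closed form `err · x / (rt_detect · (1 − err))`.

## Read processing

Adaptor trimming removes the leftmost occurrence of an adaptor prefix
(≥ 10 nt) matching through the read's 3′ end with ≤ 1 mismatch per 10
bases; end trimming removes 5 nt from each end and then low-quality bases
(< Q20) inward; reads shorter than 20 nt are discarded. Placement is
gapless and seeded: an error-free 20-mer (tried at offsets 0/20/40)
anchors the read via a sorted k-mer index, and the placement is accepted
if the mismatch fraction is ≤ 0.2 — deliberately permissive, because
DMS-induced mismatches are the signal. Reads whose anchor occurs at two
or more reference loci are dropped and counted as ambiguous. Pre-aligned
gapless SAM records are accepted as an alternative entry point
(soft-clips excluded, secondary/supplementary/unmapped skipped).

Each per-read operation also exists as a vectorized batch equivalent used
at full depth; batch adaptor trimming locates an exact 16-mer adaptor
prefix (the simulator appends the adaptor without errors), and tests pin
the batch paths to the per-read implementations on simulated data.

## Rates, accessibility, and calling

Rates are defined only where coverage reaches a floor: 50 absolute, and
additionally half the library's median coverage. The relative part
removes the reference edges, whose coverage decays linearly over the last
fragment-length of positions and whose rate estimates would otherwise be
the noisiest scored values in the profile (this mirrors the practice of
masking poorly covered rRNA ends). An optional BED-like mask excludes
naturally modified positions.

For each treated/mock pair, every defined A (resp. C) rate is divided by
the mock's mean rate over defined A (resp. C) positions; the scaled mock
value is subtracted from the scaled treated value to give the **net
accessibility**, and the replicate scores are averaged after subtraction.
Two readings of this procedure were genuinely open and are fixed here:

- the untreated class mean is computed per sample pair, not pooled across
  replicates (keeps replicates independent; a pooled mode exists);
- subtraction precedes replicate averaging.

Net scores are discretized into five half-open bins
[0, 0.5), [0.5, 1), [1, 2), [2, 4), [4, ∞) — lower boundary inclusive, a
convention the printed ranges (which share endpoints) do not decide.
Negative scores clamp to bin 0; protection then appears as the *other*
condition's bin decrease, which is why negative values are retained
rather than clamped to zero earlier. A residue is called differential
when its replicate-averaged bin differs between conditions; the severity
tier (yellow / orange / red) counts how many paired replicates change by
two or more bins (0 / 1 / ≥ 2). Averaged-bin change detection with
per-replicate severity is a deliberate split reading: averaging precedes
binning in the score pipeline, while the tier definitions speak of
per-sample changes. Replicates are paired across conditions by
sample-sheet order; no statistical test is performed — the rule is
deterministic binning by design.

## Spectral-count occupancy

Counts are simulated multinomially per replicate (probabilities
proportional to per-protein abundance; lognormal σ = 0.25 spread around
equal abundance for detectability variation). The analysis normalizes
each sample by its total spectra, forms the mutant/wt fraction ratio per
replicate pair, and averages the ratios (ratio-then-average; an
average-then-ratio mode exists for sensitivity analysis). Zero wild-type
fractions make the pair's ratio undefined and are excluded from the mean,
not imputed. Proteins with fewer than 10 total spectra across samples are
flagged low-evidence rather than filtered.

Total normalization is compositional: if protein p's abundance changes by
factor f_p, the expected measured ratio is f_p / ⟨f⟩ where ⟨f⟩ is the
abundance-weighted mean factor. The default scenario (47 unchanged
proteins, one each at 0.8 / 0.5 / 0.2) keeps this closure constant near
1.03; the ground truth records both the planted factors and the exact
expected compositional ratios, and recovery is assessed against the
latter (plus the raw factors for the depleted proteins).

## Numerical and reproducibility notes

- All coordinates are 1-based inclusive; a `numbering_offset` maps
  internal positions to reported residue numbers when the sequenced
  precursor and the numbering reference differ (the correct offset for
  real data must come from the user).
- Every stochastic stage derives its seed from a single run seed via
  `numpy.random.SeedSequence.spawn`, making full runs byte-reproducible;
  replicate averaging sorts by replicate id first so the mean is
  bit-identical under input permutation.
- N bases carry no evidence: excluded from both coverage and mutation
  counts.
- Batch placement verifies candidates grouped by read length so the
  mismatch arithmetic stays dense; an integer base-4 rolling hash (exact
  in int64) is used for both adaptor search and the k-mer index.

## Known limitations

- Gapless placement only; no paired-end, spliced, or gapped alignment
  (use an external aligner and the SAM entry point instead).
- The bin-change rule has no error control: at shallow coverage it will
  produce noise calls, which is a property of the rule, not of the
  implementation. The default conditions were chosen so that the
  sampling error of a score is small relative to bin width.
- The simulator's mutation model is positionally independent; correlated
  errors (homopolymers, RT fall-off gradients) are out of scope.
- Spectral-count occupancy is semi-quantitative; no peptide-level
  inference, length correction (NSAF/emPAI), or significance testing is
  attempted.
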