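# Methods

## The experiment being modelled

A 247-nt region of the P_BMO promoter (the BmoR-binding region, including a
near-palindromic hairpin and, further downstream, a putative IHF-like
element) is mutagenized by error-prone PCR, cloned upstream of *gfp*, and
transformed into *E. coli*. Induced cells are FACS-sorted into a high-GFP
bin (top 5% of fluorescence) and a low-GFP bin (bottom 10%), and the
amplicon of each bin plus the unsorted library is deep-sequenced. Sequence
positions whose base identity drives expression show up as peaks of mutual
information between base and bin; enrichment maps then say *which* base at
those positions helps or hurts.

## Synthetic-data generator

The generator is a first-class module, not a fixture: it defines the study
conditions every downstream statistic is tested under.

**epPCR model.** The five sequential epPCR rounds of a real library build
are collapsed into one effective per-position Bernoulli substitution
process; only the final library's mutation frequency matters downstream.
Default rate 0.05 per position (the ~5% per-position frequency of a
round-5 library). The mutant base is drawn from a 4×4 row-stochastic bias
matrix (diagonal zero); the default is uniform (1/3 each) and
user-overridable, since mutational bias is polymerase- and
condition-specific. Indels are not simulated: the exact-length filter of
the preprocessing chain would remove them anyway, so substitution-only
generation is self-consistent.

**Planted expression model.** The true sequence–function map of the
promoter is unknown; the simulator plants one calibrated to the validated
variant phenotypes so that parameter recovery is a meaningful test surface:

| feature | positions | effect (natural-log scale) |
|---|---|---|
| essential core | P199–P201 | any non-reference base → expression = basal leak |
| graded deleterious band | P196–P207 except P203 (and the core) | −max(2.0 − 0.25·\|p − 200\|, 0.25) for every non-reference base |
| beneficial single mutant | P205=A | +ln(1.64) |
| epistatic pair | (P129=T, P130=C) | +ln(4) jointly; each single mutant exactly 0 |

Baseline 1000 AU, basal leak 10 AU (a 100-fold dynamic range; the leak is
what a dead promoter still fluoresces). The graded band's decay constant
(0.25 nats/position, floor 0.25) was chosen once so that the weakest band
member is still a ~0.8σ shift against the population's log-expression
spread — detectable but not trivial at realistic read depths.

**Noise and sorting.** Cell-level noise is Gaussian on log expression
(default sd 0.3), i.e. log-normal fluorescence, matching the approximately
log-normal histograms flow cytometers record. Cells are sampled from the
library with replacement proportional to abundance; after noise, the top
`round(n·0.05)` cells form the high pool and the bottom `round(n·0.10)`
the low pool. Note the bin/gate assignment: top 5% = high bin, bottom
10% = low bin.

**Sequencing.** One read per cell, independent uniform substitution errors
(default 10⁻³/base), constant Phred quality (simulated reads carry no
quality information). An optional `n_reads` resamples the pool with
replacement, emulating amplicon sequencing at a depth decoupled from the
sorted cell count.

**The wild-type sequence** bundled as `SYNTHETIC_BMO_AMPLICON` is a
synthetic stand-in: random except at the positions the planted model
references, which carry the documented wild-type identities (P129=C,
P130=A, P199–201=TGT, P205=G, P191–196=GCCGCG).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PCR amplification bias and chimeras, indels,
read-pair merging artifacts, quality-score structure, sorter impurity
(misgated cells), plasmid copy-number variation, and growth/toxicity
selection between sorting and sequencing. Real libraries also have
position-dependent mutation rates; the generator's rate is homogeneous.

## Preprocessing

Merged reads are assumed (read-pair merging is out of scope). The chain:

1. reads with ambiguity codes (N, …) are dropped with a logged count;
2. length filter: only exact-length (247 nt) reads are kept. Reads longer
   than the reference are rejected too — with substitution-only chemistry
   and a fixed amplicon, off-length reads are artifacts, and positional
   identity alignment requires equal lengths;
3. redundant reads are collapsed to unique sequences with multiplicities;
4. Hamming filter: unique sequences more than 20 substitutions from wild
   type are removed (boundary inclusive: distance 20 is kept);
5. per-position A/C/G/T counts. Default weighting counts each unique
   sequence once, matching a deduplicated analysis; multiplicity weighting
   is a flagged option;
6. trim: 20 positions per end are dropped (primer-proximal bases carry
   artificially low mutation frequency), leaving the P21..P227 window.

Alignment is positional identity — no gapped alignment. Every filter
partitions its input exactly (kept + removed = in), filters are
idempotent, and identical inputs yield byte-identical matrices.

## Footprint statistics

Mutual information uses only the two sorted bins; the unsorted library
enters only enrichment and mutation-frequency summaries. Within-bin base
frequencies are `(count + ψ)/(total + 4ψ)`; the joint is
`f(μ)·f(b|μ)`.

Numerical choices:

- **Bin weighting** f(μ) defaults to equal (½, ½); read-proportional
  weighting (by library totals) is an option. Equal weighting makes the MI
  scale independent of how deeply each bin happened to be sequenced.
- **Pseudocount** defaults: ψ = 0 for MI, with 0·log 0 := 0 (an empty cell
  contributes nothing); ψ = 1 for enrichment, so depleted bases keep
  finite log2 ratios. Both are recorded in every result object.
- **No small-sample MI bias correction** is applied. Finite counts inflate
  MI by roughly (|b|−1)(|μ|−1)/(2N ln 2); instead of subtracting an
  analytic term, a permutation-null utility is provided: shuffle reads
  between bins (preserving bin sizes), recompute the footprint, and use
  per-position null quantiles to judge observed values. This calibrates
  dedup effects and sequencing errors too, which the analytic term misses.
- **Ties** in position ranking break by ascending position label, so
  rankings are deterministic.
- **Degenerate inputs**: positions with a single observed base across both
  bins are flagged `no_variation` and report MI = 0 (at ψ = 0) rather than
  being dropped; empty bins reject footprint computation with a
  stage-attributed error, and the pipeline downgrades that to a warning,
  omitting the footprint artifact.

MI for two bins is bounded by 1 bit; the implementation is checked in the
tests against an independent entropy-decomposition oracle
(I = H(b) + H(μ) − H(b, μ)) to 10⁻¹².

## Pipeline and reproducibility

One `PipelineConfig` drives simulate / analyze / end-to-end modes; analyze
mode never invokes the simulator. A single top-level seed is expanded into
per-stage seeds via `numpy.random.SeedSequence`, so an identical config and
seed reproduce byte-identical artifacts; the manifest records SHA-256
checksums of every output and of the serialized config.

## Problem sizes

The packaged study conditions are 10,000 library variants, 100,000 sorted
cells and 50,000 reads per bin — about 1% of the bench-scale experiment
(~2.7 million variants, ~10⁶ sorted cells), chosen as the scale at which
the planted signals are comfortably measurable and the full suite runs on
a laptop. Unit tests use smaller sizes (hundreds to thousands of reads);
the statistical tests state their expected sampling error explicitly
(3 binomial/multinomial standard errors at the stated n).

## Known limitations

- MI values are upward-biased at low coverage; compare against the
  permutation null, not zero.
- The planted model is a stand-in; recovering its sites demonstrates the
  pipeline's statistical machinery, not the biology of any real promoter.
- Strictly epistatic pairs with silent single mutants (the planted
  P129/P130 pair) are near the detection floor at default depths: their
  double mutants occur at ~(rate/3)² ≈ 2.8·10⁻⁴ per variant, so their MI
  can fall below the permutation null in some realizations. This mirrors
  the real difficulty of seeing epistasis in single-base footprints.
- No quality-based filtering, no gapped alignment, no demultiplexing; the
  pipeline consumes merged, single-amplicon reads only.
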