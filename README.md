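# sortseq-footprint

Analysis pipeline for **sort-seq** experiments on mutagenized bacterial
promoters, built around the σ54-dependent, butanol-responsive BmoR–P_BMO
biosensor system: an error-prone-PCR library of a 247-nt promoter region
drives GFP, cells are FACS-sorted into a high-GFP bin (top 5%) and a
low-GFP bin (bottom 10%), and each bin is deep-sequenced. The package turns
the per-bin amplicon reads into **mutual-information footprints** and
**enrichment heat maps** that localize the positions and base identities
governing expression — and it ships a synthetic-data generator that
emulates the entire experiment, so every stage is testable without any
sequencing download.

Intended users: synthetic biologists and regulatory-genomics analysts who
run massively parallel reporter assays (sort-seq / MPRA) and want a tested,
reproducible footprint pipeline, or who want to simulate a sorting
experiment before running one.

## The statistic

For position *i*, let *b_i* be the base observed in a read and *μ* ∈
{low, high} the bin the read came from. With joint frequency *f(b_i, μ)*
and marginals *f(b_i)*, *f(μ)*, the per-position mutual information

```
I(b_i; μ) = Σ_{b_i, μ} f(b_i, μ) · log2 [ f(b_i, μ) / ( f(b_i) · f(μ) ) ]
```

is measured in bits (at most 1 bit for two bins). Positions whose identity
does not affect expression give I ≈ 0; positions under selection peak.
Enrichment maps complement the footprint with the per-base, per-position
log2 ratio of a sorted bin's base frequency to the unsorted library's.

Preprocessing follows the standard chain for merged amplicon reads:
exact-length filter (247 nt) → deduplication → Hamming-distance filter
(> 20 mismatches to wild type removed) → per-position base counts →
trimming 20 primer-proximal positions per end (analysis window P21..P227,
207 positions).

## Worked example

`examples/footprint_analysis.py` simulates the default planted experiment
(10,000 variants at 5% per-position mutation rate, 100,000 sorted cells,
50,000 reads per bin) and maps the footprint:

```
top-10 MI positions (bits):
  P201: 0.2020
  P199: 0.1828
  P200: 0.1819
  P205: 0.0320
  P202: 0.0211
  P198: 0.0200
  P196: 0.0190
  P197: 0.0178
  P204: 0.0164
  P206: 0.0147
most enriched identity in the high bin: P205A (log2 ratio +2.39)
```

The essential core P199–P201 — where any substitution abolishes promoter
function — dominates the footprint; the flanking deleterious band
(P196–P207) follows; and the one beneficial single mutation planted by the
model, G(205)A, is the most enriched identity among high-GFP cells. That is
exactly the read-out a sort-seq screen uses to nominate engineering
targets.

Other examples: `examples/simulate_library.py` (library calibration and
substitution spectrum), `examples/score_variants.py` (the planted
sequence→expression map, including the strictly epistatic 4-fold
CA(129,130)TC double mutant), `examples/run_pipeline.py` (file-based run
with manifest).

The same pipeline runs from the shell:

```bash
sortseq-footprint run --seed 11 --outdir run1
sortseq-footprint footprint --outdir fp --unsorted-fastq u.fastq \
    --low-fastq low.fastq --high-fastq high.fastq
```

Outputs are plain TSV (count matrices, footprint, enrichment long tables,
filter report), FASTQ/FASTA, and a JSON manifest with SHA-256 checksums;
identical config + seed reproduces identical checksums.

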