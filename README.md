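# exposeq

Simulation and analysis toolkit for sequencing-based profiling of RNA
accessibility in partially disassembled viral particles.

The package covers the full computational loop:

1. **`exposeq.barrier` / `exposeq.simulate`** — a generative model of a
   particle library: per-region logistic temperature responses yield
   per-position accessibility; random-hexamer priming anchors are drawn in
   proportion to the mean accessibility of the 6-nt annealing window; cDNA
   lengths follow a truncated geometric law set by the terminator:extender
   ratio (default 1:6 termination per nucleotide); molecules carry 12-nt
   UMIs, optional crosslink-induced U→C conversions (CL+ libraries only),
   PCR duplication and sequencing error. Output is a paired FASTQ library
   (R1 = UMI + sense insert, R2 = 7-nt hexamer/buffer prefix + antisense
   insert) plus truth tables and a manifest.
2. **`exposeq.fastqio` / `exposeq.align` / `exposeq.pileup` /
   `exposeq.samio` / `exposeq.processing`** — native read processing for a
   small (≤ a few kb) reference: UMI extraction and prefix trimming, exact
   k-mer-seeded ungapped alignment with an exhaustive-scan guarantee of
   mismatch-count optimality, UMI deduplication keyed on the R2-derived
   priming anchor, and molecule-level pileups (mates merged, overlap
   counted once). SAM import/export is provided for interoperability with
   external aligners.
3. **`exposeq.exposure`** — ratiometric per-segment coverage and
   priming-site profiles, window statistics (% of segment length vs % of
   total signal), centered moving averages with shrinking edges,
   temperature-series trend classification (increasing / decreasing /
   flat_low / fluctuating) and region fold changes; bedGraph/TSV export.
4. **`exposeq.crosslink`** — per-U transition rates from deduplicated
   pileups with depth masking (default threshold 1000), CL+/CL− fold-change
   signal with a 1/min_depth pseudocount, two-sample Kolmogorov–Smirnov
   condition tests, Pearson/Spearman track correlations and signal
   thresholding with achieved quantiles.
5. **`exposeq.pipeline` / `exposeq.cli`** — config-driven orchestration of
   simulate → process → analyze → integrate, including the smoothed
   priming-vs-signal Spearman anti-correlation readout, with deterministic
   seeding and per-stage counters.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite (worked region
percentages, normalization conservation, uniform-exposure null,
exposure/trend recovery, brute-force oracle equivalences, crosslink-signal
recovery and null behavior, fragment-length law, and the directional
priming-vs-signal property). Brute-force oracles live in
`tests/oracles.py` and share no code with the package.

## CLI

```bash
exposeq all -c examples/demo.yaml -o out/           # full pipeline
exposeq simulate -c examples/demo.yaml -o out/sim   # one library
exposeq process --r1 R1.fastq.gz --r2 R2.fastq.gz --reference ref.fasta -o out/proc
exposeq exposure --pileup out/proc/pileup.tsv --region RNA1:151-250 -o out/exp
exposeq vparcl --plus plus_pileup.tsv --minus minus_pileup.tsv \
        --reference ref.fasta -o out/xl
```

A run is reproducible from its config alone: identical config + seed gives
byte-identical outputs.

## Conventions

- Coordinates are 1-based inclusive throughout; bedGraph output is 0-based
  half-open.
- The reference alphabet is DNA (U stored as T); "U→C" statistics are
  computed at reference-T positions from sense-oriented base counts.
- The priming anchor *p* is the position immediately 5′ of the hexamer
  annealing window [p+1, p+6]; after trimming the 7-nt R2 prefix the R2
  5′-most aligned coordinate equals *p* exactly.
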