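# Methods

## The screen being modeled

A pooled shRNA survival screen splits a genome-wide knockdown library into
pools of barcoded hairpins (here, by default, the structure of a 18,205-gene
library with 10 pools of 9,570 constructs and 4–7 hairpins per gene, no two in
the same pool). Cells are transduced at MOI 0.3 so most carry a single
integration, kept at ≥1,000 cells per hairpin, and split into an untreated
reference arm and a treated arm (3 specimens each per pool). Sequencing the
integrated barcodes gives counts whose treated/reference ratio reflects how
much each knockdown protects from (enrichment) or sensitizes to (depletion)
the selective pressure. A parallel counter-screen with a generic lethal agent
identifies genes whose loss blocks cell death nonspecifically; its hits are
subtracted.

## Generative model (synthetic_data)

The simulator is the package's test bed and defines the conditions under
which everything downstream is validated.

- **Library**: per-gene construct counts are drawn uniformly from
  [min, max] and repaired by ±1 adjustments on randomly chosen genes until
  the requested total is met (the published totals constrain only the range
  and the per-pool sizes, not the per-gene distribution — the repair scheme is
  this package's construction). Pool assignment fills the currently
  least-loaded pools first, excluding pools the gene already uses; this keeps
  pool sizes within one of each other, hence exactly equal whenever the total
  divides by the pool count. Barcodes (default 22 nt) are uniform random with
  pairwise Hamming distance ≥ 3 enforced by rejection (chunk-hashing makes the
  check linear-time at full library scale), so single-mismatch assignment is
  unambiguous by construction.
- **Counts**: each pool draws a log-normal baseline abundance per hairpin
  (σ = 0.5 by default — a typical representation skew for pooled libraries;
  the screen protocols do not publish one). The treated arm reweights the
  baseline by 2^effect per hairpin (effect on the log2 scale, 0 neutral).
  Replicate counts are negative binomial with mean = depth × relative
  abundance and variance μ + φμ² (φ = 0.1 default; φ = 0 recovers Poisson).
  Effects renormalize the within-pool composition, so large planted effects
  on many hairpins depress the apparent abundance of neutral ones — real
  compositional behavior that matters when planting dense effects.
- **Reads**: one read per counted molecule; the barcode sits at a fixed
  offset of 18 nt (after a constant mir-30-style 5′ flank) inside a 75 nt
  read (the screen's minimum single-read length). The spike-in stand-in for
  the run's 10% unassignable fraction adds ⌈f/(1−f) × assigned⌉ random-
  sequence reads whose barcode window is verified to be ≥ 2 mismatches from
  every library barcode; only their unassignability matters downstream, so no
  actual phiX sequence is used. Per-base substitution noise is available but
  defaults to 0: the default models the spike-in as the sole source of
  unassignable reads, and substitution robustness is exercised explicitly via
  the mismatch-tolerance tests rather than folded into every simulation.
- **Reproducibility**: every sample's draws come from a generator seeded by a
  (seed, pool, arm, replicate) tuple, so outputs are bit-identical per
  (config, seed) and independent of evaluation order.
- **Default depth** is 100,000 reads per sample — a desk-scale default sized
  for simulated pools of a few hundred to a few thousand constructs; a real
  9,570-hairpin pool at 1,000× would need ~10⁷ reads and is supported but not
  the default.

What the simulator does *not* emulate: PCR amplification bias, apoptotic-cell
removal, integration-site effects, index hopping, or quality-score structure
(qualities are constant). Passing tests therefore demonstrate correctness of
the statistics and bookkeeping under the stated NB model, not robustness to
those artifacts.

## Quantification

Reads are assigned by Hamming matching of the fixed-offset barcode window
against the pool's barcode set: exact lookup first, then (optionally) a
precomputed 1-mismatch neighborhood table. A read is assigned iff exactly one
construct matches within tolerance; ambiguous and unmatched reads, and reads
shorter than offset + barcode length, count as unassigned. Single-mismatch
mode refuses to run unless the pool's barcodes keep pairwise distance ≥ 3,
which makes 1-neighborhoods disjoint and assignment exact. The conservation
identity assigned + unassigned = total is validated on every matrix
construction. An offset-scan mode (try all offsets, require a unique hit
across offsets) is available for reads with unknown barcode position.
Full-read alignment against construct references is deliberately not used:
with a known barcode set at a known offset, direct matching is deterministic
and exactly testable.

## Differential representation

- **CPM** is count / column-sum × 10⁶ (zero-sum columns are an error naming
  the sample).
- **Size adjustment for testing**: counts are scaled to the geometric-mean
  library size and rounded; this keeps the conditional test on an integer
  lattice without a full quantile-adjustment scheme.
- **Dispersion**: per-hairpin method of moments on the size-normalized
  counts, (s² − m̄)/m̄², pooled across arms with (n−1) weights; the common
  dispersion is the mean over hairpins (clipped at 0). Per-hairpin values are
  shrunk toward the common value with weight prior_df/(prior_df + residual
  df) and floored at 10⁻⁸. The default prior_df = 40: with 3+3 replicates
  there are only 4 residual df, the tagwise moments estimate is mostly noise,
  and — because the estimate correlates with the test statistic — weak
  shrinkage makes far-tail p-values anticonservative. Null-simulation
  diagnostics (600–2,000 hairpins, φ = 0.1) show that at prior_df ≈ 25–50 the
  per-family probability of any BH discovery matches the nominal 0.05 and the
  raw rejection rate sits at ~0.051; prior_df = 40 is adopted as the default.
  With a single replicate per arm the estimator falls back to a documented
  default (0.1) with a warning.
- **Exact NB conditional test**: arm totals Y_trt, Y_ref are NB(nμ, φ/n);
  conditioning on T = Y_trt + Y_ref, the two-sided p-value is the summed
  conditional probability of all splits whose probability is ≤ that of the
  observed split (ties within 10⁻¹⁰ in log space count as equal, so the
  modal/symmetric outcome gives p = 1, and identical arms give p = 1
  exactly). All-zero hairpins are flagged and reported with p = 1,
  log2FC = 0.
- **log2FC** is log2((CPM̄_trt + 0.5)/(CPM̄_ref + 0.5)); the 0.5 CPM
  pseudocount bounds fold changes for zero counts.
- **FDR**: Benjamini–Hochberg within each pool — each pool is its own
  experimental unit with its own specimens and dispersion, so each gets its
  own multiple-testing family.

## Hit calling

A gene is a hit iff all of: (1) ≥ min_enriched (default 2) hairpins with
FDR < 0.05 and log2FC > 0; (2) those enriched hairpins occupy ≥ min_enriched
distinct pools (automatic for libraries that never place a gene twice in one
pool, but enforced regardless); (3) at least one enriched hairpin with
log2FC ≥ 1, i.e. more than two-fold (log base 2, threshold applied as ≥);
(4) no hairpin of the gene with FDR < 0.05 and log2FC < 0, with no magnitude
requirement on the depletion side. Every violated rule is recorded in
`failure_reasons`; genes with fewer than min_enriched constructs are reported
as `insufficient_constructs`. Counter-screen subtraction is a set difference
on gene-level hit lists, serialized sorted.

One subtlety: relaxing the FDR threshold is monotone (never loses a hit) only
with the depletion exclusion disabled — a looser FDR also flags more
depleted hairpins, which can disqualify a gene. The monotonicity property is
therefore stated (and tested) for the enrichment-side rules.

## Over-representation

Exact hypergeometric upper tail P(X ≥ k) per term after intersecting members
with the universe (default: all genes in the library design — the screen's
tested gene space); k = 0 gives p = 1. BH across all supplied terms,
significant at FDR < 0.1. An EASE-style conservative variant (scoring k − 1
overlapping genes) is available behind a flag for comparability with
DAVID-like tools; no hierarchy-aware correction is attempted, since the
module takes flat GMT gene sets rather than an ontology graph.

## Pipeline

`run_pipeline` wires the stages from one YAML config (library manifest or
design block; simulated or FASTQ-backed screens; optional counter-screen;
hit criteria; optional GMT). Result tables are written with fixed column
order and `%.10g` floats, so identical config + seed reproduces them byte for
byte; the counter-screen simulation derives its seed as seed + 1,000,003 so
the two screens are independent but jointly reproducible. Stage failures
propagate with the stage name and leave an `INCOMPLETE` marker in the output
directory. Sample sheets must provide both arms for every pool; validation
errors name the offending pool.

## Numerical and testing notes

- The exact test enumerates the full split lattice 0..T per hairpin
  (vectorized log-pmf); at the test suite's depths T stays ≤ ~3×10⁴ and the
  enumeration is microseconds per hairpin.
- Monte-Carlo oracles: the conditional law of the test is cross-checked by
  rejection sampling (draw arm totals, keep exact-total matches). A
  resampling oracle with B kept draws cannot resolve probabilities below
  ~1/B, so comparisons use agreement within 10% or within Monte-Carlo
  resolution, with an extreme-split case (both sides below resolution) and a
  moderate-split case (informative 10% comparison).
- Simulation sizes in the suite (600–2,000 hairpins for calibration, 120-gene
  5-pool screens for recovery, 8 seeds for specificity) are chosen as the
  smallest sizes at which the binomial/Monte-Carlo error of each checked
  quantity is well inside its assertion band.
- Planted-hit recovery is validated at 5,000 reads per hairpin (5× the
  screen's 1,000× coverage floor) with all-member effects of +2 log2; at
  those conditions recovery is complete and no neutral gene is called in any
  tested seed.

## Known limitations

- The NB test assumes a common dispersion scale across arms and conditions on
  rounded size-adjusted totals; at very unequal library sizes the rounding
  introduces sub-count distortions.
- The moments dispersion estimator is consistent but inefficient; with many
  pools of real data an empirical-Bayes likelihood estimator would be
  preferable.
- Barcode matching trusts the fixed offset (or the offset scan); indels in
  reads are not modeled or tolerated.
- Gene-set results inherit whatever redundancy the supplied GMT carries; BH
  across overlapping terms is valid but conservative in aggregate.
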