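# Methods

This note records the statistical model behind `stat5kit`, the meaning and
default of every parameter, what the synthetic generator does and does not
emulate, and the numerical choices. It makes no empirical claims beyond
what the test suite computes.

## Coordinates and data model

Internally every interval is 0-based half-open `[start, end)`; everything
user-facing — including the packaged site tables — is 1-based inclusive.
`GenomicInterval.from_one_based`/`to_one_based` convert. Sequencing reads
are reduced to strand-less *tags* at the read's floor midpoint; all
counting is by tag midpoint within a half-open window.

The packaged fixture (`stat5kit/data/`) transcribes 36 binding-site rows
over 27 candidate genes: sequence, printed span, and one peak q-score per
ChIP experiment, with "–" parsed as *censored* (no accepted peak), never
as zero. Some printed rows have a sequence length that disagrees with the
printed span; `length_consistency_report` flags them and nothing corrects
them.

## Peak calling

**Density.** Tags are binned at `step = 10` bp and convolved with a
Gaussian kernel of SD `bandwidth = 30` bp (`truncate = 6`, zero-padded
edges), giving a density in tags/bp that integrates to the tag count and
is linear in the tags. 30 bp matches the scale of a focal binding
footprint after fragment-position smearing; 10 bp keeps summit resolution
well under the 100-bp pairing tolerance at 1/3 the kernel SD.

**Candidates.** Local maxima above `min_density_fold = 5` × the
genome-wide mean density become candidate summits (maxima closer than one
bandwidth merge). Each interval grows outward until the density drops
below `boundary_fraction = 0.1` of the summit value, truncated at the
midpoint between adjacent summits. This pre-filter is deliberately loose;
the acceptance filters below do the real work.

**Acceptance filters — all strict inequalities.** A candidate is accepted
only when

* `fold_input > 3`: depth-normalised window tag fraction in the ChIP
  sample over the same fraction in the input control, with a pseudocount
  of 0.5 tags on the input count to stabilise near-empty windows;
* `fold_uniform > 30`: observed window count over the uniform expectation
  `chip_total · window_length / genome_length`;
* `q_score > 10`: −log10 of the Benjamini–Hochberg q-value of the
  upper-tail Poisson probability of the observed count at the uniform
  expectation, the BH family being all candidates of that experiment.

"More than" is taken literally: a candidate sitting exactly on any
threshold is rejected, and the tests pin this.

**Log-space significance.** Realistic peak q-scores reach the hundreds,
i.e. q-values far below the double-precision underflow limit (~1e-308).
`poisson_log10_sf` therefore uses SciPy's log-survival function where it
is finite and otherwise sums the tail in log space from log-pmf terms
(the terms decay geometrically by `mu/(j+1)`, so 400 terms are exact to
machine precision in the regime where SciPy underflows). Benjamini–
Hochberg runs directly on log10 p (`bh_log10_qvalues`: order statistics
plus `log10(m/rank)`, reversed cumulative minimum, capped at 0); it
matches `statsmodels` `fdr_bh` wherever the linear scale does not
underflow, which the tests verify. Linear-scale `p_value`/`q_value`
properties exist for display and may underflow to 0; `log10_p`/`log10_q`
are the authoritative values.

## Comparative classification

Peaks from the two experiments are paired greedily by increasing summit
distance, same chromosome, up to `max_summit_distance = 100` bp, each
peak used at most once; leftovers are one-sided sites. Per site:

* one-sided detection → **specific** for the detected factor (censoring,
  not a ratio of infinity — though a measured zero against a positive
  score is treated as infinite ratio and hence dominant);
* both detected → **dominant** for the higher-scoring factor iff
  `max(q)/min(q) > rho` with `rho = 2`, *strictly*; a ratio of exactly 2,
  or identical scores, is **equal**.

Per gene: all sites equal → equal; all sites favouring one factor → that
factor's specific (every site one-sided) or dominant (any site
two-sided); any mixture of directions, or equal mixed with one-sided, is
flagged `ambiguous` and labelled by the site with the highest q-score.
On the packaged fixture this reproduces every printed gene label with no
ambiguous flags: 9 equal, 10 specific (4 A + 6 B), 8 dominant (4 + 4).

## Annotation and motifs

A gene is assigned to a site when the edge-to-edge distance between the
intervals is ≤ `window = 10,000` bp (overlap counts as 0); the anchor is
the nearest gene edge, not the TSS, and one site may collect several
genes. Sequences are scanned on both strands against IUPAC consensus
patterns (default `TTCNNNGAA`); a sequence with no full match but
containing `TTC` or `GAA` is *core_only*, otherwise *none*. Because
revcomp(TTC) = GAA, the either-strand core check reduces to a
forward-strand check; the scanner is property-tested for strand symmetry
and against a plain-regex oracle.

## Knockdown validation

Per donor and condition, ΔCq = Cq(target) − Cq(reference); ΔΔCq =
ΔCq(knockdown) − ΔCq(control); relative expression = 2^(−ΔΔCq), so the
control is 1 by construction and the result is invariant to any constant
added to all of a donor's Cq values. The two-sided paired t-test runs on
per-donor ΔCq differences rather than on the exponentiated ratios —
Cq-scale differences are closer to normal. Zero-variance differences make
the t statistic undefined and are reported as the appropriate limit (p=1
for identical values, p=0 for a constant shift) with a `degenerate` flag.
A gene is called **A-specific**/**B-specific** when p < `alpha_specific =
0.01` under exactly that factor's knockdown, **redundant** under both,
**none** under neither; `alpha = 0.05` is reported but never used for
classing, and no multiple-testing correction is applied across genes,
matching per-gene reporting practice. The crosscheck maps ChIP classes to
expected knockdown classes (equal → redundant, A-specific/dominant →
A-specific, likewise B) and lists discordant genes explicitly — binding
without a transcriptional consequence is a legitimate outcome, never
suppressed.

## Synthetic generator

The generator exists to make the analysis testable against ground truth,
not to mimic a sequencer.

* **Genome**: i.i.d. bases at `gc = 0.41` on a single chromosome
  (default 2 Mb — large enough for ~20 well-separated sites, small enough
  for sub-second runs).
* **Sites**: concrete `TTC NNN GAA` 9-mers written into the sequence at
  cell-centred anchors with bounded jitter, guaranteeing a minimum gap
  (`min_gap = 5,000` bp, floor 2,000) and 20-kb edge margins; class order
  is shuffled so position never encodes class.
* **Strengths**: the stronger factor's expected yield is `lambda_major =
  1000` tags. Equal sites draw a λ ratio in [1, 1.5]; dominant sites in
  [4, 5]; specific sites set the minor factor's λ to 0 — all regimes
  placed safely on their side of the classifier's strict 2-fold boundary
  so truth recovery is well-posed. `lambda_major = 1000` was derived
  before any recovery measurement: with the default 0.005 tags/bp
  background on 2 Mb and ~350-bp accepted windows, the weakest dominant
  minor (λ = 1000/5 = 200) sits near 40-fold over uniform, safely above
  the strict 30-fold filter, whereas a ×10 smaller scale would push
  dominant minors to ~13-fold and misread dominant sites as specific.
* **Tags**: per site, Poisson(`depth_scale`·λ) tags at
  Normal(midpoint, `frag_sigma = 75` bp) positions (fragment-position
  smear), plus uniform Poisson background at `background_rate = 0.005`
  tags/bp; the input control is background only.
* **Genes**: placed at controlled edge distances (near ≤ window, far >
  window, paired-near flanking one site on both sides).
* **qPCR**: knockdown shifts the target Cq by −log2(1−effect); donors get
  random intercepts (SD 0.5 cycles) shared across their conditions so the
  paired design retains power; every Cq read adds N(0, `sd_noise = 0.15`)
  cycles; defaults `n_donors = 6`, effects 0.45/0.58 (a realistic siRNA
  efficiency regime).

Deliberately **not** emulated: read alignment and mappability, GC or
fragment-length bias, duplicate reads, diploid copy number, chromatin
accessibility of the input, amplification-efficiency curves in qPCR.
Genome-scale peak inventories therefore cannot be reproduced here; the
generator supports property checks (recovery, calibration, determinism),
not effect-size realism.

## Calibration properties the tests enforce

Over 100 seeded experiments: ≥ 90% of planted major sites recovered with
summit within 100 bp, and ≥ 90% of recovered sites classified to their
true regime. Under the null, the knockdown type-I rate over 2,000 tests
stays within exact binomial 99% bounds of α = 0.01; at effect 0.5,
`sd_noise` 0.15 and 6 donors, ≥ 90% of B-specific genes are called
B-specific. Pipelines rerun with the same config and seed produce
byte-identical outputs (fixed float formats, sorted iteration, no
timestamps in the manifest).

## Limitations

* The KDE caller misses maximal plateaus at the extreme chromosome edge
  (interior sites only — the only case the generator produces).
* The comparative step inherits the censoring of the peak caller: a site
  just below acceptance in one factor looks specific rather than
  dominant; this is a property of the published decision rule, not a bug.
* The gene aggregation rule labels ambiguous mixtures by the strongest
  site — a tie-break that never fires on the packaged fixture but is a
  modelling choice for de-novo data.
* No across-gene multiplicity control in the qPCR validation; with many
  genes, expect a 1% false-specific rate per factor by construction.
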