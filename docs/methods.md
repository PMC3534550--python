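# Methods

## Scope and data model

The package analyzes per-probe allele-intensity tables from SNP arrays of
a staged mouse breast-cancer model: two normal samples define the
reference; transgenic hyperplasia, tumor and tumor-derived cell-line
samples are compared against it. Probes live on a genome map (ordered
chromosomes, strictly increasing positions); all downstream structures —
CNA tracks, segments, breakpoints, ISRs — are defined per chromosome.
Coordinates are 0-based half-open internally and in BED output, 1-based
inclusive in SEG output.

## CNA calling

Both allele channels are summed per probe (the analysis uses totals only;
no allele-specific copy number). The reference is the arithmetic mean of
the designated normal samples' totals on the raw intensity scale. The CNA
measure is `log2((T+ε)/(R+ε))` with pseudocount ε = 1 intensity unit —
negligible against typical signals (~10³) but it keeps dead probes finite.
A sample referenced against itself gives exactly zero everywhere.

Five-bin classification: *unchanged* is the closed interval [−0.2, 0.2]
(fold change 0.87–1.15), the *highly* bins are closed outward at ±0.6,
and the *slight* bins are the open remainders. Probes with NaN ratios are
excluded from the fraction denominator and reported as an excluded tally.
No GC/wave correction is applied.

## Segmentation (CBS)

For a chromosome's ordered values, every circular arc `[i, j)` whose arc
and complement both contain ≥ `min_width` (default 2) probes is scored
with the pooled-variance two-sample t-statistic; the maximal |t| arc is
the candidate change. Ties (complementary arcs score identically) break
to the smallest `i`, then smallest `j`, detected with a 1e−10 relative
tolerance so floating-point noise cannot flip the representative.

*Why pooled rather than Welch variance:* with per-group variances a 2–3
probe arc of nearly equal values has an effectively unbounded t, in the
observed data and in every permutation alike; the permutation null is
then dominated by micro-arc artifacts and genuine change points are
swamped. The pooled statistic ties the denominator to the whole
chromosome's within-group scatter and does not have this failure mode.

Significance is a within-chromosome permutation test with the add-one
estimator `p = (1 + #{T* ≥ T_obs}) / (1 + n_done)`; default
`n_permutations = 10000` at `α = 0.001`. Permutations run in geometric
batches (16, 64, 256, 1024…) and stop early only once enough exceedances
have accrued that `p > α` is guaranteed; confirming a rejection always
runs the full loop, so accepted splits use the full permutation
resolution. Per-chromosome generator seeds derive from
(seed, sample id, chromosome) via CRC32, making reruns bit-identical and
order-independent.

A significant arc splits the run into up to three sub-runs, each entered
into recursion independently; runs shorter than `2·min_width` are left
alone. After recursion, the sd-undo rule repeatedly merges the adjacent
pair with the smallest |Δmean| while that difference is below
`undo_sd · σ̂` (default 0.5), recomputing means after each merge. The
noise scale σ̂ is the MAD of first differences divided by 1.4826·√2 —
first-differencing removes the piecewise-constant signal except at the
few breakpoints, which the median ignores; `undo_sd = 0` disables
merging. Segments always partition the chromosome's probes.

## Breakpoints, ISRs

Each adjacent-segment junction yields one breakpoint (count per
chromosome = segments − 1). The ISR is the open genomic interval between
the last probe of the left segment and the first probe of the right one;
its |Δ segment mean| filter is inclusive at the 0.8 default. Cross-sample
breakpoint overlap matches midpoints on the same chromosome within a bp
tolerance, greedily nearest-first and one-to-one; the tolerance is an
explicit parameter (default 0) because any physically meaningful window
depends on the local probe spacing (ISRs here average a few kb).

## Expression concordance

The top-n (default 500) genes by FDR-adjusted p-value (ties: |logFC|
descending, then gene id) are labeled up/down by the sign of logFC. SNP
level: every probe inside a selected gene's interval (introns and UTRs
included) contributes one count to that gene's direction row, classed as
amplification (> 0.2), deletion (< −0.2) or no variation; a probe inside
k overlapping genes counts k times. Segment level: every (segment, gene)
pair with a nonempty interval intersection contributes one count, classed
by the segment mean. The concordance percent is
`100·(up∩amp + down∩del) / grand total`, reported to one decimal. DE
model fitting is out of scope — the module consumes a precomputed table,
real or simulated.

## ZOOPS motif discovery

Model: a sequence carries, with probability γ, exactly one motif
instance at a uniformly random admissible site on either strand (the
reverse-complement scan contributes the extra sites), drawn column-wise
from a 4×w PWM; otherwise it is 0-order background (estimated from the
input with add-one smoothing). EM alternates posterior site occupancies
with PWM/γ re-estimation. The M-step adds a 0.01 pseudocount per PWM
cell, and γ carries a weak Beta(1, 1 + n/2) prior (n = number of
sequences):
with no real motif the likelihood is flat in γ (a PWM equal to the
background fits any occupancy equally well) and the prior pulls γ to
zero along that ridge, while with genuine sites the data term dominates
(50 planted sequences still fit γ ≈ 0.6 and per-site posteriors ≈ 1).
The monitored objective is therefore the MAP-penalized log-likelihood —
data likelihood plus the Dirichlet and Beta terms — which is
non-decreasing by the EM guarantee and asserted at every iteration; the
raw likelihood alone is not monotone under smoothed M-steps.

Restarts are seeded from the most recurrent exact w-mers (default 10)
plus random windows (default 5), consensus weighted 0.7; the best final
objective wins. Recurrence-based seeding was chosen over
background-surprise scoring because repeated occurrence across sequences
is exactly the ZOOPS signal, whereas surprise seeding locks onto
low-complexity composition. Width selection, when requested, scans 15–40
bp and picks the best `LL − 0.5·3w·log(total sites)` (three free
parameters per column); no E-value machinery is implemented.

Hits are sites with posterior > 0.5, reported with forward-strand
offsets and log-odds scores in bits. Motifs serialize to MEME minimal
format (with a round-trip parser for verification).

## Tandem repeats

Maximal runs of a primitive unit (1–6 bp) are reported when they contain
≥ 2 whole copies and ≥ `min_total` bp of whole copies; a trailing partial
copy is flagged but not counted in the length (so `length = unit ×
copies` always). Units are canonicalized to the lexicographically
smallest rotation. Runs are maximal — extending either end breaks the
period — and non-ACGT characters break runs. The scanner advances one
position after each hit because a phase-shifted run with a different
unit can begin inside a reported one.

## Synthetic data generator

The generator emulates the staged study design, not array chemistry:

* **Profiles.** Alteration segments with geometric probe-length
  (mean 20 probes) and states from {0, 1, 3, 4, 6} are placed uniformly
  (no overlap) on a diploid baseline until the stage's altered-bp target
  is reached — 0% normal, 22% transgenic, 40% tumor, 46% cell line —
  with boundaries snapped to inter-probe midpoints. The final segment is
  truncated at the probe where the target is met; without this the
  overshoot of up to one whole segment exceeds the ±0.05 tolerance on
  desk-scale maps and can even reorder the stage fractions.
* **Intensities.** Expected total = baseline · c_eff/2 with
  c_eff = f·c + (1−f)·2 (tumor-cell fraction f), times 2^ε,
  ε ~ Normal(0, sd): the noise sd is stated directly on the log2 scale so
  segment means converge to log2(c/2) with the usual √n rate. Totals
  split into A/B channels through a simulated AA/AB/BB genotype at a
  configurable allele frequency; the pipeline consumes totals only.
  Default sd = 0.15, chosen (from the plausible 0.15–0.25 band) because
  it reproduces the ~95%-unchanged normals that characterize the study's
  reference samples; it is a free parameter, not a measured value.
* **Expression.** Gene logFC = κ·log2(c_eff/2) at the gene midpoint plus
  Normal noise; adjusted p-values come from a z-test against the noise sd
  with Benjamini–Hochberg correction. κ = 0 decouples expression from CN.
* **ISR sequences.** i.i.d. background with a motif (PWM or
  consensus/repeat-unit string) planted in ⌊occupancy·n⌋ sequences, one
  instance each, forward strand, positions recorded.

Not emulated: probe-level hybridization chemistry, GC bias, genotype
calling, spatial artifacts, replicate structure. Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated
noise model, not robustness to real-array systematics.

## Calibration and recovery studies

Problem sizes are the package's own desk-scale choices:

* Null calibration: 1,000 pure-noise chromosomes of 200 probes
  (sd 0.2), full CBS with n_perm = 2000 (≥ 1/α; add-one p floor 1/2001 <
  α); split rate is compared with Binomial(1000, 0.001) and the median
  segment count with 1.
* Breakpoint recovery: 100 chromosomes of 100 probes, one planted
  15-probe segment at Δ = 3σ; recovery = both boundaries within ±2
  probes; n_perm = 2000.
* Motif recovery: 20 replicates of 50 × 300 bp at occupancy 0.9 with a
  fresh random deterministic 15-mer each; recovery = exact consensus on
  either strand.
* Staged pipeline: 3 chromosomes × 150 probes, five samples, run twice;
  checks bit-identical manifests and a non-decreasing altered-probe
  fraction across normal → transgenic → tumor → cell line.

## Numerical choices and degenerate inputs

Arc statistics use cumulative sums with within-group sums of squares
clipped at zero; zero-variance arcs give t = ∞ when the means differ and
0 otherwise, so a constant chromosome never splits. Chromosomes shorter
than 2·min_width return a single segment. ε > 0 is enforced for ratio
computation; negative intensities, unknown sample ids, non-ACGT motif
sequences, out-of-bounds ISRs and invalid parameter ranges raise
ValueError. EM handles all-identical sequences through the pseudocounts.

## Known limitations

Single-sample segmentation only (no joint multi-sample model); no
localization of the break within an ISR; no E-value calibration or motif
database comparison; the breakpoint-overlap tolerance is user-set rather
than derived; concordance uses whole-gene intervals rather than exon
annotation. Reported percentages on synthetic data include the
noise-induced spill of diploid probes out of the unchanged band, exactly
as array data would.
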