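# Methods

## The measurement being modelled

After mitosis, transcription restarts from a globally silenced state. The
pipeline analyses the bulk version of this experiment: cells arrested in
metaphase, released, and sampled at 20–120 minutes, with transcription read
out as pre-mRNA TPM (intronic signal, a proxy for ongoing synthesis rather
than accumulated mRNA). Two anchors frame the release grid: mitotic samples
(the baseline) and asynchronous samples (the steady-state a gene eventually
returns to — or, for S-phase-enriched genes such as histones, exceeds
because cycling populations are S-phase-rich). A second arm with acute
degradation of a candidate bookmarking factor (CTCF via auxin) asks which
genes depend on the factor, and when.

## Pre-mRNA quantification support

Two annotation rules sit upstream of quantification. First, each gene gains
one single-exon "pre-mRNA" transcript spanning its longest existing
transcript, so intronic reads are countable as a distinct isoform; the
literal reading (span of the single longest transcript, not the union of
all isoforms) is the default, union mode behind a flag. Second, one primary
TSS per gene is selected as the candidate maximizing the sum of three
min–max-rescaled chromatin evidence scores (RNAPII, H3K4me3, DNaseI);
rescaling is needed because the raw marks live on incomparable scales, and
exact ties resolve to the 5′-most candidate on the gene's strand. The
combiner (sum of rescaled scores) is this package's choice; only the three
marks themselves are given by the protocol.

## Trajectories

Per replicate r: lfc_r(t) = log2((TPM_t,r + pc)/(TPM_M,r + pc)), averaged
over replicates; the asynchronous anchor identically. Pairing is by
(condition, replicate); a condition with a single mitotic pool pairs all
samples to it. The pseudocount (default 1 TPM, config-exposed) bounds fold
changes of near-zero mitotic signal; with pc → 0 the trajectories become
exactly scale-equivariant (tested). z-scores standardize the ordered
vector (asynchronous, mitotic ≡ 0, release grid) per gene, population SD;
constant trajectories get all-zero z-scores rather than NaN. Ranking uses
the arithmetic mean of the 20–90-min fold changes, descending, gene-id
lexicographic on ties. A missing timepoint stays NaN — never imputed — and
routes the gene to an explicit `unclassifiable` bucket downstream.

## Reactivation classes

"Reaching" asynchronous levels uses ≥, so equality counts. G1_high
(asynchronous fold change < 0) takes precedence over the reach-time rule:
such genes trivially reach their (sub-mitotic) asynchronous level at the
first timepoint, and they are biologically a distinct early-G1 class.
Reach times ≤ 40 min collapse into t40; 120-min reachers and never-reachers
merge into late. The trajectory maximum for the cumulative "maximum
reached" curve is taken over the asynchronous anchor plus the release grid;
the mitotic anchor (identically 0) is excluded from the argmax. Both the
max-at-asynchronous count and the never-crossed count are emitted, since
the two readings of "never reached" differ on edge cases.

PCA: per-gene centring of the samples × genes per-sample fold-change
matrix, no variance scaling, exact SVD. Loadings are unit-norm; each
component's sign is fixed so the last sample's score is non-negative
(reproducible across linear-algebra backends). The top/bottom
`loading_group_size` genes per component form the t/b groups; at full-data
scale this is 1,000, and the synthetic default scales it to n/10 so the
groups remain small against the universe.

## Enrichment machinery

The one-sided Fisher p is the hypergeometric upper tail P(X ≥ a), evaluated
through `scipy.stats.hypergeom.logsf` so that log10 p stays finite for
arbitrarily extreme tables (p itself may underflow to 0 in float64; the
log-space value is always reported alongside). Odds ratio is the sample
(a·d)/(b·c), NaN for 0/0, +inf when only the denominator is zero. BH is the
textbook step-up with monotonicity enforcement, input order preserved;
statsmodels' implementation serves as an independent cross-check in the
tests, never as the implementation. The sliding-window scan uses 500-gene
windows advanced by 50 (both config-exposed; the step is this package's
choice), intersects each set with the ranked universe first, and corrects
across all (window, term) pairs of a run as one family (per-term families
behind a flag). All enrichment tests default to one-sided greater —
enrichment questions are directional — with two-sided behind a flag. The
default background universe is the filtered gene set.

## Binding-site integration

An interphase peak is Book iff it overlaps ≥ 1 bp of any mitotic peak,
else Lost; Book + Lost partitions the interphase set exactly. Gene-level
association uses any ≥ 1 bp overlap between a peak and the 25-kb window
[TSS − 12,500, TSS + 12,500). Gene-level bookmarked = ≥ 1 Book peak in the
window; gene-level lost = ≥ 1 interphase peak but no Book peak (one of two
defensible readings; documented, not asserted as canonical). TSS-to-peak
distance is the unsigned gap to the nearest peak edge, 0 inside a peak;
the distance grid (1, 2.5, 5, 10, 25, 50, 100, 250, 500, 1000 kb) is a
discretization choice. Nearest distances use a sorted-array scan whose
equivalence to an O(n·m) brute force is tested on random instances.
Metagene profiles bin coverage over 8 kb around each TSS at 50 bp, flip
minus-strand windows so upstream is left, average across genes, and scale
by 1e6/library_size; windows leaving chromosome bounds are dropped with a
logged count.

## Differential response to depletion

Per contrast the +IAA and untreated arms are compared on log2(TPM + pc).
The default test is an empirical-Bayes **moderated t**: gene-wise pooled
variances (df = n1 + n2 − 2) are shrunk toward a scaled-inverse-chi-square
prior fitted across all genes by matching the moments of log s² (Smyth-style
method of moments; prior df solved with Brent's method), and the statistic
uses the posterior variance with df + d0 degrees of freedom. With the
design's two replicates per arm per timepoint, a per-gene Welch test has
~2 denominator df and essentially no power at FDR 0.1; borrowing strength
across genes is what the count-based tools used on real data of this kind
do through dispersion shrinkage, and the moderated t is the log-scale
analogue. The plain Welch test remains available (`method="welch"`), and
externally computed DE tables in the same schema can be imported to bypass
the stand-in entirely, which is the recommended route for real data.

Response rule, verbatim from the thresholds: a gene responds iff
(FDR < 0.1 and |log2FC| > 0.2) in the asynchronous contrast or in ≥ 2
release contrasts. Timing: early iff the earliest qualifying release
minute ≤ 40 (config `early_max_min`; the early/late boundary is a
documented decision, the source experiment marks response windows only
graphically); late iff release support exists only from ≥ 50 min; asy iff
asynchronous-only. Direction comes from the common sign of the qualifying
contrasts; sign-conflicted genes are flagged discordant and excluded from
the six classes (conservative; counted). A gene with one release hit plus
an asynchronous hit classifies as asy: single release hits never count as
post-mitotic support.

## The synthetic generator

Every downstream stage is exercised on simulated data with planted truth.
The generator is not a fixture factory but a model of the study conditions:

* **Design**: 3 replicates each of asynchronous and mitotic pools, 2 per
  release timepoint, grid {20, 30, 40, 50, 60, 90, 120} min, one or two
  conditions.
* **Kinetics**: mean TPM is the mitotic baseline before onset, jumps to
  amplitude × baseline at onset, and decays back with a configurable
  half-life (infinite = sustained). This piecewise form is the simplest
  that reproduces the four observed dynamic families (fast/slow
  reactivation, G1-specific burst, poorly transcribed); real trajectories
  are empirical and smoother.
* **Class mixture** (defaults, chosen once to mirror the published
  composition of reactivation classes): fast_burst 32%, slow_sustained
  25%, g1_specific 8%, s_phase_like 10% (asynchronous-maximal,
  histone-like), late 5%, silent 20% (below the expression filter).
  Burst magnitudes (amplitudes 2–12×, baselines log-normal around 3 TPM)
  are calibration choices; no quantitative per-class magnitudes are
  printed anywhere to copy.
* **Noise**: multiplicative log-normal, SD 0.25 log2 units (TPMs are
  positive and heteroscedastic). The noise matrix is drawn from its own
  stream keyed only on seed and shape, so changing a kinetic parameter
  never reshuffles noise — response means are monotone in amplitude under
  a fixed seed (tested).
* **Depletion effects**: 2×/0.5× multipliers on the +IAA arm over
  class-specific samples (asy: asynchronous only; early: all release
  timepoints; late: ≥ 50 min), planted on ~8% of genes (3% early_down,
  1.5% early_up, 1.5% late_down, 1% late_up, 0.5% each asy).
* **Peaks**: background interphase sites at 50/Mb, 30% retained in
  mitosis; early responders additionally receive a promoter-proximal Book
  site with probability 0.8 at a signed-exponential offset (scale 2 kb),
  with planted heights 2× background. Mitotic binding is a strict subset
  of interphase binding (the Book/Lost dichotomy); de-novo mitotic-only
  sites are not modelled. Coverage tracks are piecewise-constant sums of
  peak heights — adequate for geometry contracts (symmetry, strand flips,
  RPM scaling), not for realistic read-level noise.

What passing on this generator shows: the arithmetic, classification
rules, test calibration, and planted-structure recovery of every stage are
correct under log-normal noise and idealized kinetics. What it does not
show: robustness to count noise at low expression, isoform ambiguity,
batch structure, or mappability artifacts in real coverage.

## Problem sizes and numerical choices

The packaged study runs at 2,000 genes on three 20-Mb chromosomes — large
enough that the filter, the PCA groups (200 genes at this scale), the
500-gene windows and the distance strata are all non-degenerate, small
enough that the full seed-swept acceptance run completes in well under a
minute per seed. Determinism is byte-level: all randomness flows from one
user seed through named substreams, tables are written with fixed float
formatting, and manifests carry no timestamps. Degenerate inputs are
guarded explicitly: empty curated sets, empty TSS lists and zero
chromosomes are configuration errors distinct from empty results; zero
variance in both arms yields p = 1, not NaN; constant trajectories z-score
to zero; empty groups and empty-after-intersection terms are skipped with
warnings, never silently dropped.

## Known limitations

* The DE stand-in operates on TPM, not counts; per-sample library depth
  and gene length do not enter the variance model. Import real DESeq2/edgeR
  tables for publication-grade calls.
* The early/late response boundary (40/50 min) and the ≥ 2-release-contrast
  support rule are documented defaults, not uniquely determined by the
  source analysis.
* LOESS-smoothed trajectory displays are intentionally absent from the
  statistics path; figures plot the unsmoothed stage tables.
* Peak calling, motif analysis, read alignment and isoform quantification
  are out of scope; the pipeline starts from TPM tables and peak BED files.
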