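# Methods

## Coordinates, gene models, canonical transcripts

All internal coordinates are 0-based half-open on a named chromosome with
an explicit strand; GFF3 (1-based inclusive) and the refFlat-style TSV /
BED12 dialects are converted at the file boundary only. A gene model is
one transcript: ordered non-overlapping exons inside the transcript span,
optionally a CDS interval. Introns are the gaps between consecutive
exons; their **ordinal** is counted 5'→3' in gene orientation, so for a
minus-strand gene intron 1 is the gap with the largest genomic
coordinates. UTR lengths are exonic basepairs strictly 5' (respectively
3') of the CDS in gene orientation; non-coding transcripts carry no UTR
features and are excluded from UTR/ARE statistics rather than counted as
length 0, which would conflate absence with shortness.

Where several transcripts share a symbol, one **canonical transcript** is
chosen deterministically: greatest exonic length, ties broken by smallest
gene id. This rule is a declared convention of the package — collapsing
transcripts to "one gene" is under-determined and any fixed deterministic
rule serves, provided it is applied uniformly to hosts and controls.

Sequences are normalized to uppercase RNA (T→U) on ingest so the AU-rich
element pentamer is always written AUUUA.

## miRNA classification

A miRNA is **intragenic** iff its hairpin interval is fully contained in
some transcript span; a locus straddling a gene boundary stays
intergenic (containment is conservative and deterministic; the
alternative — any-overlap — would make the class depend on how far a
hairpin annotation extends). Among several containing genes the host is
the same-strand gene if any exists, otherwise the longest, ties by
smallest id; ambiguous cases are logged. An intragenic miRNA overlapping
≥ 1 bp of any host exon is **exonic**, otherwise **intronic** with the
ordinal of its containing intron. Classification is evaluated against
the host's canonical transcript only.

## Positional statistics

The expected share of intronic miRNAs at ordinal k weights each ordinal
by its total intron length across the host cohort:

    E_k = Σ_hosts len(intron_k) / Σ_hosts Σ_j len(intron_j),

so an ordinal that is frequent *and* long attracts proportionally more
expectation — the null of uniform placement per intronic basepair.
Observed counts are tested by Pearson goodness-of-fit χ² (asymptotic, no
continuity correction; df = cells − 1). The strand split of intragenic
miRNAs is tested against equal proportions by the same statistic. The
"first five introns" test restricts to ordinals 1–5 and renormalizes E_k
over that support, using only miRNAs located there — observed and
expected then live on the same support, at the cost of discarding the
tail. Small-sample behavior was checked against exhaustive multinomial
enumeration; the asymptotic p tracks the exact mid-p tail within ~0.15
at totals as small as 8, which is ample for cohort-scale counts.

## Host-gene features and cohort comparisons

Per gene: total genomic length, intron count, UTR lengths, ARE count
(AUUUA occurrences at **overlapping** positions — standard motif-scan
semantics; declared because plain "occurrences" is ambiguous), ARE per
kb of 3'-UTR (undefined, not 0, when the 3'-UTR is empty), and 5'-UTR GC
fraction.

Control cohorts are sampled per (chromosome, strand) stratum to match
the host distribution exactly, by default 10 controls per host; strata
with too few candidates are sampled with replacement and logged. The
3'-UTR-length-matched resampling sets stratify the universe over 20
quantile bins of host 3'-UTR length and accept a set only when a
Mann–Whitney test against the hosts gives p > 0.05 (conventional level;
resampling capped at 50 attempts, keeping the best attempt with a
warning).

The Mann–Whitney U test is exact by full enumeration of label
assignments (midranks, so ties are handled) for n₁ + n₂ ≤ 12, and the
tie-corrected normal approximation with continuity correction otherwise.
Three-group comparisons use Kruskal–Wallis with post-hoc pairwise
Mann–Whitney tests at the Bonferroni cut-off α/(number of pairs) —
0.05/3 ≈ 0.016 for three groups.

## Prediction agreement

Each catalog is reduced to a set of (miRNA, gene) pairs; a validation
database keeps only support types True or Microarray. Symbols missing
from the reference set are rescued by numeric-suffix extension
("-1" … "-5", all matches kept — the bounded deterministic search; known
families use at most "-3" but the cap leaves headroom), then by
stripping a single trailing letter and repeating; unmatched symbols are
dropped. **Agreement** is the number of distinct sources containing a
pair; the validation database counts toward the tally (seven possible
sources), and ≥ 6 defines the high-confidence set, ≥ 2 the coverage set.
A switch excludes the validation database where a methods-only tally is
wanted. The two-group voting check requires one vote from each of two
disjoint three-method groups and never admits the validation database as
a voter.

## Resampling enrichment

For a pathway gene set S_p, S_t is the union of predicted targets
(agreement ≥ 2) of miRNAs hosted by genes in S_p, and the coverage is
C = |S_p ∩ S_t| / |S_p|. The null replaces S_p by |S_p| genes drawn
without replacement from the universe (all annotated genes by default;
configurable). Because a uniform random gene set enters the statistic
only through its overlap with S_t, that overlap follows the
hypergeometric law exactly, and the implementation draws it directly —
an O(n_iter) equivalent of materializing each random set, verified
against exhaustive subset enumeration on small universes.

The empirical p is the plain fraction of null coverages ≥ C over 1000
iterations, with no smoothing, so p = 0 is representable ("< 1/n_iter").
A smoothed (+1)/(n_iter+1) estimator is available and off by default.
The distinction matters for FDR control: the plain estimator assigns
p = 0 with probability 1/(n_iter+1) under the null, and q-value
procedures always reject p = 0, which lifts the null expected false
discovery proportion of the whole pipeline to ≈ 0.126 — above the
nominal 0.10 for any seed. The smoothed estimator restores validity
(P(p ≤ t) ≤ t, null E[FDP] ≈ 0.09), and is the right choice whenever
calibrated FDR control is the goal; the plain fraction is kept as the
default for comparability with the conventional formulation.

q-values: Benjamini–Hochberg step-up, or Storey with the single-λ = 0.5
estimator π₀ = min(1, 2·mean(p > 0.5)) — deterministic and
dependency-free, in place of the spline-based π₀ of the original
q-value implementation (a declared simplification; for the pathway-scale
m ≈ 40–80 the spline estimate is noisy anyway).

Self-targeting: miRNAs whose pair with their own host reaches agreement
≥ 2. The null exchanges every host for a random surrogate (without
replacement within an iteration) drawn either from the non-redundant
predicted-target set of the hosted miRNAs or from caller-supplied
3'-UTR-length-matched sets, and recounts; p is the fraction of null
counts ≥ observed. Surrogates inherit only the host role — not strand or
position, which the statistic never consults.

Gene-set overrepresentation is the upper-tail hypergeometric
P(X ≥ overlap) per category with FDR across categories; category genes
absent from the universe are dropped with a warning.

## Evaluation

AUC uses the rank-sum identity (concordant + half-tied pairs over
n₊·n₋), scoring by the **negated** fold change since predicted targets
are expected to be repressed. The agreement-stratified evaluation pools
all measured (miRNA, gene) instances of the supplied miRNAs — the
measurement is per transfected miRNA, so the fold-change mapping is
keyed by the pair, not the gene alone — and labels positives by
agreement ≥ k, skipping single-class strata with a warning.

Conservation comparisons use the two-sample test for equality of
proportions with continuity correction (Yates-corrected χ² on the 2×2
table, statistic floored at 0); degenerate margins return p = 1.

Correlation contrasts default to Pearson (Spearman available) on the
provided expression values, with two-sided t-approximate p per group and
α = 0.05 for the pattern labels: *negative_in_N_lost_in_T* when the
host–target correlation is significantly negative in group N and
non-significant or significantly positive in group T;
*more_negative_in_N* when r_N < r_T otherwise; *other* else; constant
vectors are flagged undefined.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with every planted effect recorded in a truth object. Defaults (one
number per line: value — what it mirrors):

* class probabilities 0.426 / 0.053 / 0.521 (intronic / exonic /
  intergenic) and same-strand probability 0.85 — the human
  classification split;
* host/control median ratios: total length 2.9, intron count 13 vs 8,
  3'-UTR length 1.4, ARE per kb 2.0 (the absolute-ARE contrast; the
  per-kb medians printed for the real cohorts imply ≈ 1.3, but the two
  published rows are mutually inconsistent and the absolute ratio is the
  cleaner plant);
* positional bias β = 0.15 in the placement weight
  len(intron_k)·exp(−β(k−1)), which yields ~65% of intronic miRNAs in
  the first five introns, the reported magnitude;
* 6 prediction methods with sensitivities 0.8…0.5 against a latent
  true-target set (~30 targets per miRNA) plus 25 false positives per
  miRNA per method, and a validation database sampled from true pairs
  (never miRNA–host pairs) with support labels; sources are
  conditionally independent given the latent truth — real catalogs share
  biases, but independence is the minimal generative model under which
  agreement is informative, accepted openly as idealization;
* self-target fraction 0.2 of intragenic miRNAs; 40 pathways of 20–60
  genes; enrichment planting redirects a fraction γ = 0.5 of a hosted
  miRNA's true targets into its host's pathway (never onto the host
  itself, so the self-target truth stays exact);
* expression: 30 samples per group, host–target correlation −0.6 in
  group N and 0.0 in group T; conservation probabilities 0.35
  (self-targeting) vs 0.245;
* scale: 1000 genes on 5 chromosomes, 700 miRNAs, gene-length
  log-normal with median 25 kb and σ_log = 0.8 — a scaled-down genome
  whose cohort medians are estimable at ~250 genes per cohort while
  lengths still span about two orders of magnitude.

3'-UTR sequences carry **exactly** the planted number of AUUUA motifs:
after planting, accidental occurrences are scrubbed (a G placed at a
position not covered by a planted motif destroys every window through
it), so the host/control density contrast is not diluted by background
hits. Gene bodies are coordinate-only; only UTRs get sequence, since
nothing downstream reads body sequence.

What the generator does **not** emulate: correlated prediction sources,
realistic nucleotide composition beyond the planted motifs and GC,
splice-site signals, isoform structure (one transcript per gene),
overlapping genes, expression normalization artifacts. Tests passing on
these bundles therefore validate the statistical machinery and the
plumbing, not robustness to those real-data complications.

## Determinism and problem sizes

One seed drives everything: the pipeline derives per-stage generators
from the run seed via seed sequences, and reruns are byte-identical.
The shipped analyses use the generator's default scale (1000 genes, 700
miRNAs, 40 pathways, 1000 resampling iterations); the FDR-behavior
study uses 50 replicates of a 600-gene, 40-pathway configuration with
self-targeting disabled, since planted self-targets place host genes in
S_t and would contaminate the no-enrichment null. These sizes give the
resampling statistics stable behavior (binomial SE of an empirical p at
1000 iterations is ≤ 1.6 points) while keeping any single analysis in
the seconds-to-minutes range.

## Known limitations

* The exact Mann–Whitney path enumerates up to C(12,6) = 924
  assignments; beyond n = 12 the normal approximation is used even when
  ties are heavy.
* The plain empirical-p estimator is anticonservative at the p = 0
  boundary (see above); use the smoothed option for calibrated FDR.
* Storey's single-λ π₀ is noisy for small test families; BH is the
  safer choice below ~20 tests.
* Host assignment for miRNAs contained in several genes follows a fixed
  preference rule; true nested-gene biology may differ.
* The correlation contrast assumes pre-normalized expression and
  ignores probe-to-gene mapping issues entirely.
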