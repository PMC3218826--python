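# Methods

This note documents the models, parameter choices, and numerical decisions
behind mirsolid, and what the synthetic-data tests do and do not establish
about real data.

## Color-space model

A SOLiD read is a primer base followed by one color per sequenced base;
color i encodes the di-base transition (base i−1, base i) as the XOR of
the 2-bit base codes (A=0, C=1, G=2, T=3). Three consequences drive the
design:

* decoding is a prefix-XOR given any one anchor base;
* a single base substitution changes exactly two adjacent colors
  (one at a terminal position), whereas a single color *error* changes
  every decoded base downstream — hence all matching is done in color
  space, never on decoded sequence;
* colors are complement-invariant, so reverse-complementing is string
  reversal.

The first color of a read pairs the primer (or, at an adapter junction,
the adapter's last base) with the insert's first base. It is the only
anchor-dependent symbol, so both the genome matcher and the census drop
it and work on the insert's internal colors: a t-color trimmed read
contributes t−1 matchable colors. Quality values are carried one integer
per color exactly as read from `.qual` files, with no Phred rescaling.

## Adapter trimming

Inserts shorter than the 35-color read run into the 3' adapter. The
trimmer removes the longest read suffix whose colors match a prefix of
the adapter's internal colors — exactly for short overlaps, tolerating
one mismatch when the overlap spans ≥ 10 colors — together with the one
anchor-dependent junction color before it. Untrimmable reads pass through
unchanged; reads shorter than 15 colors after trimming are excluded as
`too_short` and tracked in the conservation identity.

## Matching and exclusive assignment

The mismatch budget is split: at most 1 color mismatch within the first
18 colors (the seed), at most 2 in the remainder; reads shorter than the
seed use their full length as the seed with the seed budget. Matching is
seed-and-extend over an exact color 8-mer index of both genome strands:
with a 1-mismatch seed budget, two disjoint 8-mers inside the seed region
pigeonhole every admissible hit, so index seeding is lossless; reads too
short for two disjoint index words fall back to an exhaustive scan. The
suite verifies hit-set equality against a literal budget scan on random
genomes.

Each mapped read is assigned exclusively: among its minimum-mismatch
hits, the highest-priority hierarchy class whose feature overlaps the hit
by at least half the read length wins; ties break by hierarchy priority,
then leftmost coordinate (deterministic output). Genome hits without a
qualifying feature are `non_annotated`. Assignment targets are leaf
features only — mature arms rather than precursor spans — so loop- or
flank-derived reads inside a hairpin fall through to `non_annotated`
rather than inflating mature counts. Multi-mapped reads count once, for
the single tie-broken feature, since downstream tables carry integer read
counts. The 50% rule also keeps isomiR end-variants (a ±1–2 nt jittered
22-mer) on their mature feature.

The default hierarchy (human miRNA first, non-annotated last) is a
configuration value, not a constant, because the category order of an
exclusive classifier is an analysis decision.

## Quantification

Raw counts are reads per mature miRNA per sample; normalized counts are
reads per 10⁶ miRNA reads in that sample (cpm), so each non-empty
sample's normalized column sums to exactly 10⁶ and a relative abundance
of 0.03% is exactly 300 cpm. Samples with zero miRNA reads get missing
normalized values rather than zeros. Condition-level relative abundances
average the per-sample percentages (not pooled counts), so replicates
with very different depths weigh equally. Pre-miR profiles report
per-base coverage in precursor orientation plus 5p/3p arm counts under
the same 50%-overlap rule; the arm fraction is undefined (NaN) when no
arm reads exist. The comparative-CT utility implements
2^−(CT_target − mean CT_refs) for qPCR cross-checks.

## Differential expression

The model is a one-way Gaussian linear model on log₂(cpm + 0.5). The
pseudocount lives on the cpm scale (half a normalized read per million):
large enough to make zeros finite, small enough (< 1% bias above 100 cpm)
not to distort tested features. Per-feature residual variances s² with d
degrees of freedom are shrunk toward a scaled inverse-chi-square prior
whose parameters (d₀, s₀²) are estimated by matching the first two
moments of log s² — digamma/trigamma identities, with the trigamma
inverted by Newton iteration (guarded closed forms for extreme targets).
If the observed spread of log s² does not exceed what chi-square sampling
noise alone predicts, the prior degrees of freedom are set to +∞
(complete pooling; test statistics become z-scores). The moderated t uses
the squeezed variance and d₀+d degrees of freedom.

Technical replicates (the two sequencing directions of one library) are
averaged on the log scale into one biological unit before fitting, to
avoid pseudo-replication; fold changes reported per contrast are
replicate-pairwise log-ratios with their standard error. Selection
follows raw P < 0.05 with Benjamini–Hochberg values always reported
alongside — the selection rule is permissive about multiplicity, and the
table makes that visible. The implementation is cross-checked in the test
suite both against straight-line evaluation of the closed forms (1e-10)
and against R limma on a shared fixture.

## Census of near-identical candidates

Two mature candidates differing at one 3'-terminal base differ at exactly
one color. The census encodes each candidate, drops the anchor-dependent
first color, and counts raw reads whose colors contain the remaining
string — at insert offset 0 by default, since small-RNA inserts start at
the adapter junction (any-offset search is available; offset-0 is the
default because offset matches elsewhere in a 35-color read are almost
surely adapter or chimera artifacts). 3'-direction reads are searched
with reverse-complement (reversed) colors. Candidates of unequal length
are compared over the shorter one. `positional_quality` then reports the
mean quality at the discriminating color positions against the read-wide
mean: a genuine rare species shows ordinary quality there, while
sequencing errors concentrate at low-quality cycles.

## Seed sites and enrichment

Sites are perfect Watson-Crick complements of miRNA bases 2–7 (6mer) with
optional m8 extension and/or the anchoring adenosine opposite base 1 —
an A in the target regardless of the miRNA base. No G:U wobble is
allowed, matching canonical site definitions. Each 6mer core occurrence
is reported once at its strongest extension (8mer > 7mer-m8 > 7mer-A1 >
6mer), with 1-based inclusive UTR coordinates. Enrichment of a target set
among regulated genes is the upper hypergeometric tail with fold
enrichment observed/expected; the suite checks it against exhaustive
enumeration on small universes. Conservation scoring is out of scope; a
user-supplied conservation flag is carried as metadata only.

## Synthetic data generator

The generator emulates the statistical structure of a two-condition
(baseline ND, differentiated AD8) small-RNA study at 10⁵ reads per
sample, 2 biological replicates, each sequenced in both directions:

* **Composition.** Category budgets: miRNA 43% of reads, non-annotated
  38%, transcript 5%, tRNA 4%, rRNA 3%, piRNA 3%, snoRNA 2%, other ncRNA
  1.5%, other-species miRNA 0.5% — the observed shape of such libraries,
  where roughly 40–45% of mapped reads are miRNAs and over a third are
  un-annotated.
* **miRNA skew.** 150 precursors with 5p/3p arms; two dominant matures at
  30.2% and 13.8% of baseline miRNA reads; remaining unregulated arms
  log-normal (σ = 1.5), split 85/15 between arms.
* **Regulation.** A 5-member family planted up-regulated so its share
  rises ~1.1% → ~4.9% of miRNA reads; 15 further up- and 5 down-regulated
  matures with fold changes of the magnitudes such studies report
  (|log₂| ≈ 1.3–4.5); 21 planted up and 5 down in total. Recorded truth
  is the resulting cpm-scale fold change after compositional
  renormalization — unregulated features therefore carry a true lfc of
  about −0.22, which the estimator is expected to reproduce, not to
  remove.
* **Novel arm and decoy.** The last precursor's 3p arm has exactly zero
  baseline weight and ~450 cpm after differentiation (its 5p partner
  stays below the 300-cpm filter); a decoy mature sequence sits on the
  opposite strand nearby, equal to the 3p arm except at its final base,
  at 1/14 its abundance. The substituted base is chosen not to equal the
  adapter's first base — otherwise a 3'-shortened isomiR of the twin
  reads into the adapter and becomes byte-identical to the decoy, which
  would conflate end jitter with the planted species.
* **Background classes.** 5'-tRNA fragments (20 nt from the 5' end),
  rRNA/snoRNA/transcript degradation windows (17–30 nt, uniform), full
  piRNAs, an up-regulated 21-nt intronic locus with no annotation, and
  intergenic noise.
* **Read geometry and errors.** Inserts of 17–35 nt inside 35-color
  reads with adapter read-through; isomiR end jitter (5': 92% exact, 3':
  80% exact, ±1–2 nt otherwise); per-color quality declining linearly
  along the read (≈32 → ≈13 with Gaussian cycle noise), error probability
  10^(−q/10) capped at 0.25 — about 1% per color averaged over the
  matchable region, concentrated late in the read. A `flat_quality`
  override gives a uniform error rate for controlled experiments.
  Biological replicate noise is log-normal, σ = 0.15 log₂ units per
  feature and replicate, shared between the two technical directions.
* **Reproducibility.** One master seed feeds named substreams (reference,
  abundances, per-sample reads), so outputs are byte-identical for a
  fixed seed; a separate `reads_seed` varies sequencing noise under a
  fixed planted truth, which is what the multi-seed recovery analyses
  use.

What passing tests on this generator do **not** show: real SOLiD error
physics (spectral cross-talk, panel effects) is not modeled; adapter
ligation biases and GC effects are absent; the genome is collision-free
random sequence, so multi-mapping is far rarer than in a real genome with
miRNA families of near-identical paralogs; and the decoy is the only
planted near-duplicate. Results on real libraries will be noisier in all
of these directions.

## Problem sizes and numerical choices

The acceptance analyses run the full pipeline at the study scale —
10⁵ reads/sample × 8 samples × 20 sequencing seeds for fold-change
recovery, and 50 seeds at 4×10⁴ reads for the census ratio; the census
scenario plants the twin at 0.5% of miRNA reads with a uniform 1%
per-color error so the expected decoy count (~5 perfect matches) makes a
ratio informative. At the 100-cpm floor a feature receives only ~4–6
reads per sample, leaving irreducible shot noise of ~0.15 log₂ units in
the 20-seed-averaged estimate; recovery is therefore summarized as the
fraction of qualifying features within ±0.25 (≥ 95%) and the mean
absolute error, rather than a per-feature worst case that sampling noise
alone would break.

Degenerate inputs: zero-miRNA catalogs are valid (everything maps to
other classes or non-annotated); samples with no miRNA reads normalize to
missing values; all-zero residual variances raise a prior-estimation
error rather than returning numbers; trigamma inversion failures fall
back to d₀ = ∞. Ties anywhere in assignment break deterministically.
Index k-mers are restricted to 8–18 colors: shorter words index nothing
usefully, longer ones exceed the seed.

## Known limitations

* The matcher reports all equal-budget hits but the assignment keeps one
  feature per read; fractional allocation of multi-mapped reads is out of
  scope by design.
* The abundance filter and the moderated-t fit assume cpm-scale
  normalization is adequate; no attempt is made at count-likelihood
  (negative binomial) modeling, multi-factor designs, or batch
  correction.
* Seed-site scanning covers canonical site types only — no context
  scores, conservation, or accessibility.
* The pipeline targets desk-scale genomes (toy references up to a few
  hundred kb); the color index is held in memory and is not designed for
  a full mammalian genome.
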