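# Methods

## The two-compartment epiallele model

Every sample is modeled as a mixture of two cell compartments: germ cells
(fraction `f ∈ [0, 1]`) and somatic cells (`1 − f`). Each sequenced read is
one allele drawn from one compartment. Alleles are *epiallele-coherent*: a
single Bernoulli draw with the compartment's methylated-allele probability
sets all CpGs of the read identically. This reproduces the dominant structure
of single-allele methylation plots at these loci — rows that are fully
methylated or fully unmethylated — and makes read classification well-posed.
Partial methylation enters only through (i) the mixture, (ii) incomplete
bisulfite conversion, (iii) sequencing error, and (iv) injected epimutations
acting on the germ compartment's allele probability.

Methylated-allele probabilities by locus class:

| class             | soma                         | germ | examples           |
|-------------------|------------------------------|------|--------------------|
| germ_marker       | 1.0                          | 0.0  | FGFR3, DDX4, RHOXF1|
| maternal_imprint  | 0.5                          | 0.0  | MEST, LIT1, MEG3*  |
| paternal_imprint  | 0.5                          | 1.0  | H19                |
| x_inactivation    | 1.0 (46,XY); 0.5 (46,XX, 47,XXY) | 0.0 | XIST          |

\* The assayed *MEG3* region is modeled with the germ-unmethylated class
because its methylation *decreases* in germ-cell fractions (sperm-side level
~0), which is also the direction against which the MEG3-gain anomaly is
defined. The class label describes mixture behavior at the assayed amplicon,
not the gene's parental imprint annotation.

An epimutation of magnitude `e ∈ [−1, 1]` at a locus shifts the germ
compartment's probability to `clamp(P + e, 0, 1)`. The three anomaly types
observed in Klinefelter germ-cell fractions map to: `e = −1` at H19 (loss of
germline methylation), `e = +1` at MEG3 (gain), `e = +0.5` at MEST (germ
alleles at the somatic 50% level, hence no shift).

## Bisulfite chemistry and sequencing noise

One `conversion_rate` parameter (default 0.995) governs both failure modes:
an unmethylated C reads as T with probability `conversion_rate` (else it
stays C — inappropriate non-conversion), and a methylated CpG C stays C with
probability `conversion_rate` (else it reads T). Sequencing error (default
0.002/base) substitutes a base uniformly with one of the other three.
Substitution-only: indel and homopolymer artifacts of the original sequencing
chemistry are out of scope. Read length equals the amplicon length; FASTQ
qualities are constant and unused downstream.

With these defaults a 200 bp amplicon with 10 CpGs and ~15 non-CpG cytosines
gives near-perfect read classification while still exercising the QC filters:
about 7–10% of reads fail the per-read conversion threshold (one conversion
failure among 15 non-CpG Cs gives 14/15 ≈ 0.93 < 0.95). The filter keys on
non-CpG cytosines only, so it is independent of methylation state and does
not bias the methylation estimates.

## Alignment

Reads are aligned semi-globally (the read fully consumed; reference overhang
at the read's ends free) against the *unconverted* reference. Scoring is
bisulfite-asymmetric: reference C vs read T scores as a match (expected
conversion), reference C vs read C as a match (methylated or unconverted);
the reverse (reference T vs read C) is an ordinary mismatch. Methylation
state therefore never changes the score, keeping M/U calling unbiased.
Defaults: match +1, mismatch −1, gap −2. DP ties break diagonal > up > left;
among equal-scoring end columns the rightmost is taken.

Both the read and its reverse complement are aligned under the same matrix
and the higher score wins (ties → forward). Scoring the reverse complement
against the top strand with C~T tolerance is the mirror image of scoring the
original read letters against the bottom-strand G~A conversion expectation;
calls from a reverse alignment are made on the reverse-complemented sequence,
which equals the G→M / A→U convention on the original letters.

The exact full-matrix DP is validated against an exhaustive enumeration
oracle on small instances. The high-throughput sample caller additionally
uses a diagonal band (default ±16) — exact for the substitution-only reads
this assay produces — to keep million-read simulations tractable; `band=None`
restores the full matrix.

## Calling, QC, and summaries

Per read: CpG positions covered by a base are called M (C), U (T) or N
(anything else or a gap); `conversion_rate_read` = converted / aligned
non-CpG reference Cs (undefined, and the read fails QC, if none aligned);
`aligned_fraction` = aligned reference positions / reference length.
Defaults: `min_conversion = 0.95`, `min_aligned = 0.8`. A read is *fully
unmethylated* if its M fraction over non-N calls is ≤ `read_class_max_minor`
(default 0.1, tolerating one miscall on a 10-CpG amplicon), *fully
methylated* if ≥ 0.9, otherwise *mosaic*. Mean methylation is the mean over
passing reads of the per-read M fraction (×100): the single-allele (per-read,
then average) convention. Zero passing reads yield an explicit missing
summary, never 0%. Coordinates are 0-based internally and 1-based in exported
matrices.

## Mixture inference

**Purity gate.** Applied only to SN fractions declared gate-eligible in the
sample sheet (normal-group SN). A sample is excluded iff its VASA/DDX4 mean
methylation is strictly above 4% ("higher than 4%": a sample at exactly 4.0
is kept). KS SN fractions bypass the gate — for these patients only
enrichment, not purification, is achievable, and the germ fraction is instead
estimated explicitly. Gated samples lacking a marker summary are reported
unevaluable rather than silently included.

**Fraction estimation.** `f̂` is the read-count-weighted mean of `p_unmeth`
over the germ-marker loci (all three markers are averaged; per-locus values
are also reported). The 95% CI is a percentile bootstrap (default 1000 reps,
seeded) that resamples each locus's read classes multinomially. Because
epialleles are near-binary, resampling classes is equivalent to resampling
reads up to the negligible within-class spread; the same scheme supplies the
uncertainty for mean methylation, using the observed class-conditional means.

**Expected shift and flags.** The somatic reference is taken from each
patient's own AT fraction — absorbing residual germ cells in AT — via
`s = (m_AT − f_AT·g)/(1 − f_AT)` (undefined for `f_AT = 1`; requires
`f_AT ≤ f_SN`), with `f_AT` estimated exactly like `f_SN`. The SN expectation
is `m_expected = (1 − f_SN)·s + f_SN·g`, clamped to [0, 100]; it is monotone
in `f_SN` (decreasing for germ-unmethylated classes, increasing for the
paternal class). Flags, tried in order on each non-marker locus:

1. `wrong_direction` — the observed AT→SN shift is real (|m_SN − m_AT|
   exceeds the bootstrap 95% null width) and opposes the expected direction,
   while the expected |shift| exceeds `tolerance_delta` (default 10 pp). The
   null-width condition keeps flat profiles, whose tiny sampling noise has an
   arbitrary sign, out of this rule.
2. `no_shift` — the observed shift is within the null width while the
   expected |shift| exceeds the tolerance.
3. `magnitude` — |m_SN − m_expected| exceeds the tolerance and the SN
   bootstrap CI excludes `m_expected`.

The three rules correspond one-to-one to the three anomaly phenotypes the
flagging is designed to detect (a shift in the wrong direction; no shift
where one was expected; a shift of the wrong size). The 10 pp tolerance and
the bootstrap null-width construction are this package's operationalization
of qualitative published judgements; both are exposed in configuration.

## Group statistics

Per locus (one multiple-testing family per locus): if any group with n ≥ 3
fails Shapiro–Wilk at α = 0.05, all groups are transformed `x → log(x + 0.5)`
(the offset covers exact zeros) for testing; displayed means remain on the
percent scale. One-way ANOVA, then all pairwise two-sided Welch t-tests
(unequal group sizes and variances are the norm in these cohorts), Holm
step-down adjusted. Letter codes: reference group *i* owns letter chr('a'+i);
a group's code appends that letter once/twice/thrice for adjusted
p < 0.05 / 0.005 / 0.001. Holm is implemented directly (sort ascending,
multiply the k-th smallest by m−k, enforce monotonicity, cap at 1) and is
cross-checked against statsmodels in the tests.

## Synthetic cohorts: what they do and do not establish

The demo cohort mirrors the study's group sizes (normal: 5 SN / 4 AT / 3 SCO
/ 5 blood / 6 sperm; KS: 7 blood, 3 SN + 3 AT with germ cells, 3 AT without).
Published per-sample germ-cell percentages are figure-only, so the demo germ
fractions are chosen values: KS SN f = 0.6 / 0.5 / 0.7 (enrichment without
purification), KS AT f = 0.02–0.05, normal SN f = 0.985–1.0 (differential
plating of normal tissue yields highly pure fractions, clearly below the 4%
gate), normal AT f = 0.03–0.10, SCO and blood f = 0, sperm f = 1. Default
depth is 500 reads/locus.

The simulator emulates mixture composition, epiallele coherence, conversion
failure, and uniform sequencing error. It does **not** emulate PCR bias,
chimeras, bisulfite degradation, indels, primer or barcode artifacts, partial
(CpG-by-CpG) epimutations, or biological within-compartment heterogeneity. A
green test therefore establishes that the inference correctly inverts the
stated generative model at realistic noise — not that it is robust to
artifacts outside that model.

## Numerical and reproducibility choices

- All randomness flows from one seed through `numpy.random.SeedSequence`
  spawning (stable derivation per stage, sample, and bootstrap), so re-running
  a configuration reproduces byte-identical FASTQ and TSV outputs; the run
  manifest records a configuration hash and artifact checksums.
- Percentile bootstrap CIs are clamped to contain the point estimate.
- Degenerate inputs are explicit errors or explicit missing states: empty
  reads, all-constant groups, pure-germ AT fractions, zero passing reads,
  absent marker summaries.
- Synthetic panel sequences control their CpG layout exactly (no accidental
  CpGs; ≥ 5 non-CpG cytosines per locus so conversion is always estimable);
  they are stand-ins, so per-locus quantitative claims about the real assays
  are out of scope.

## Known limitations

- The germ-fraction estimator assumes markers are strictly soma-methylated /
  germ-unmethylated; marker epimutations would bias it.
- The magnitude rule propagates no uncertainty from `f̂` or `m_AT` into
  `m_expected`; at very low read counts (≲ 200/locus) its false-positive
  rate rises. Defaults (500–1000 reads) keep expected deviations well inside
  the 10 pp tolerance.
- Mosaic (partially methylated) reads are summarized but the aberration rules
  treat methylation only through per-sample means.
- XIST karyotypes beyond 46,XY / 46,XX / 47,XXY (e.g. 48,XXYY) are not
  modeled.
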