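# epiallele

Single-allele deep bisulfite sequencing (DBS) analysis of germ-cell-enriched
testicular cell fractions.

## The problem

Testicular biopsies processed by differential plating yield a germ-cell
enriched supernatant fraction (SN) and a somatic-cell-rich attached fraction
(AT). Amplicon DBS reads each sequenced molecule — one allele — across the
CpGs of a targeted region, so a sample's reads form a mixture of germ-derived
and soma-derived epialleles. This package implements the complete analysis of
such data on synthetic cohorts with known ground truth:

- **Read calling** — bisulfite-aware alignment of each read against the
  unconverted reference, per-CpG M/U/N calls, per-read conversion-rate QC from
  non-CpG cytosines, and per-sample × locus summaries (mean methylation;
  proportions of fully methylated / fully unmethylated / mosaic reads).
- **Purity gating** — germ-cell marker promoters (*FGFR3*, *VASA/DDX4*,
  *RHOXF1*) are methylated in soma and unmethylated in germ cells; SN
  fractions from normozoospermic donors with VASA/DDX4 methylation above 4%
  are excluded as contaminated.
- **Germ-cell fraction estimation** — at the marker loci, the proportion of
  fully unmethylated reads estimates the germ-cell fraction
  `f̂ = Σᵢ nᵢ p_unmeth,i / Σᵢ nᵢ` (read-count-weighted over marker loci), with
  a seeded nonparametric bootstrap 95% CI.
- **Imprinting-aberration detection** — for each patient, the somatic
  reference level is inverted out of the AT fraction,
  `s = (m_AT − f_AT·g)/(1 − f_AT)`, and the SN methylation expected under
  intact imprinting is `m_expected = (1 − f_SN)·s + f_SN·g`, where `g` is the
  germline level of the locus class (0% for maternally imprinted DMRs, germ
  markers and *XIST*; 100% for paternally imprinted DMRs). Deviations are
  flagged by three rules: `wrong_direction`, `no_shift`, `magnitude`.
- **Group statistics** — per-locus one-way ANOVA and pairwise Welch t-tests
  with Holm's step-down correction, optional `log(x + 0.5)` transform when a
  Shapiro–Wilk check fails, and compact letter codes (a / aa / aaa for
  adjusted p < 0.05 / 0.005 / 0.001 against each reference group).
- **Simulator** — generates FASTQ amplicon reads from an 8-locus panel
  (*H19*, *MEG3*, *MEST*, *LIT1*, *FGFR3*, *DDX4*, *RHOXF1*, *XIST*) for
  cohorts with chosen germ fractions, karyotypes (46,XY / 46,XX / 47,XXY),
  bisulfite conversion rate, sequencing error, and injected germ-compartment
  epimutations, together with read-level ground-truth tables.

## Worked example

```bash
epiallele all --demo --seed 1 --out runs/demo
```

simulates the demonstration cohort (normal group: 5 SN, 4 AT, 3 SCO,
5 blood, 6 sperm; Klinefelter group: 7 blood, 3 SN + 3 AT from 47,XXY
patients with germ cells, 3 AT without), calls every read, and writes all
stage outputs plus a manifest. The three KS patients carry one injected
germline anomaly each: *H19* unmethylated instead of methylated, *MEG3*
methylated instead of unmethylated, *MEST* pinned at the somatic level.
`assessments.tsv` then reads (values in %, 300 reads/locus shown):

```
patient_id locus  m_AT  m_SN  m_expected  delta  aberrant          reason
       KS1   H19  51.7  21.9        80.7  -58.8      True wrong_direction
       KS2  MEG3  53.6  75.4        28.4   47.0      True wrong_direction
       KS3  MEST  48.0  50.1        16.0   34.2      True        no_shift
       KS3  LIT1  48.0  15.6        16.0   -0.4     False
```

KS1's *H19* dropped to 21.9% where the mixture model expected a rise to
80.7%; KS2's *MEG3* rose instead of falling; KS3's *MEST* stayed flat where a
32-point drop was expected — while intact loci (e.g. *LIT1*) match their
expectation within a point. The estimated germ-cell fractions
(`fraction_estimates.tsv`) recover the simulated truth, e.g. KS1 SN:
f̂ = 0.617 (95% CI 0.581–0.650) for a true f = 0.6. In `group_stats.tsv` the
marker locus *DDX4* shows the expected group structure: SN and sperm near 0%
methylation with letters `aaabbb` (different from blood and AT at p < 0.001),
somatic fractions near 100%.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-simulates three scenarios from scratch and reports: the mean *XIST*
methylation of a noise-free 46,XY somatic sample and of a 47,XXY somatic
sample under default noise (500 reads each, via the full caller), and the
maximum VASA/DDX4 methylation among SN fractions retained by the 4% purity
gate on a mixed-purity synthetic cohort.

## Layout

- `src/epiallele/panel.py` — amplicon loci, imprint classes, panel generator
- `src/epiallele/simulate.py` — allele model, bisulfite chemistry, cohorts
- `src/epiallele/align.py` — bisulfite-asymmetric semi-global aligner
- `src/epiallele/calling.py` — demultiplexing, pattern calling, QC, summaries
- `src/epiallele/mixture.py` — gate, fraction estimator, shift model, flags
- `src/epiallele/stats.py` — ANOVA, Holm-corrected t-tests, letter codes
- `src/epiallele/pipeline.py`, `cli.py` — orchestration and `epiallele` CLI

See `docs/methods.md` for the model, its assumptions, and numerical choices.
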