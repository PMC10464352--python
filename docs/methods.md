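# Methods

This note documents the model assumptions, parameter choices, numerical
decisions, and known limitations of the `mutprev` pipeline.

## Assay model

Four amplicons are modeled: three *TP53* exon targets (TP53.5/6/7) whose
analyzable spans sum to 193 bp, and one SCGB1A1 target used for competitive
molecule counting.  Each target's synthetic internal standard (IS) is the
native sequence with substituted dinucleotides approximately every 50 bases.
Excluded from variant analysis are the primer spans and each substituted
dinucleotide position plus one flanking base on either side; the remaining
positions form the analyzable mask.  Coordinates are 0-based half-open
internally and 1-based in VCF output.

The SCGB1A1 IS is an external complexity calibration ladder (ECCL) of four
rungs (default 50,000 / 5,000 / 500 / 50 molecules).  Lower rungs carry an
additional rung-identifying dinucleotide so that reads can be attributed to
a rung bioinformatically; rung 1 (IS1) is the calibrator in the molecule
formulas.  The exact rung concentrations and the minimum-read threshold
(default 10) are configuration, not constants.

## Read classification

A read is assigned to a sample by exact barcode match (optionally ≤1
mismatch; barcodes are generated with pairwise Hamming distance ≥3), to a
target by its 5′ primer (≤2 mismatches), and to NT or IS by vote over the
dinucleotide sites: IS iff a strict majority of sites carry the IS allele,
NT iff a strict majority carry the reference, ambiguous otherwise (counted,
excluded from pileups).  The vote rule is this package's choice; with four
sites and per-site error e, the NT→IS misclassification probability is
bounded by C(4,3)e³, negligible at realistic error rates and verified by
simulation at inflated rates.  Alignment is replaced by primer-anchored
positional decoding, which is exact for fixed-length substitution-only
amplicons; a SAM import path accepts externally aligned reads.

## Molecule counting and down-sampling

If the most dilute ECCL rung yields at least the minimum reads, the library
captured the full ceiling (top rung nominal, 50,000 by default); otherwise
the ceiling is scaled down by (lowest rung nominal / deepest passing rung
nominal) — one 10-fold ladder step per failing rung.  Molecule counts then
follow the two competitive formulas (SCGB1A1 NT from the NT/IS1 read ratio;
per-target NT from the target/SCGB1A1 NT read ratio).  The second formula is
implemented as a multiplication by SCGB1A1 NT molecules — the only
dimensionally coherent reading; `formula_literal=True` preserves the
division variant for audit.

NT pileups are thinned to molecule scale by per-position multivariate
hypergeometric draws (seeded, reproducible), which preserves expected allele
fractions and is equivalent to down-sampling read records for
substitution-only analysis while costing O(positions) instead of O(reads).
Sample QC fails on ECCL failure, on a calibrator-read floor (default 1,000
IS1 reads), or on a per-target molecule floor (default 10,000); all QC
decisions carry a reason string.

## Variant calling

The limit of blank for each analyzable position-substitution is the IS
variant-read fraction, floored at 0.5/depth when zero variant reads were
observed (a zero blank rate would make any observation significant; the
half-count floor is the standard continuity choice).  The Poisson exact test
is the one-sided upper tail P(X ≥ k), X ~ Poisson(LOB × molecule depth),
computed by exact summation (`scipy.stats.poisson.sf`).  A two-sample
conditional-binomial variant (NT count vs IS count given the total) is
available behind a switch; the one-sample form is the default.  Calls
require p below 0.05/579 (Bonferroni over 193 positions × 3 substitutions),
strictly more than 5 supporting molecules, and VAF strictly above 10⁻⁴.
Per-subject mutation uniqueness is the distinct (target, position, alt)
triple.

The plug-in λ treats the measured LOB as known, which is adequate only when
IS read depth is large relative to the NT molecule count; at the default
simulation depth (60 reads/molecule, i.e. ~3×10⁶ IS reads/target) the LOB's
relative sampling error is small and the family-wise false-call rate stays
inside the Bonferroni budget of 0.05 (the null study below checks exactly
this).  Shallow libraries make the plug-in test anti-conservative; the
two-sample variant is the robust alternative there.

## Biomarker statistics

Prevalence = unique clones / 193 bp.  Group comparisons use tie-corrected
Kruskal–Wallis (χ² reference) and the two-sided Wilcoxon rank-sum normal
approximation with tie-corrected variance and 0.5 continuity correction.
AUC is the Mann–Whitney probability with half-credit for ties; its 95% CI
uses the DeLong variance applied on the logit scale, which respects (0,1)
and is better calibrated than the raw-scale Wald interval for small tied
samples (the AUC recovery study below checks the coverage).  The Youden
cutoff maximizes sensitivity + specificity − 1 under the rule "positive iff
score ≥ cutoff", resolving ties to the smallest cutoff.  Paired AUC
comparison uses a stratified bootstrap of the AUC difference (default
B = 2,000, seeded; paired DeLong available by flag).

The combined biomarker is a fixed-coefficient logistic model,
Xβ = −3.165853 + 29.31218·PRS + 0.5462315·TP53.  PRS is a demographic risk
probability on [0,1].  The TP53 term enters as the mutation *count*
(prevalence × 193) by default: with the coefficient ~0.55, a count scale
(0–19 in the packaged cohort) moves the linear predictor by up to ~10,
whereas the prevalence scale (≤0.097) would make the term inert.  The
packaged cohort's risk-score column carries no per-subject values, so CBM
analyses require an explicit `prs_column` mapping and are otherwise skipped.

Signature classes are reported on the pyrimidine strand (C>A tobacco; C>T,
T>C age; everything else "other").  Per-class enrichment uses Kruskal–Wallis
on per-subject class prevalence with Bonferroni over the classes actually
observed.  Hotspot enrichment is a two-sided Fisher exact test on the
(hotspot yes/no) × (case/control) call table; hotspot sites are a
user-supplied BED, not a database lookup.

## Synthetic-data generator

The generator realizes the cohort at the level the statistics assume:
subjects carry Poisson numbers of mutation clones (group-specific means,
defaults 159/30 ≈ 5.3 for cases and 33/29 ≈ 1.14 for controls, matching the
packaged cohort's totals), placed uniformly over analyzable sites with
substitution classes drawn from a tobacco/age-weighted spectrum (C>A 0.45,
C>T 0.30, T>C 0.15, other 0.10) and clone VAFs log-uniform on the assay's
working window 10⁻⁴–10⁻².  Each target loads 50,000 NT and 50,000 IS
molecules; every molecule is duplicated into a zero-truncated Poisson number
of reads (default mean 60, consistent with ~26M reads/sample over ~4×10⁵
loaded molecules); substitution errors hit every base of every read i.i.d.
from a shared 4×4 matrix (default 10⁻⁴ per substitution, giving an LOB at
the 0.01%-VAF working scale).

Reads are represented sparsely (template + explicit per-read error records),
which is exactly equivalent to materialized reads for classification and
pileups — a round-trip test asserts bit-identical pileups against the
literal gzip FASTQ path.  Not simulated: indels, quality-score realism,
paired-end overlap, flow-cell artifacts, PCR efficiency bias between NT and
IS.  Consequently, passing tests demonstrate the statistical machinery under
the assay's stated assumptions, not robustness to alignment artifacts or
context-dependent error spectra in real data.

## Validation studies and problem sizes

* **Null study** — 20 zero-mutation samples at full scale (50,000
  molecules, 60 reads/molecule); ≥95% of samples must yield zero calls.
* **Detection study** — 100 single-subject samples at full scale with all
  clone VAFs ≥ 10× LOB; clone-level sensitivity ≥0.95 and molecule-count
  relative bias <2% (the read-ratio estimators are consistent; bias is
  O(1/n)).
* **AUC recovery study** — 100 cohorts of 30 cases / 29 controls whose
  clone-count means (3.3287 vs 1.1379) separate with true AUC exactly
  0.850; the DeLong logit CI must cover the truth in ≥90% of replications.
  This study runs on 2,000-molecule libraries at 25 reads/molecule with
  clone VAFs ≥0.8%, so detection is effectively certain and the >5-molecule
  filter makes false calls negligible; the statistical
  content is the sampling behavior of the AUC estimator, with the pipeline
  still exercised end-to-end.

## Known limitations

* The LOB plug-in PET is anti-conservative for shallow libraries (above).
* Clones are treated as independent point mutations; phasing across
  positions and multi-nucleotide variants are out of scope.
* The ECCL adjustment is a step function of the deepest passing rung;
  between-rung complexity is not interpolated.
* Hotspot and consequence annotation depend entirely on user-supplied site
  lists and codon contexts; packaged panels use synthetic reference
  sequences, so their translations are structural placeholders, not *TP53*
  codons.
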