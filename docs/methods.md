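# Methods

This note documents the statistical procedures implemented in `aneucomp`,
the synthetic cohort the tests run against, and the design choices made
where the method left room.

## Chromosome calling and recurrence testing

Arm scores take values in {−1, 0, +1, missing}. Whole-chromosome states
require arm agreement for chromosomes 1–12 and 16–20 and take the q arm for
the acrocentric chromosomes 13–15 and 21–22; conflicting or missing arms
produce an undetermined (NA) state, and samples with an NA state for a
chromosome are excluded from that chromosome's analyses. Only autosomes are
modelled.

Recurrence uses, for every (cancer type, chromosome, direction), the 2×2
table {this type, all other types} × {altered in this direction, not
altered}. This one-vs-rest construction is the minimal reading of testing
"within each cancer type against random expectation"; amplifications and
deletions are tested separately because they form separate case lists
downstream. Pearson chi-square is computed without continuity correction so
that the reported standard residual (O − E)/√E is the raw Pearson component;
tests with any expected cell below 1 are skipped. Holm correction runs
across all (type, chromosome, direction) tests; cases need adjusted
p ≤ 0.05 **and** residual ≥ 2. Co-amplification testing conditions on each
amplification case's cancer type, requires a positive residual, and retains
pairs at Holm-adjusted p strictly below 0.01.

## Preprocessing and differential calling

FPKM → TPM normalizes each sample to 10⁶ (features that are zero everywhere,
and an optional mitochondrial ID list, are removed first). Quantile
normalization maps each column onto the mean order-statistic profile, with
tied values receiving interpolated reference values, followed by
log2(x + 1); ranks within a column are preserved exactly.

The differential test is a two-sided Mann–Whitney rank-sum test per feature
(SciPy's implementation: exact for small untied samples, normal
approximation with tie correction otherwise). Transcript mode adjusts with
Benjamini–Hochberg and calls significance at adjusted p < 0.1; when fewer
than 250 protein-coding features pass, calls fall back to raw p < 0.05 so
downstream enrichment tests have enough genes. Protein mode uses raw
p < 0.1 with no adjustment and requires at least 3 non-missing values per
group per feature; missing values are excluded pairwise, never imputed.
Constant features get p = 1 by convention and are flagged. Direction comes
from the median difference (aneuploid − diploid); a log fold change of
means is reported alongside for transcripts. The <250 fallback is applied
to transcripts only; protein mode always uses the relaxed raw cutoff.

## Co-complex analyses

The complex database is a GMT-backed map complex → subunit set with
functional-term labels; a membership index supports partner lookup,
promiscuity (> 5 complexes) and co-occurrence frequency (complexes
containing both over complexes containing either). Association tests are
2×2 chi-squares over the universe of proteins quantified on non-aneuploid
chromosomes for the case — the most conservative universe consistent with
the procedure. Only direction-consistent aneuploid proteins (increased for
amplifications, decreased for deletions) seed the pair set.

Correlations are Spearman with average-rank ties, per cancer type, over
pairwise-complete samples (≥ 3); pooling keeps the maximum **signed** rho
per unordered pair (an absolute-maximum variant is available via
`pool_correlations(..., absolute_max=True)`; signed is the default because
"maximum correlation" reads most naturally as the largest value).
Group contrasts (co-complex vs not, aggregation-prone vs not, promiscuous
vs not, co-occurrence by correlation class with a ±0.2 non-correlated band)
are two-sided rank-sum tests on rho distributions.

## Network randomization

The PPI graph is undirected and simple; self-loops are rejected at parse
time. Cross-set interaction counts treat an edge with one endpoint in each
set once, including edges inside the intersection. The null replaces every
member of the aneuploid set by a distinct protein sampled uniformly from
its log₂ degree bin (its own identity excluded; bins widen to adjacent bins
when exhausted, up to a hard limit), keeping the partner set fixed, and
p = (1 + #{null ≥ obs})/(N + 1). The pseudocount avoids zero p-values; a
raw k/N variant exists behind a flag. Because null counts are integers,
this estimator is conservative when the count distribution is narrow: the
tie mass at the observed value is included in the upper tail. Calibration
checks therefore use graphs dense enough that counts spread over many
values, and redraw both protein sets per repetition so p-values are i.i.d.
under the null.

## Regulatory attribution

Methylation: per gene, the mean promoter beta value across aneuploid and
across diploid samples; the paired per-gene differences enter a Wilcoxon
signed-rank test (a pooled rank-sum variant is available). Run separately
for up- and downregulated gene sets; a case is "consistent" when
downregulated genes are hyper-methylated or upregulated genes are
hypo-methylated in aneuploid samples at p < 0.05. Each gene maps to its
most upstream promoter, resolved at generation time.

TF targets: observed = DE other-chromosome genes hit by targets of DE
aneuploid-chromosome TFs; the null redraws size-matched TF sets (100
iterations by default) from the TF universe *excluding* the observed set —
the randomization replaces the DE TFs, so redrawing them would make the
extreme-case p floor of 2/(N+1) unreachable. The two-tailed empirical p
uses pseudocounts with mid-p tie handling (ties contribute half to each
tail): without mid-p the discrete target-count null makes the test visibly
conservative at N = 100.

Ubiquitination: per-protein total site counts; groups are all quantified
proteins, complex subunits, and partners from top-positive (rho ≥ 0.4) and
top-negative (rho ≤ −0.4) correlation rows, compared pairwise by rank-sum.
Proteins missing from the ubiquitination source are removed, not
zero-filled.

## Functional enrichment

Top pairs are the 20 strongest positive and 20 strongest negative
correlations (sides are sign-restricted; short sides are truncated and
flagged); the background is all pairs with rho in [−0.2, 0.2]. Per term, a
2×2 chi-square of {top, background} × {annotated, not} over the complexes
of the partner proteins; the enrichment score is (O − E)/√E of the
top-annotated cell; significance is raw p < 0.05 with no multiple-testing
correction (a BH option exists but is off by default, matching the
per-case, small-term-universe setting). Sensitivity variants re-run after
removing ribosomal proteins or complexes with more than 10 subunits and
report the Jaccard concordance of significant terms. Selection runs per
case before pooling.

## Deviation score and survival

The top 30 strongest (|rho| by default; "strongest" is read as magnitude)
amplification-case pairs give per-pair OLS models of partner on aneuploid
protein abundance over all pairwise-complete cohort samples. A sample's
deviation score is the mean absolute residual over the models that cover it
(at least half the models by default); residuals are computed in-sample,
matching the construction, with an out-of-fold option for methodological
comparison.

The survival cutpoint maximizes the absolute standardized log-rank
statistic over all observed scores inside the 10–90% quantile window
(an exhaustive scan; the statistic uses the hypergeometric variance and is
cross-checked against lifelines). The low group is score ≤ cutpoint.
The reported p is the naive log-rank p at the selected cutpoint; because
cutpoint selection makes the naive p anti-conservative, a
selection-adjusted permutation p (default 1000 permutations) is available
via `survival_stratify(..., n_permutations=...)`. Degradation-machinery
coupling is the rank-sum comparison of Spearman correlations between
protein abundance and deviation scores, degradation set vs all proteins,
for all samples and for amplification/deletion carrier subsets.

## The synthetic cohort

The generator emulates the shape of a pan-cancer proteogenomic cohort; its
defaults define the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| n_samples_per_type / n_cancer_types | 100 / 4 | cohort size |
| n_genes / n_chromosomes | 1000 / 10 | genome scale (desk-scale stand-in for ~19k genes / 22 autosomes) |
| planted_aneuploidies | chr1 amp in CT1, chr2 del in CT2, carrier fraction 0.6 | recurrent alterations |
| background_alteration_rate | 0.05 | sporadic whole-chromosome changes |
| dosage_effect / attenuation | 1.0 log₂FC / 0.5 | transcript effect and its protein-level damping |
| compensation_rho | 0.6 | target partner Spearman correlation |
| noise_sd (transcript, protein) | 0.5, 0.5 | log-scale measurement noise |
| survival_hazard_ratio | 3.0 | hazard multiplier across the planted deviation range |
| protein_missing_rate | 0.10 | missing-completely-at-random protein values |

Transcripts are log-normal with dosage shifts on altered chromosomes,
rescaled to TPM (columns sum to 10⁶). Proteins carry the attenuated dosage
effect. Compensated partners are constructed from the standardized
aneuploid-protein profile with a Pearson coefficient chosen via
r = 2·sin(πρ/6) so the *Spearman* correlation hits its target (verified by
Monte-Carlo at 200 samples: mean 0.609, all pairs within ±0.1 of 0.6).
Compensated aneuploid proteins are marked aggregation-prone and their
partners draw ubiquitination counts at the elevated rate; matched null
pairs (co-complex, rho 0, non-prone) and a few anti-correlated pairs
provide the contrast groups. Each planted pair forms a dimer complex so it
contributes exactly one correlation pair; random complexes (sizes 3–8) and
a handful of high-membership hub proteins provide background membership and
promiscuity structure. The PPI graph is Erdős–Rényi plus planted
aneuploid-partner edges. Per-sample deviation magnitudes are uniform on
[0, 1]; they scale partner residual noise (with the pooled correlation
re-solved so it stays on target), drive degradation-protein abundance, and
enter an exponential survival model with log-hazard linear in the
deviation; censoring is uniform administrative. Survival is generated for
overall and disease-free endpoints (median baselines 36 and 24 time units).

What the generator does **not** emulate: real copy-number segmentation,
batch effects, platform-specific normalization artifacts, correlated gene
co-expression programs, informative missingness, or realistic complex-size
and degree distributions. Passing recovery tests therefore demonstrates
that the statistical machinery detects the signals it is designed for at
realistic effect sizes and sample counts — not that real-data effect sizes
match the planted ones.

## Numerical choices and degenerate inputs

Chi-square tables with a zero margin are skipped; expected cells below 1
skip the test with a warning. Constant vectors are dropped from
correlation and regression steps. Ties in top-pair selection break on pair
IDs so runs are deterministic. All pipeline randomness flows from one seed
through per-stage child streams (`numpy.random.SeedSequence.spawn`), so
stage reordering cannot silently change results. Problem sizes in the test
suite and acceptance script (cohorts of 40–150 samples per type, 80–900
genes, 100–1000 randomization iterations) were chosen so each recovery
check runs in seconds at the planted effect sizes.

## Known limitations

- The one-vs-rest recurrence table is one possible reading; a full
  type × status table is not implemented (the spec of the chi-square in the
  source procedure is ambiguous) beyond the configurable option surface.
- The naive log-rank p after cutpoint selection is anti-conservative by
  design; use the permutation-adjusted option for inference.
- Pipeline-level partner-enrichment residuals are modest at desk scale
  (hundreds of proteins) because the raw p < 0.1 protein rule admits ~10%
  false positives into the differential sets; this mirrors the method, not
  a defect of the implementation.
- No stage caching: the pipeline is fast enough at supported scales that
  deterministic re-runs replace a cache.
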