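# Methods

## Scope and data model

The toolkit operates downstream of allele-specific read counting: its
inputs are GATK ASEReadCounter tables (one per sample per strand), VCF
genotypes per sample (phased heterozygotes carry parental information), an
optional maternal VCF per sample, and a GTF. External coordinates stay
1-based as printed; all interval arithmetic is 0-based half-open
internally and converts at the boundary. The unified count table is keyed
by (sample, contig, position, strand); ingesting the same file twice is an
integrity error rather than silent duplication. ASEReadCounter's
`totalCount` can include bases its own quality filters later remove, so a
row whose total disagrees with `refCount + altCount` is repaired to the
sum with a warning.

## Union-exon annotation

All isoform exons of a gene are merged into maximal sorted intervals;
book-ended exons merge because they are contiguous transcribed sequence.
A SNP is annotated to every gene whose union exons contain it (one output
row per (SNP, gene) pair — no best-gene heuristic, no silent loss; records
matching nothing go to a side table). In strand-specific mode a record
only joins genes on its own strand. SNPs in introns are not assigned to
the gene: containment is defined on union exons only. Merging is validated
against a per-base membership oracle and is idempotent.

Phase convention: whether the first allele of `a|b` is paternal is not a
property of the VCF but of the phasing pipeline, so it is an explicit
switch (`first_is_paternal` by default). Flipping the convention
complements every paternal allele frequency, which the tests assert
exactly.

## Contamination estimation

At a homozygous site, reads carrying the opposite allele must come from
another individual or from sequencing error. Per sample we report the
unweighted mean over sites of the non-alternative-allele frequency at
hom-alt sites (`est_homalt`) and of the non-reference-allele frequency at
hom-ref sites (`est_ref`). A mean of per-site frequencies, rather than a
pooled count ratio, keeps one very deep site from dominating; duplicating
every site leaves the estimate unchanged, which is asserted. `other_bases`
join both numerator and denominator because contaminant reads need not
carry the on-panel alternate base. Strands are pooled per site first —
contamination is not strand-specific. Defaults: `min_depth = 10` reads per
site, `min_sites = 5` sites per estimate; below these the estimate is
undefined ("when measurable") and the sample passes the contamination
filter by default. Sites where the read data contradict the genotype class
are not used.

For maternal contamination (placental tissue), the same non-reference
frequency is averaged per (sample, gene) over offspring hom-ref sites
inside the gene's union exons where the mother's genotype is het or
hom-alt, attributing non-reference reads there to maternal tissue.

## Filtering

Retention requires `total_count >= 10` per SNP×sample×strand row and, for
samples with any measurable estimate, max(defined estimates) strictly
below 5%. The strict bound means a sample at exactly 5.0% is dropped. For
the PofO subset, unphased rows are additionally removed. Dropped rows are
attributed to the first failing rule in the fixed order (count,
contamination, phasing), making the accounting deterministic; retained
plus dropped always partitions the input, and filtering is idempotent on
its own output. Gene-level contamination estimates are reported but do not
drop rows by default (a configurable hook, `drop_unmeasurable_contamination`,
covers the stricter reading).

## The PofO regression

Each (subject, SNP) contributes a ref row and an alt row with
$X = \pm 1/2$, $Z = \pm 1/2$ (paternal/maternal) and $Y$ the allele
counts. By default ref/alt counts are summed across strand records per
(subject, SNP) before row construction — the test is per gene, not per
strand — with `combine_strands=False` available. Zero counts are retained
as rows (informative under the Poisson likelihood) as long as the SNP row
passed the read filter.

The SNP indicator matrix $U$ is reduced to $V$, the left singular vectors
with $\sigma_l \ge 0.01\,\sigma_{\max}$ ("at least" read inclusively; a
value exactly at the threshold is kept, with a $10^{-12}$ relative guard
against floating-point representation of the product). Because every row
of $U$ sums to one, keeping all singular vectors makes the $V$ block span
the constant column; rank reduction is therefore structural, not
incidental. It is resolved by a greedy left-to-right independence scan
over the columns `[1, Z, X, V, V·X]` (modified Gram–Schmidt with one
re-orthogonalisation, relative tolerance $10^{-8}$), so redundant $V$ or
$V{\cdot}X$ columns are dropped and the intercept, $Z$ and $X$ survive
unless the design genuinely cannot identify them — in which case the gene
is untestable (`po_unidentifiable`). The estimate of `po` does not depend
on which redundant column is removed.

Point estimates are Poisson maximum likelihood (quasi-Poisson shares
them), by iteratively reweighted least squares started from
$\eta = \log(y + 1/2)$, converged at relative coefficient change
$< 10^{-10}$ or declared non-convergent after 100 iterations; the linear
predictor is clipped at $\pm 30$ to guard overflow during early
iterations. Tests verify the estimates against a generic Newton/trust-region
optimizer of the Poisson log-likelihood to $10^{-6}$ on random small
designs.

The covariance of the coefficients is the clustered sandwich over
subjects, $B \left(\sum_g s_g s_g^{\top}\right) B$ with $B$ the inverse
Fisher information and $s_g$ the per-subject score; it equals statsmodels'
cluster-robust GLM covariance (without small-sample scaling) to $10^{-6}$
in tests. The small-sample factor is configurable: `cr1` ($G/(G-1)$,
default) or `none`. Quasi-Poisson dispersion is *not* applied to the
standard error — the clustered sandwich is already robust to
overdispersion and within-subject correlation — but the Pearson dispersion
is reported as a diagnostic. `po_z` is the raw ratio `po / se(po)`;
thresholding against a normal or $t_{G-1}$ reference is left to the
classification cuts, which default to $|po| > 3$ ("strong", implying at
least $e^3 \approx 20.1$-fold allelic imbalance) and $|po_z| > 3$
("significant").

Testability is explicit: ≥ 3 subjects (clusters), ≥ 1 phased SNP, $Z$
retained after rank reduction, and IRLS convergence; anything else yields
an untestable result with a reason code rather than an exception.

Exact invariances asserted by the tests: flipping every paternal/maternal
label negates `po` and `po_z`; swapping ref/alt labels (with the paired
counts) leaves `po` unchanged.

## The simulator

The generator emulates the data the ingestion layer expects, with the mean
structure of the regression itself: per heterozygous (subject, SNP), the
paternal-allele mean is $\exp(\mu_0 + d_j + e_i + po/2 + b_j x_{pat})$ and
the maternal mean its mirror image, where $\mu_0 = \log 25$ sets the
median total depth near 50 (comfortably above the 10-read filter),
$d_j \sim N(0, 0.4)$ is a per-SNP depth offset, $e_i \sim N(0, 0.3)$ is a
subject-level random effect shared across all of a subject's rows —
precisely the within-cluster correlation the sandwich must absorb — and
$b_j \sim N(0, \sigma_b)$ is a per-SNP genetic-ASE effect entering through
the $\pm 1/2$ ref/alt coding ($\sigma_b = 0.5$ by default). Counts are
Poisson or negative binomial with size $\theta$; as $\theta \to \infty$
the draws converge to Poisson (asserted at 5% on the variance/mean ratio).
Heterozygosity is Bernoulli(0.5) per (subject, SNP) and the paternal
allele is ref with probability 0.5.

Homozygous panel sites are placed inside the synthetic genes' exons (so
gene-level maternal contamination is computable), 200 per sample by
default, with clean counts carrying only the genotype's allele — with zero
injected contamination and no sequencing-error model, every contamination
estimate is exactly 0. Contamination injection relabels a
Binomial(total, c) subset of each site's reads according to the
contaminant's genotype profile, removing the relabelled reads
hypergeometrically from the existing composition so totals are conserved.
The contaminant is the mother, drawn hom-ref at offspring hom-alt sites
and hom-alt (with probability 0.5, else hom-ref) at offspring hom-ref
sites, so the injected fraction maps one-to-one onto the opposite-allele
frequency at informative sites; a heterozygous contaminant would
contribute c/2 per site and is deliberately not drawn at panel sites.
Counts are emitted to the forward or reverse strand file according to the
host gene's strand, so the strand-matching join is exercised end to end;
an unstranded mode writes a single file per sample. All output is
byte-identical under a fixed (config, seed).

What the simulator does not model: reference mapping bias, read-level
errors and base-quality structure, isoform-specific expression, linkage
between SNPs beyond the shared subject effect, and genotyping error.
Passing recovery and calibration tests therefore demonstrates correctness
of the statistics under the stated generative assumptions, not robustness
to alignment artefacts — those must be handled upstream of the counts.

## Validation problem sizes

The statistical suite uses: 50 random small designs (≤ 30 subjects, ≤ 12
SNPs) for oracle equivalence at $10^{-6}$; 500 null genes (50 subjects, 4
SNPs, subject SD 0.3, genetic-effect SD 1.0, so per-SNP effects range to
roughly ±2–3 on the log scale) for calibration of the $|po_z| > 3$ rate
against the nominal $2\Phi(-3) \approx 0.0027$ within ±0.02; 200 genes per
true effect in {0.5, 1, 2} for recovery of the mean `po` within ±0.1; and
10-sample datasets with 200 homozygous sites per sample for contamination
recovery (±0.01 sample-level on the hom-alt estimator, ±0.02 gene-level,
exact zero at c = 0). These sizes give Monte-Carlo error comfortably
inside each tolerance while keeping the whole suite around ten seconds.

## Known limitations

- Isoform-level ASE is out of scope; annotation is union-exon only.
- The PofO test needs phased heterozygous SNPs; unphased data stop at
  annotation and contamination estimates.
- Multi-allelic sites and indels are skipped at genotype parsing.
- `po_z` is reported against no particular reference distribution; with
  very few clusters the usual caveats about cluster-robust inference
  apply (the `cr1` factor mitigates but does not remove small-G bias).
- Gene-level contamination is an average over qualifying sites; with a
  heterozygous contaminant it underestimates the contaminated fraction by
  up to a factor of two per site.
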