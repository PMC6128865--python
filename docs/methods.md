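# Methods

`spliceoscope` analyses bulk RNA-seq splice-junction data from cohorts of
myelodysplasia patients stratified by spliceosome-gene genotype (SF3B1,
SRSF2, U2AF1, ZRSR2 hotspot mutations). This note documents the models,
the statistics, the synthetic-data generator, and the numerical choices;
every number quoted here is computed by the test suite or
`scripts/acceptance.py`.

## Event model and PSI

Splicing events are typed against the annotation: cassette exon, alt 5'
and alt 3' splice site (alternative site within 500 nt of the annotated
one, signed offset in transcript orientation, negative = upstream),
intron retention (annotated introns only), mutually exclusive exons, and
alternative first/last exons (annotation-declared terminal exons with
junction support). A novel junction is assigned to at most one event via
the precedence alt 5'/3'SS (shared annotated anchor site, unannotated
alternative site) > cassette exon (both sites annotated, one exon
skipped) > mutually exclusive > terminal — so one junction never feeds
two events. Adjacent cassette candidates collapse to a mutually-exclusive
event only when no observed junction joins the two exons. "Coordinate
cassette exons" (several exons skipped together) are not detected.

PSI (percent spliced in) is the fraction of reads supporting the
alternative isoform:

    PSI = 100 · inclusion / (inclusion + exclusion)

with junction reads summed over each evidence set, undefined when the
total is below `min_reads` (default 5, applied per sample). For intron
retention, inclusion evidence is the mean of the two exon–intron boundary
counts and exclusion is the spliced junction; boundary evidence is
required because length-normalized intron body coverage cannot be
reconstructed from junction tables. All coordinates are 1-based inclusive
and junctions are stored as intron extents (first/last intronic bases),
strand-qualified.

## Differential splicing

Per event and cell fraction, PSI is compared between mutation carriers
and samples without any splicing-factor mutation using Welch's two-sided
t-test (variances not assumed equal; Welch–Satterthwaite df). Events need
PSI defined in ≥3 samples per group; events with two zero-variance groups
are excluded with a reason code rather than given p = 0. No ΔPSI floor is
applied at the testing stage. BH adjustment is per (comparison ×
fraction) family; the significance cutoff is q < 0.01, and an event is
"associated" with a mutation when significant in at least one fraction.
PSI fold changes use a 1-percentage-point pseudocount on both means.

## Transcript consequences

Each event is applied to its anchor transcript — the longest-CDS
transcript of the gene (a design choice; per-transcript labels can be
produced by calling the classifier with any transcript) — to reconstruct
the alternative mRNA. Keeping the annotated start codon, the classifier
assigns one of five classes:

* **non_coding** — the nucleotide sequence between the start codon and the
  annotated stop is unchanged (e.g. a 5'UTR alt 3'SS);
* **alt_first/last_coding_exon** — the start/stop codon's exon is removed
  or replaced;
* **truncating / frameshift** — net CDS length change ≢ 0 (mod 3); labelled
  truncating regardless of where a new stop falls;
* **truncating / PTC_in_frame** — in-frame length change with a new stop
  codon strictly 5' of the annotated stop;
* **non_truncating** — in-frame change with no premature stop.

The 50-nt exon-junction rule (PTC more than 50 nt upstream of the last
junction) is emitted as an auxiliary annotation only; NMD sensitivity is
determined empirically from CHX data. The classifier is validated two
ways: exact recovery of the generator's constructed labels, and 100%
class agreement with a brute-force oracle that fully translates both
isoforms and compares protein products (>1,000 events, both strands).

## NMD assessment

Paired cycloheximide (CHX)-treated/untreated samples from the same
patient quantify NMD: CHX blocks translation and thereby NMD, rescuing
PTC-bearing isoforms. The default test is Cochran–Mantel–Haenszel over
per-pair 2×2 tables (inclusion/exclusion × treated/untreated), without
continuity correction — calibration verified by simulation; on a single
stratum the statistic equals the Pearson chi-square times (n−1)/n. A
paired t-test on PSI is reported alongside. An event is `nmd_sensitive`
when q < 0.01 (BH over events) and the treated mean PSI exceeds the
untreated mean (two-sided test plus sign requirement). Events detected
(PSI defined and > 0) in at least one treated sample but in no untreated
and no primary sample are `chx_specific` — completely degraded under
physiological conditions.

## Canonical-transcript expression

Gene counts are adjusted to estimate canonical-transcript abundance: for
each gene with a truncating event, the event with the highest PSI fold
change versus controls is selected and counts are multiplied by
(100 − PSI)/100 per sample (rounded to integers for NB support; samples
with undefined PSI are left unadjusted). Adjusted counts are normalized
by weighted trimmed mean of M-values (TMM: reference sample by upper
quartile, 30%/5% M/A trims, inverse-variance weights, factors scaled to
geometric mean 1; verified against the published reference implementation
to <5%), filtered to genes with >1 CPM in ≥6 samples, and tested with a
negative-binomial GLM likelihood-ratio test (log link, offset =
log(library size × TMM factor), mutated-vs-control coefficient), BH at
q < 0.01. The NB dispersion is a per-gene method-of-moments estimate
shrunk 50% (log scale) toward a binned median trend — a deliberately
simple estimator whose type-I error is calibrated by simulation
(0.05 ± 0.015 on null genes at n = 30/40).

## Motif and sequence analysis

SRSF2 binds the exonic splicing enhancer consensus SSNG (S ∈ {C,G}); P95
mutants gain CCNG and lose GGNG affinity. Exons are split into four
segments of near-equal length (remainders go to the 3'-most segments),
overlapping matches are counted and assigned to the segment containing
their first base, and per-segment densities of differentially spliced
exons are divided by constitutive-exon densities; 95% CIs come from the
normal approximation of the log ratio of rates (SE² = 1/x_t + 1/x_b).

Acceptor context: the −3 position is the last intronic base before the
acceptor AG (standard yAG convention) and +1 the first exonic base;
non-AG acceptors are flagged non-canonical. U2AF1 S34 and Q157 mutants
alter recognition at −3 and +1 respectively. Intron features (length, GC)
are compared with the two-sided Mann–Whitney U test.

## Target filtering

Functional targets must be significant in the primary cohort (q < 0.01),
recapitulated in isogenic clones when clone data exist (Welch p < 0.05,
3 vs 3 clones, with group-mean direction matching the primary cohort —
the direction rule uses group means, not unanimity), and quantitatively
substantial: mutant mean PSI > 2 × control mean (1-pp pseudocount) and
>10% in primary or CHX-treated samples (the CHX clause admits targets
visible only after NMD inhibition). "Almost specifically detected" is
interpreted as mutant mean ≥ 10 × control mean with the same pseudocount,
since the denominator is otherwise undefined at control PSI 0. The
expression–PSI association regresses PSI on log2 expression (Gaussian
identity link) per event and pooled with event fixed effects (Wald p on
the expression coefficient), restricted to samples passing a sample-sheet
purity column. Mutation mutual exclusivity uses the two-sided Fisher
exact test by the point-probability method (matches exhaustive
enumeration for all tables with N ≤ 200) with a Haldane 0.5 correction
for the odds ratio when a cell is zero.

## Synthetic-data generator

The generator emits, from one seed, a byte-deterministic reference
(FASTA + GTF), mutation-stratified cohorts, CHX pairs, isogenic clones
and a complete truth ledger. It emulates:

* **Gene models** — 5–8 exons of 90–240 nt with CDS and UTRs; ~30% of
  genes on the minus strand. Exonic sequence (UTRs included) is drawn
  from the stop-free codon pool so base composition is homogeneous across
  exons — fully coding and UTR-containing exons would otherwise differ
  slightly in C content and bias motif ratios.
* **Intron regimes** — retention-prone introns are log-normal with median
  0.41 kb (log-σ 1.43, matching an IQR of 0.16–1.1 kb) and GC 54%;
  constitutive introns median 1.8 kb (log-σ 1.71, IQR 0.58–5.8 kb) and
  GC 43%. All introns are GT…AG with a configurable −3 base profile
  (T-rich by default; A/C-rich at planted cryptic acceptors).
* **Cohorts** — default design: one fraction with 30 SF3B1-, 15 SRSF2-,
  8+8 U2AF1 (S34/Q157)-mutated and 40 control samples. Junction counts
  are beta-binomial: inclusion ~ Bin(T, p), p ~ Beta(μ, ρ) with
  intraclass correlation ρ = 0.02 (biological replicates are
  overdispersed; required for honest t-test calibration) and T ~
  Poisson(depth 100). At baseline PSI ≈ 40–50% this yields a within-group
  SD of ~8 percentage points at depth 175 — the regime in which a
  10-point shift is detectable at α = 0.001 with power ≈ 0.95 at n=30/40.
* **Planted effects** — SF3B1-specific alt 3'SS spikes (baseline ~1%,
  +25 points, mostly truncating), a broad mild intron-retention decrease
  (−3 points), cassette shifts for SRSF2 (±15) and U2AF1 (+12), and a few
  terminal-exon events. Consequence truth labels are enforced by
  construction: in-frame TAA placement for PTC archetypes, bounded
  resampling for stop-free inserts, and a reading-frame scan on final
  sequences for geometry-determined sites.
* **NMD** — reads of truncating isoforms survive physiological NMD with
  probability d (inclusion reads thinned binomially; exclusion reads
  untouched), so the observed aberrant fraction is exactly
  d·ψ/(d·ψ + 1 − ψ); CHX treatment sets d → 1 within a pair that shares
  one underlying PSI draw. d = 0 gives CHX-specific events.
* **Expression coupling** — gene counts are NB (dispersion 0.1, log-normal
  base means) with mean scaled by (1−ψ) + ψ·d for genes whose truncating
  event couples splicing to expression, so canonical-transcript
  downregulation follows mechanistically from splicing plus NMD.
* **Motif composition** — exon classes (included/skipped/constitutive)
  carry per-quarter CCNG/GGNG planting rates (default 0.008/nt, doubled
  in the 3'-most quarter of the affected class). Background SSNG matches
  are scrubbed first and planted instances are spaced and flank-cleaned
  so each contributes exactly one match: realized densities are Poisson
  at the configured rates, which is what makes the ratio-of-rates CI
  calibrated (~95–97% observed coverage). Instance-spacing collisions
  attenuate the realized 2× contrast to ≈1.9.

What the generator does **not** emulate: alignment and mapping artifacts,
coverage-dependent junction detection bias, batch effects beyond
overdispersion, isoform-level read assignment ambiguity, multi-isoform
genes beyond a second terminal-exon transcript, and correlated mutations
(each effect targets one genotype group). Passing tests therefore show
that the statistics and classifiers behave correctly under the assumed
noise model, not that the pipeline is robust to upstream alignment error.

## Problem sizes and runtime choices

Validation studies run at desk scale: FDR calibration uses one fixed
5,000-gene null reference with 20 cohort seeds; power uses 200 replicate
events; classifier equivalence ~1,050 events; NMD recovery 500 events ×
6 seeds × 4 pairs at depth 500; expression coupling 60 coupled + 2,000
null genes; motif recovery 380 affected exons × 25 seeds. These sizes put
Monte-Carlo error comfortably inside the stated tolerances while keeping
a full run to a few minutes.

## Known limitations

* Intron-retention PSI uses boundary-count means, not length-normalized
  body coverage; absolute IR PSI values are therefore not comparable to
  coverage-based estimates.
* The NB dispersion estimator is simpler than empirical-Bayes approaches;
  with a large fraction of same-direction expression changes, TMM (like
  its reference implementation) under-corrects compositional bias and the
  type-I error drifts upward — at ≤3% affected genes calibration holds.
* Mutually-exclusive-exon detection is junction-pattern based and only
  handles adjacent exon pairs.
* The mutation mutual-exclusivity test treats patients as exchangeable;
  no cohort covariates are modelled.
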