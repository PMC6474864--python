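# Methods

This note documents the models behind `xenosplit`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the numerical
decisions a user auditing results should know about.

## Read classification model

Both transcript references are decomposed into canonical k-mers — the
lexicographic minimum of each k-mer and its reverse complement, packed
two bits per base into a 64-bit word (hence k odd, 3 ≤ k ≤ 31; odd k makes
the canonical form strand-unambiguous). The canonical k-mer universe of the
two references is partitioned into `graft_only`, `host_only` and `both`.
A read pair is classified from the pooled counts (h, m, b, u) of its
k-mers in those sets, one per position, both mates together:

| category  | condition            |
|-----------|----------------------|
| graft     | h > 0 and m = 0      |
| host      | m > 0 and h = 0      |
| both      | h = m = 0, b > 0     |
| neither   | h = m = b = 0        |
| ambiguous | h > 0 and m > 0      |

The human portion of a xenograft sample keeps `graft`, `ambiguous` and
`both`. These are clean-room category definitions consistent with the names
used by dual-reference k-mer classifiers; no tool's probabilistic marker
refinements are reproduced, and the boundary between `both` and `ambiguous`
here is exactly the table above.

Two consequences follow directly from the definitions and are verified in
the tests:

* **Retention theorem.** An error-free read drawn from a graft transcript
  has every k-mer in `graft_only ∪ both`, hence m = 0, hence is always
  retained. The idealised classifier is lossless on clean human input.
* **Leakage law.** Under substitution-only divergence, a host read pair is
  retained (category `both`) exactly when its 2 × 51 sampled bases cover no
  divergent site, i.e. with probability ≈ c^102 at per-base identity c.
  This is ~0.17 averaged over genes above 0.96 identity, ~10⁻³ in
  [0.9, 0.96), and numerically zero below 0.9. Host leakage is therefore
  confined to nearly-identical genes but is *not* exactly zero in the
  [0.9, 0.96) stratum: at cohort scale a few reads per hundred thousand
  survive there, and the tests report this honestly.

The lossless-on-clean-input property also means the pipeline-sensitivity
control (below) flags essentially nothing on this simulator: real
classifiers lose conserved-gene reads through heuristics and
reference/sample sequence differences that substitution-only simulation
does not create. The artifact-attribution machinery is therefore exercised
both on the end-to-end control (where the expected flag set is ~empty) and
on constructed flagged sets in unit tests.

k = 25 by default: long enough that host leakage is negligible below ~0.96
identity at 51 nt reads, short enough that a transcriptome-scale index is a
few million 64-bit words.

## Quantification

Reads are assigned to genes by transcript k-mer voting: each canonical
k-mer of the pair votes for every gene containing it; the unique maximum
wins; ties and zero-evidence reads are left unassigned, keeping counts
integral and unique-assignment in spirit. Synthetic transcripts have no
introns, so pseudo-alignment deliberately replaces spliced genome
alignment.

## Paired differential expression

Per gene g and sample s, counts are modeled as NB(μ_gs, φ_g) with
log μ_gs = x_sᵀ β_g + log(L_s f_s), where L_s is the library size and f_s
the TMM normalization factor. The design contains an intercept, patient
indicators and one condition term; the condition is tested by the deviance
difference between the full and patient-only fits against χ²₁, then
BH-adjusted. This is an LRT-GLM route (a paired design needs covariates) —
edgeR-inspired, not edgeR-identical; quasi-likelihood F-tests and exact
tests are out of scope.

* **Filtering:** genes with mean CPM across all samples below 2 are removed
  before testing.
* **Normalization:** TMM against the sample whose upper-quartile count
  fraction is closest to the mean upper quartile; 30% trim per tail on
  M-values, 5% per tail on A-values; inverse-variance (delta-method)
  weights; factors rescaled to geometric mean 1.
* **Dispersion:** per-gene Cox-Reid adjusted profile likelihood maximized
  over a log-spaced grid (10⁻⁴ … 10), then shrunk halfway to the across-gene
  median and floored at 10⁻⁶. The adjustment term −½ log det(XᵀWX) corrects
  the downward bias of plug-in estimation at the paired design's eight
  residual degrees of freedom; a plain residual method-of-moments estimator
  under-estimates φ by ~10–20% there and makes the null test anti-
  conservative, which is why the adjusted likelihood is used. Null
  simulations (φ = 0.1, nine pairs, 2000 genes) give raw p < 0.05 fractions
  of 0.051–0.063 across ten seeds.
* **IRLS:** at most 50 iterations, relative deviance tolerance 10⁻⁸,
  initialization from log(y + 0.5) projected onto the design, linear
  predictor clipped to ±30; non-converged genes are flagged and reported
  with p = 1. Reported log2 fold changes are clamped to ±20 for display
  (genes expressed in one condition only sit at the boundary).
* **Exact invariances:** the CPM filter and TMM factors are invariant to
  doubling one sample's counts and library size. The GLM itself is only
  approximately depth-invariant — a count model gains information with
  depth — and the tests assert the approximate version (median |Δlog2FC|
  < 0.01 on a doubled-depth sample).

## Conservation and artifact attribution

Per-gene conservation is the mean of per-base scores over covered bases
(uncovered bases excluded from numerator and denominator; fully uncovered
genes reported missing). In synthetic mode the simulator's per-gene
conservation stands in for the track with the whole transcript covered; in
real mode a bedGraph track and BED-like intervals are supplied, and the
supplied intervals define coverage (the exon-union versus gene-body choice
is the user's). Which conservation track to use (phastCons vs phyloP,
species set) is likewise left to the user. Flagged-vs-background
comparison reports group means and a two-sided Mann-Whitney U against the
full background set.

## Concordance

Pairwise donor-PDX similarity is Pearson correlation on log2(CPM + 0.5)
(the correlation flavor is not dictated by the problem; Spearman is a
flag). Clustering is average linkage on 1 − Pearson r; a pair is "aligned"
iff donor and PDX are dendrogram siblings (merged with each other before
either merges with anything else). Passage association is per-gene Spearman
ρ of PDX expression with passage number; with nine or fewer samples the
two-sided p-value is exact by full enumeration of passage-order
permutations (the t-approximation is poor at n = 9 and the permutation
null is valid under ties); with n ≥ 10 the t-approximation is used.
Constant genes have undefined ρ and are excluded from the BH adjustment.

## Enrichment

Gene-list overlap uses the upper-tail hypergeometric probability
P(X ≥ k) with an explicit, caller-supplied universe — overlap odds ratios
are not interpretable without one, and the pipeline's convention is the
set of genes surviving the CPM filter in both compared analyses. The
sample odds ratio is the 2×2 cross-product with a Haldane +0.5 correction
on zero cells (flagged). Family enrichment is the two-sided Fisher exact
test (point-probability method) with BH across families; family
definitions are user-supplied TSV, and signature correlation is Spearman
on the intersection genes (≥5 required).

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes:

* **Cohort:** nine donor/PDX pairs, 51 × 2 paired-end reads, 200 nt
  fragments placed uniformly (no positional bias), 2 × 10⁵ fragments per
  sample by default (~100 per gene at 2000 genes), iid base-error rate
  10⁻³.
* **Gene pairs:** lengths uniform in 300–3000 nt; host orthologs derive
  from graft sequences by substitution only (no indels), keeping
  coordinates aligned and expected k-mer survival analytically computable.
  The substitution count is fixed at round((1−c)·L) with uniformly drawn
  positions and uniform choice among the three alternative bases, so
  empirical identity equals the requested conservation to within rounding
  — a variance-free variant of iid substitution with the same expectation.
* **Conservation:** c ~ Beta(5, 2) per gene (mean ≈ 0.71, spanning low to
  near-identical), giving a usable gradient across the leakage strata.
* **Compartments:** 30% of genes are stromal; stroma baselines are rescaled
  so the stromal share of donor fragments equals `stroma_fraction_donor`
  (default 0.3 — **a free parameter**; no measured stromal fraction for
  donor ovarian tumors is assumed). In PDX samples the human profile
  expresses tumor-compartment genes only, and host-origin fragments from
  the mouse orthologs of stroma genes make up `mouse_stroma_fraction_pdx`
  (default 0.16) of reads.
* **Counts:** NB(μ, φ) with φ = 0.1 for every gene (configurable
  per gene); per-(gene, patient) lognormal factors (σ = 0.3) shared between
  the two members of a pair make pairs correlated, which is what the paired
  design exploits and the clustering detects. σ = 0.3 is a free parameter.
* **Micro-dissected emulation:** stroma/epithelium profiles for the overlap
  analysis are NB counts with 5% cross-contamination, ten samples per
  compartment, compared with the unpaired NB test. The public compartment
  data this emulates are microarray; microarray noise is not modeled, and
  this package's own unpaired test deliberately stands in for a linear-model
  microarray analysis.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: indels and structural divergence between the
species, splicing and isoform structure, patient genetic variation from the
reference, positional/GC bias, quality-score structure beyond iid errors,
strand-specific protocols, and the marker-based heuristics of production
classifiers. The most consequential of these is patient variation +
classifier heuristics: they are what make real pipelines lossy at conserved
genes, and their absence is why the synthetic sensitivity control flags ~no
artifact genes even though the attribution machinery is fully implemented.

## Problem sizes used in the shipped evaluations

The test suite and `scripts/acceptance.py` run: the classification
evaluation at full default scale (2000 genes, nine pairs, error-free);
null calibration at 2000 genes × ten seeds; one full default-scale study
(2000 genes, 2 × 10⁵ fragments/sample); and the ten-seed concordance
replication at 1000 genes with 10⁵ fragments per sample, which preserves
the default per-gene depth (~100 fragments/gene) that the XDG-calling power
and clustering margins depend on.

## Known limitations

* Gene assignment ignores multi-mapping structure beyond ties; fractional
  allocation is deliberately not implemented.
* The exact permutation p-values for passage association enumerate n! orders
  (feasible to n = 9); ties in expression are handled, ties in passage reduce
  the effective resolution.
* The index holds sorted k-mer arrays in memory (~8 bytes per distinct
  k-mer per class); transcriptome-scale references fit easily, whole
  mammalian genomes would not.
* With two samples per patient and one condition term, the GLM cannot
  separate patient-condition interaction from noise; the LRT tests the
  average condition effect.
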