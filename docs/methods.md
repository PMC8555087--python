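# Methods

## Scope and data model

The package analyses 3′-end sequencing data in which each read's
alignment terminus marks a cleavage-and-polyadenylation event. The unit
record is a `CleavageEvent`: chromosome, strand, 0-based coordinate of
the last transcribed nucleotide, sample. The study design is two pooled
condition groups ("low" and "high" temperature) with three biological
replicates each; all differential statements compare pooled low against
pooled high.

## PAS calling

Events are aggregated to distinct positions per (chromosome, strand)
and clustered greedily: the unassigned position with the highest total
read count becomes a cluster seed and absorbs all unassigned positions
within ±w nt; ties in read count break toward the smaller genomic
coordinate. Defaults: w = 25 nt. The seed (an observed position, not a
count-weighted mean) represents the cluster, which keeps coordinates on
real sites. Greedy-by-support with 5′-most tie-breaking is the standard
approach of 3′-seq PAS callers and is fully deterministic; because
per-position counts never change during absorption, processing
positions in a precomputed (count desc, coordinate asc) order is
equivalent to re-finding the maximum after every step. No minimum read
support is imposed at this stage; a configurable total-count threshold
(default 10 across samples) applies before testing.

## Sequence-context filters

Both filters evaluate the sense (transcript) strand around the cluster
seed, with inclusive offsets; on the minus strand the genomic window is
mirrored and reverse-complemented. Windows are clipped at chromosome
edges and evaluated on what remains.

* Internal priming: remove the site if offsets −30..+10 contain a run
  of ≥ 7 consecutive A. This captures oligo-dT priming on genomic
  A-stretches, which mimics a poly(A) tail.
* Signal requirement: remove the site if offsets −30..0 contain none of
  the canonical polyadenylation-signal hexamers. The default set is the
  twelve metazoan variants AATAAA, ATTAAA, TATAAA, AGTAAA, AAGAAA,
  AATATA, AATACA, CATAAA, GATAAA, AATGAA, TTTAAA, ACTAAA; it is
  configurable from a file. A hexamer must lie fully inside the window
  (valid start offsets −30..−5).

Both filters are always evaluated so the removal log can carry combined
reason codes (`IP`, `NO_SIGNAL`). Filtering is per-site, hence
order-independent, and monotone: growing the signal set or lengthening
the required A-run never removes more sites.

## 3′UTR extension and gene assignment

Each gene's 3′ end is extended downstream by
`extension = min(5000, floor(d/2))` nt, where d is the sense-strand
distance from the annotated 3′ end to the 5′ start of the nearest
downstream same-strand gene (abutting genes give d = 0, extension 0);
without a downstream gene the extension is capped by the chromosome
end. The half-distance is computed once per gene from the annotated 3′
end — a per-PAS midpoint would make the assignment region depend on the
site being assigned. Opposite-strand genes do not cap the extension. A
PAS belongs to the gene whose body-plus-extension covers its seed on
the matching strand; when several genes qualify (e.g. nested genes),
the nearest annotated 3′ end wins, with ties resolved toward the
lexicographically smallest gene id. Per gene, PASs are ranked 0..k−1
from proximal to distal along the direction of transcription; genes
with ≥ 2 assigned PASs are APA genes.

## Differential usage test

Counts are normalized to counts-per-million per sample. For each
feature (PAS, or gene after summing its PASs):

* Effect: `log2fc = log2((mean CPM low + 0.5) / (mean CPM high + 0.5))`.
  The 0.5 pseudocount keeps the estimate finite at zero counts.
* Dispersion: the per-feature NB dispersion φ solves
  Σ_g (n_g−1) s²_g = Σ_g (n_g−1)(μ_g + φ μ_g²) by the method of
  moments, pooled over the two groups. With three replicates per group
  there are only four residual degrees of freedom, so the raw estimate
  is shrunk toward the globally pooled estimate (the same moment
  equation summed over all features) with a prior weight of eight
  pseudo-degrees of freedom, then floored at 1e-8. The global target is
  used instead of the median of per-feature estimates because the
  latter is biased low by the skew of small-sample variances; with a
  median target the Wald test stays anticonservative (~0.08 empirical
  size at nominal 0.05 in our null simulations) while the pooled target
  brings it to ~0.05–0.06.
* Inference: Wald statistic log2fc/se with the delta-method standard
  error from the NB variance of each group mean, two-sided p from the
  normal reference, Benjamini–Hochberg adjustment across all tested
  features. Features with identical group means get p = 1 by
  construction.

The empirical size of this test under a matching null (NB counts,
dispersion 0.1, 3 vs 3) is 0.05–0.07 at nominal 0.05 (see
`tests/test_acceptance.py` and `scripts/acceptance.py`, which recompute
it). The test is deliberately self-contained rather than delegating to
an external differential-expression engine; the selection logic below
is engine-agnostic and the test sits behind a narrow interface
(`nb_test`) so it can be swapped.

## APA-switch selection and classification

Per APA gene, candidate proximal/distal pairs are built in tiers from
the per-PAS test results at α = 0.05 (BH-adjusted):

* ≥ 2 significant PASs: all pairs of significant PASs with opposite
  log2fc signs ("both_significant"); if no opposite-sign pair exists
  among them, the gene yields no call.
* Exactly 1 significant: that PAS paired with the highest-mean-count
  other PAS ("one_significant").
* None significant: the two highest-mean-count PASs
  ("none_significant").

Among candidates the pair with the greatest fold-change distance
|log2fc(proximal) − log2fc(distal)| wins (ties: smaller proximal rank,
then smaller distal rank), and a pair is only reported when its fold
changes point in opposite directions. The sign of
log2fc(proximal) − log2fc(distal) gives the label: positive = enhanced
= class II (proximal preferred at low temperature), negative =
repressed = class I (distal preferred at low temperature). Relabeling
proximal↔distal (a strand flip) exchanges the classes with identical
pair distance.

A gene only enters the switch-gene table when its selected pair
involves at least one significant PAS: a "none_significant" pair
identifies the gene's most divergently used PAS pair but is not
evidence of regulation — under a pure null the two fold changes of a
gene point in opposite directions in roughly one gene out of eight
(gene-level count noise is shared by both PASs; only the multinomial
split decorrelates them), which would contaminate the switch list with
~12% of all null APA genes. The unfiltered behaviour is available via
`require_significant=False`. An alternative selection
(`mode="top2"`) always compares the two PASs with the highest mean
counts and requires one of them significant.

Gene-level differential expression uses the same NB test on per-gene
count sums with the CoolUp/CoolDown thresholds: category CoolUp iff
log2fc ≥ 1 and padj < 0.01, CoolDown iff log2fc ≤ −1 and padj < 0.01.

## Reporter-assay quantification

Flow-cytometry event tables carry linear post-compensation red (mRuby)
and green (GFP) intensities. Gates are fitted from negative controls:
`red_max` is the q-quantile (default 0.99) of red in an mRuby-negative
control; `green_split` is the q-quantile of green among mRuby-negative
events of a GFP-negative control. The original gates were drawn
interactively in analysis software, so a reproducible quantile rule
replaces them; q is configurable. For a sample, events with
red < red_max form the mRuby-negative population, split into gate 2
(green ≥ green_split) and gate 3 (green < green_split); enhancer
activity = median(green | gate 2) − median(green | gate 3). If gate 2
holds fewer than `min_events` (default 100) events the activity is 0
with flag `NO_POSITIVE_POPULATION`. Medians make the statistic robust
(1% extreme outliers in gate 2 move it by < 1%) and scale-equivariant.

## Synthetic data generator

`simdata` emulates the assumed data-generating process on a single
synthetic chromosome. Each gene owns a disjoint 1100-nt slot (400 nt
body, 300 nt downstream region, 400 nt spacer), which guarantees
non-overlapping genes and that the half-distance extension rule always
reaches every planted PAS. Per gene:

* 1–3 true PASs at sense offsets ≥ 60 nt downstream of the 3′ end and
  ≥ 60 nt apart; each gets AATAAA written at sense offset −21 (well
  inside the −30..0 window even after ±8 nt of cleavage jitter), and
  any accidental A-run ≥ 7 within −30..+10 is broken by base
  substitution.
* One internal-priming artifact site at sense offset +25, carrying a
  written A₈ run covering the site; the surrounding −30..+10 window is
  scrubbed to C/G so no signal hexamer and no second A-run can occur.

Read counts per gene and sample are NB(mean = 200, dispersion = 0.1) by
default — desk-scale stand-ins for a well-expressed gene in a 3′-seq
library with three biological replicates. Reads are split multinomially
over the gene's PASs (Dirichlet(5) baseline usage, shared between
groups); recorded positions get a signed jitter from a discretized
double-geometric distribution (p = 0.5) truncated at ±8 nt, reflecting
imprecise cleavage without committing to a mechanistic model. A
binomial `artifact_fraction` (default 5%) of each gene's reads is
emitted exactly at the artifact site. Planted switch genes (class I:
distal usage +δ in the low group; class II: proximal +δ; δ = 0.3)
alternate classes deterministically for an even split; planted DE genes
shift their low-group mean by ±1.32 log2 units (2.5-fold). Everything
derives from one seed; identical configs give byte-identical output
files.

What the generator does **not** emulate: alignment and poly(A)-tail
trimming errors, mappability and GC biases, overlapping or intronic
PASs, library-size imbalance beyond NB noise, batch effects, and
isoform-level structure. Passing recovery tests therefore validates the
pipeline's logic and calibration under its stated model, not its
robustness to every artifact of real libraries.

## Problem sizes and numerical choices

Validation runs use 200 genes (~240k reads), a 5000-feature null for
calibration, 1000 random instances for the clustering and
pair-selection oracles, and 10⁵-event flow mixtures — sizes chosen so
the whole suite replays in a few minutes while keeping binomial error
on the asserted rates small. Degenerate inputs are defined: empty BED
files parse to empty event lists; zero-gene configs give an empty
annotation over a non-empty genome; `w = 0` keeps every distinct
position; windows clipped at chromosome edges are evaluated on the
remainder; a library with zero total counts is an error rather than a
silent NaN.

## Known limitations

* With three replicates the Wald test leans on a moderated dispersion;
  strongly feature-specific dispersions are pulled toward the global
  value, trading some power on high-dispersion features for calibration.
* The joint CoolUp/CoolDown rule (fold change ≥ 2 and FDR < 0.01) has
  theoretical power ~0.6 for a 2.5-fold effect at mean 200 and n = 3
  (se(log2FC) ≈ 0.38, so the realized fold change itself falls short of
  2 one time in five); recovery assertions are set against attainable
  power, not against 1.
* Gene assignment is gene-level only; transcript-isoform assignment and
  intronic PAS classes are out of scope.
* The reporter module consumes CSV event tables on a linear scale; FCS
  parsing and spillover compensation are upstream of it.
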