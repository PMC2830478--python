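# Methods

This note documents the models, the defaults and the numerical choices
behind `piscisel`, and what the synthetic data used by the test suite
do and do not establish.

## Codon substitution model

The engine implements a Goldman–Yang style codon model on the 61 sense
codons of the standard nuclear genetic code (the study species are all
teleost nuclear genes, so no alternative code arises). Off-diagonal
rates are `q_ij = pi_j * kappa^[ts] * omega^[nonsyn]` for single-
nucleotide changes and zero otherwise; the chain is time-reversible
with stationary distribution `pi`. Every model (for mixtures: the
proportion-weighted average over classes, at the current parameter
values) is rescaled to one expected substitution per codon per unit
time, so branch lengths carry the same units CODEML reports and are
comparable across models.

Equilibrium frequencies come from the alignment by one of three
schemes: `equal` (1/61), `F1x4` (products of overall nucleotide
frequencies, stops excluded and renormalized) or `F3x4` (products of
codon-position-specific nucleotide frequencies; the default, matching
common practice). Degenerate inputs (empty alignment, zero base
frequencies everywhere) fall back to `equal` with a logged warning.

Transition probabilities use the spectral form of the reversible
generator: `B = D Q D^-1` with `D = diag(sqrt(pi))` is symmetric, so
`exp(Qt)` is computed from one `eigh` per matrix, which is stable and
cheap enough to re-run inside the optimizer; a scipy `expm` fallback
exists for callers that supply no `pi`. Codons with zero equilibrium
frequency (possible under F3x4 on short alignments) receive no flux
and are held fixed, which is exact for this parameterization. Rows are
renormalized after exponentiation to absorb eigen round-off.

Likelihoods use Felsenstein pruning on the unrooted tree (rooted
internally at an arbitrary node — reversibility makes the choice
irrelevant, and a test asserts re-rooting invariance to 1e-8). Site
patterns are compressed; per-node rescaling with accumulated log
factors prevents underflow on long alignments. Gap codons (`---`) and
codons containing ambiguity codes are missing data (all-ones partial
likelihoods); alignments with in-frame stop codons are rejected at
construction.

## Site-class models and optimization

M0 (one ratio), M1 (nearly neutral: omega_0 < 1, omega_1 = 1),
M2 (M1 plus a free class with omega >= 1), M3 (three free discrete
classes), M7 (Beta(p, q) on (0,1), discretized into K = 10
equal-probability classes represented by their conditional means) and
M8 (M7 plus an extra class with omega >= 1) are fitted by maximizing
the mixture log-likelihood over the site-model parameters, kappa, and
(by default) all branch lengths. The omega >= 1 constraint on the
extra classes of M2/M8 follows the modern convention; the boundary at
1 is one reason the M8-vs-M7 LRT is conservative.

Free parameters are transformed — log for rates and branch lengths,
logistic/stick-breaking for proportions — and optimized with bounded
L-BFGS-B (numerical gradients). Site-class surfaces are multimodal, so
each fit runs up to three deterministic starts (fixed start points per
model, no randomness) and keeps the best; non-convergence is flagged
on the result, never silent. Branch lengths are re-estimated per model
by default with a flag to fix them, since the original analysis does
not state its choice. M3's classes are reported sorted by omega.

Free-parameter counts for the LRTs (M0:1, M1:2, M2:4, M3:5, M7:2,
M8:4 site-model parameters; df = 2, 4, 2 for M2-M1, M3-M0, M8-M7)
follow the CODEML convention. The LRT statistic is computed from the
fitted log-likelihoods and clamped at zero. Published tables sometimes
print a statistic inconsistent with their own likelihood column (for
the piscidin data, the printed M8-vs-M7 statistic 5.68 does not match
the printed likelihoods −795.43 and −792.29, which give 6.28 and agree
with the printed p = 0.04); this package always reports the value
implied by the likelihoods.

## Empirical Bayes site identification

NEB evaluates `P(class k | site) = p_k L_k(site) / sum_j p_j L_j(site)`
at the MLEs. BEB (models M2 and M8) integrates the same quantity over
a uniform-prior grid on the site-model parameters with kappa, branch
lengths and the rate-matrix scale fixed at the MLEs: by default 10
grid midpoints per dimension (proportions on (0,1), beta parameters on
(0,2), the selected-class omega on (1,11)), with the beta component
approximated by 10 equal-width omega bins so per-omega site likelihoods
are computed once and reused across the grid. For M2 the proportion
pair is mapped through a stick-breaking grid with the appropriate
Jacobian weight so the prior is uniform on the simplex. A grid
collapsed onto the MLE point reduces exactly to NEB (tested). The
reporting threshold for a positively selected site is posterior 0.95.

The REL-style analysis fits independent discrete distributions (3×3
categories by default) for the synonymous and nonsynonymous rates,
normalizes the synonymous distribution to mean 1 for identifiability,
and reports per-site `P(dN > dS)` plus the distribution-mean omega.
Branch lengths are taken from a prior codon-model fit (M0 in the
pipeline) rather than from a separate nucleotide-model step — a
deliberate simplification relative to the HyPhy/Datamonkey original.
Alignments without variation yield a flagged degenerate result.

## Pairwise Nei–Gojobori analysis

Site counts: at each codon position the synonymous fraction is taken
over the single-base changes that do not create a stop codon, so
`s + n = 3` for every sense codon. Differences at multi-hit codon
pairs are averaged over all minimal mutational pathways that avoid
stops (with a documented fallback through stops only when no valid
pathway exists, possible only for three-fold differences). Codon pairs
overlapping a gap in either sequence are skipped entirely. Proportions
`pN = Nd/N`, `pS = Sd/S` are corrected with Jukes–Cantor
`d = -(3/4) ln(1 - (4/3) p)`; saturation (`p >= 3/4`, a real risk on
46-codon regions) yields a flagged NaN excluded from averages with a
warning. The "average omega" over pairs is mean(dN)/mean(dS)
(ratio-of-means, which is how the published average is arithmetically
consistent: 0.285/0.987 = 0.289); mean-of-ratios is available as an
option. Cumulative per-codon Sd/Nd profiles are averaged position-wise
over pairs.

Region contrasts compare per-pair region-restricted dN (or dS) between
the mature and signal regions with a two-sided Wilcoxon signed-rank
test: zeros dropped, average ranks for ties, the exact null
distribution (dynamic programming over doubled ranks, equivalent to
full 2^n enumeration — tested against enumeration for n <= 8) for
n <= 25, and the tie-corrected normal approximation with continuity
correction beyond. Region boundaries (signal = codons 1–22 for the
study layout) are configuration, not hard-coded, because published
per-species peptide boundaries come from figure annotations.

A caveat established by simulation: classical Nei–Gojobori counting
assumes unweighted mutation, so with a transition/transversion bias
(kappa = 2) it *underestimates* dN/dS (about 0.84 at a true omega of 1);
the estimator is centered only at kappa = 1, and the test suite checks
that case.

## Peptide analytics

Percent identity between aligned peptides counts columns where both
sequences are non-gap (BioEdit-style; an alignment-length denominator
is selectable). The helical wheel advances 100° per residue; the
hydrophobic moment is the length-normalized magnitude of the vector
sum of per-residue hydrophobicities (Eisenberg consensus scale by
default; the scale is a configurable table). Residue classes for wheel
rendering: hydrophilic-charged {D,E,K,R,H}, very hydrophobic
{F,I,L,M,V,W}, the rest neutral/polar.

## Synthetic data and what the tests show

The simulator evolves each codon site independently: draw a site class
from the mixture, draw the root codon from `pi`, then apply
`exp(Q_class t)` along each branch. Stop codons cannot be emitted
because the generator has no flux into them. One integer seed
determines everything; each site has its own derived stream
(SeedSequence spawn keyed by site index), so outputs are reproducible
and adding taxa or sites never perturbs earlier sites.

The bundled piscidin-like fixture mimics the study's shape: 10 taxa on
a tree with one long basal branch and a shallow perciform-like clade,
46 codons, signal region (codons 1–22) drawing only from the two
purifying classes, mature region drawing from the full 3-class mixture
(omega = 0.05/0.29/2.25 with proportions 0.22/0.59/0.19, kappa = 2,
equal codon frequencies). Branch lengths are scaled so the all-pairs
Nei–Gojobori averages land in the published divergence regime (mean
dS near 1, mean dN near 0.28). Real piscidin data differ in ways the
fixture does not emulate: non-uniform codon usage, among-site rate
correlation, alignment gaps, and any misalignment error. Passing tests
therefore demonstrate correctness of the machinery and recoverability
under the model, not robustness to model violation.

Problem sizes used by the verification suite were chosen to keep the
whole run in the minutes range while remaining informative: parameter
recovery at 500 codons on a deep 10-taxon tree, LRT calibration with
50 replicates of 100 codons on 6 taxa with K = 5 beta classes and
branch lengths fixed at their simulation values.

## Known limitations

* The two purifying classes of a 3-class discrete mixture are only
  weakly identified at realistic alignment sizes: on 500–1000 codon
  simulations the MLE frequently merges or re-splits them (the
  likelihood at the truth is measurably below the MLE), while the
  positively selected class omega and the M3-vs-M0 LRT are recovered
  reliably. Per-class point estimates of small omegas should not be
  over-interpreted.
* BEB approximates the beta component on a fixed 10-bin omega grid;
  posteriors very close to the 0.95 threshold can shift with the grid
  resolution (configurable).
* The REL branch lengths come from the M0 codon fit, not a nucleotide
  model; absolute REL rates are therefore on the codon-model scale.
* No indel model: gaps are missing data in likelihoods and skipped in
  pairwise counting, never evolved.
* Branch models (among-lineage omega variation) and branch-site models
  are out of scope.
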