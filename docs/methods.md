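# Methods

This note documents the models, numerical choices and synthetic-data
conditions behind the `gbgc` package, and what its tests do and do not
establish about real data.

## Polarization and the ancestral genome

SNP orientation uses invariant outgroup sites.  Under the **strict**
scheme, every outgroup individual must be homozygous for the same allele
with no missing calls; that allele is ancestral provided it is one of the
two ingroup alleles.  The **liberal** scheme consults only the highest
mean-depth individual per outgroup population and tolerates one missing
allele per individual; a half-called individual must carry only the
candidate ancestral allele.  Rejection reasons (`outgroup_missing`,
`outgroup_polymorphic`, `third_allele`, `ingroup_invariant`) are recorded
per site for auditability.  Two conventions the data formats do not settle
were fixed as follows:

* An outgroup consensus allele matching neither ingroup allele rejects the
  site (the conservative reading of "biallelic"); the same applies when
  the two outgroup populations are each invariant but disagree.
* Sex-linked SNPs receive no separate treatment: for a female-achiasmate
  ZW system the threefold Z-to-autosome ratio of effective size cancels
  against dosage, leaving only the relative recombination rate in B, so a
  common pipeline is appropriate.

The ancestral genome model substitutes the inferred ancestral allele
wherever the reference carries the derived one, masks repeats and exons,
and treats N bases as masked for all counting.  Trinucleotide contexts read
from this genome drive the CpG-prone flag (dinucleotides CG, TG, CA, NG,
TN, CN, NA overlapping the focal base, with N meaning masked/unknown);
contexts at sequence ends are N-padded, which deliberately still triggers
the N-containing prone dinucleotides.  Coordinates are VCF 1-based on
input, 0-based half-open internally and in BED.

## The DAF likelihood

Segregating sites are classified by ancestral/derived strong-weak state
into GC-conservative (N→N = S→S + W→W) and GC-changing (S→W, W→S)
categories, and histogrammed by derived count i in n = 20 sampled haploid
genomes.  Treating gBGC as directional selection of scaled strength B, the
expected relative density of a favored derived allele in class i is

    F_i(B) = ∫₀¹ (1−e^{−B(1−x)}) / ((1−e^{−B}) x(1−x)) · C(n,i) xⁱ(1−x)^{n−i} dx,

with F_i(0) = 1/i.  Expected counts per cell are

    E_i^{NN} = θ_N r_i / i
    E_i^{WS} = θ_WS r_i F_i(B)
    E_i^{SW} = λ θ_WS [gc/(1−gc)] r_i F_i(−B),

where the fixed regional ancestral GC supplies the mutational-opportunity
ratio, θ_N and θ_WS are free scale parameters, and r_i (r_1 ≡ 1) are
demographic nuisance multipliers shared across categories — sharing is what
makes them demography rather than category effects.  The star models mix in
misorientation: a fraction e_C of category C's mass appears in the reverse
category at the mirrored class n−i; exactly three error parameters, bounded
[0, 0.5], matching the 3-df test between M1 and M1*.

**Likelihood form.** Cells are independent Poisson (a Poisson-random-field
choice).  A multinomial conditioned on the total would differ only in how
the overall scale is handled; the Poisson form lets θ_N and θ_WS be free
scale parameters exactly as the parameter list implies, and is validated by
parameter-recovery simulation rather than by matching any particular
implementation.

**Optimization.** For fixed (λ, B) the cell means are linear in θ and,
separately, linear in r, so the inner problem is solved by exact scaling
updates for θ and monotone multiplicative (MM) updates for r, leaving a 1-2
dimensional outer problem in (log λ, B) handled by Nelder-Mead from ≥5
deterministic starts (a method-of-moments neutral start plus fixed
perturbations; first-best wins ties).  The error rates of the star models
trade off almost flatly against the mirrored nuisance classes — they are
identified mainly through the singleton/anti-singleton classes, where r is
pinned — and a fixed-point iteration crawls along that ridge; the star
models are therefore fitted by box-constrained L-BFGS-B over the full
parameter vector, warm-started from the corresponding non-star optimum.
Because the e = 0 corner reproduces the non-star fit exactly, the nested
log-likelihood ordering holds by construction.  Convergence tolerance is
1e-8 on the outer log-likelihood, 1e-10 to 1e-12 on the inner updates.

**Quadrature.** F_i(B) uses fixed-order Gauss–Legendre (order 64) on
(0, 1); the integrand is smooth and bounded for i ≥ 1 with the 1/(1−x)
singularity cancelled by the exponential.  Below |B| = 1e-4 the series
F_i(B) = 1/i + B/(2(n+1)) + O(B²) takes over, which keeps the neutral limit
exact and avoids expm1 cancellation.  The n = 2 closed form
F_1(B) = 2[1−(1−e^{−B})/B]/(1−e^{−B}) agrees with the quadrature to better
than 1e-8 over B ∈ [−10, 10].

**Tests.** LRTs use upper-tailed χ² with df = free-parameter difference
(M0→M1: 1; M1→M1*: 3); a negative statistic is clipped to zero with a
warning.  The bootstrap resamples segregating sites with replacement,
rebuilds spectra and refits; non-converged replicates are excluded and
counted.

## Skew diagnostic

The direction of GC evolution is summarized by a model-based flux
statistic: with σ(B) = B/(1−e^{−B}) the W→S and S→W substitution fluxes are
proportional to (1−gc)·σ(B) and gc·λ·σ(−B), and the statistic is their
normalized difference.  It is zero exactly at gc = 1/(1+λe^{−B}), positive
below (GC rising), negative above, and strictly decreasing in gc.  The
literature leaves open whether the comparable diagnostic crosses zero at
the mutation-only or the gBGC-adjusted equilibrium; this package adopts the
gBGC-adjusted crossing — the zero/sign contract, not any particular closed
form, is the tested surface.

## GC landscape

Local GC is measured in 1 kb windows of the masked ancestral genome,
N-corrected (G+C over unmasked bases); fully masked windows are excluded.
SNPs are ranked by their window's GC (ties broken by chromosome and
position for determinism) and cut into 100 bins of equal SNP count, the
remainder spread over the lowest ranks.  Centile GC aggregates base counts
over the distinct windows contributing SNPs — for equal-sized windows this
equals the length-weighted mean.  A window whose SNPs straddle a bin
boundary contributes its bases to both centiles: centiles are SNP sets, not
genome partitions, and the double counting is accepted and documented.
CDS density is coding bases over total bases of the centile's windows.
Per-centile model fits fix gc at the centile's aggregate GC; cross-centile
summaries report mean ± SEM.  Bin count and window size are configuration
(desk-scale fixtures use 3-10 bins).

## The GMD equilibrium model

With x_GC = 1/(1+λe^{−B}), diversity relative to the B = 0 reference is

    π_rel = [2λ x_GC (1/(1−e^B) + 1/B) + 2(1−x_GC)(1/(1−e^{−B}) − 1/B) + θ_N/θ_WS]
            / [2λ/(1+λ) + θ_N/θ_WS],

whose three numerator terms are the S→W, W→S and GC-conservative
contributions; both bracketed factors tend to 1/2 as B → 0, giving
π_rel(B=0) = 1 exactly (implemented with a series branch below |B| = 1e-5).
The per-category decomposition divides each opportunity-standardized
component by the common denominator; the GC-conservative diversity ratio
splits by default equally into θ_SS/θ_WS = θ_WW/θ_WS = θ_N/θ_WS, which
makes the reconstruction identity
x_GC·π_SW + (1−x_GC)·π_WS + x_GC·π_SS + (1−x_GC)·π_WW = π_rel hold exactly;
that identity is the correctness criterion for the decomposition.
θ_N/θ_WS defaults to 1 unless fits supply it.  Robustness sampling draws
(λ, B) from normal distributions around the point estimates (rejecting
λ ≤ 0) and reports percentile envelopes; the reference standard deviations
(0.1 for λ, 0.09 for B) correspond to the centile-level estimation error of
the best-sampled population.  The model assumes full gBGC–mutation–drift
equilibrium; no transient GC trajectory is modelled.

## Downstream statistics

Per category, diversity is regressed on GC and CDS density
(π ~ gc + gc² + cds + cds² + gc:cds) and reduced stepwise: the least
significant term with p ≥ 0.05 is dropped (ties resolved by removing the
higher-order term first) and the model refitted until all retained terms
are significant.  The GC-bin analysis cuts centiles into five equidistant
GC intervals and regresses per-category π on CDS density within each, so
the GC range is held roughly constant; the last bin is flagged (it
typically holds a single extreme centile) and excluded from cross-bin trend
statements.  Independent contrasts follow the standard recursion —
contrast (x_l − x_r)/√(v_l+v_r), ancestral value the branch-length-weighted
average, branch augmentation v_l·v_r/(v_l+v_r) — with polytomies rejected;
branch lengths default to 1 when the tree supplies none, since the study
tree's lengths are not a reproduction target.  Contrast regressions run
through the origin, the standard convention.  Trait ranges (e.g. diploid
chromosome numbers) enter as midpoints.

## Synthetic data: what it emulates and what it does not

The generator draws site counts per (category, frequency class) Poisson
from the same expected-spectrum law the inference assumes, places sites
uniformly on eligible (unmasked, correct ancestral class) bases, assigns
derived alleles to random haplotype subsets, and writes standard VCF 4.2 /
FASTA / BED files.  Defaults are the study conditions: 300 kb over three
contigs, blockwise window GC ~ N(0.32, 0.05), λ = 3, B = 0.21
(weak-gBGC-population-like), θ_N/θ_WS = 1, 10^4 target SNPs, n = 20
ingroup haplotypes, two outgroup populations of two diploids, 10% repeats,
3.7% coding.  The reference sequence picks the derived allele with
probability i/n (a sampled-haplotype reference), so ancestral-genome
reconstruction is genuinely exercised.  Outgroup divergence is modelled
only through a configurable misorientation fraction that flips the
outgroup to the derived state; there is no sequence evolution along a
tree, no linkage, no linked selection, and no coverage/genotyping error.
Gradient configurations couple λ and B linearly to window-GC rank in a
configurable number of strata.

Because frequencies come from the inference's own law, recovery tests
demonstrate correctness of the estimator under its assumptions, not
robustness to model violation; the r_i distortion option and the
misorientation fraction probe the two violations the model is built to
absorb.  An independent check that does not share the quadrature is the
forward Wright–Fisher mode: haploid size N with per-generation advantage
s = B/(2N) (so 2Ns = B), accumulating binomial class probabilities along
each trajectory (an occupation-measure estimator); at N = 200 it matches
F_i(B) to within ~1-8% per class, the residual being the O(1/N) diffusion
discretization.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; fixture writers are
byte-stable for a fixed seed.  The test suite uses 10 kb to 300 kb genomes
and 150 to 10^4 sites for structural checks; estimator calibration runs 50
replicates of 10^5 sites per truth point (bias on B below 0.01 against a
0.05 acceptance band) and 200 null replicates of 2×10^4 sites for the LRT
size, sizes chosen so the whole suite completes in minutes on one core.

## Known limitations

* The Poisson-cell likelihood ignores linkage between sites; standard for
  SFS inference, and bootstrap intervals inherit the independence
  assumption.
* Error rates in the star models are weakly identified at n = 20 when true
  misorientation is small; estimates may legitimately sit at the zero
  boundary, making the 3-df LRT conservative there.
* Centile GC aggregation double counts boundary windows (documented above).
* The GMD model describes equilibrium; applying it to regions far from GC
  equilibrium is an extrapolation.
* `pi_all_sites` computes diversity over polarized/segregating input rows;
  invariant sites enter only through the unmasked-length denominators.
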