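# Methods

## Marker dependence under family structure

### Gametic covariance of a phased parent

Meiosis is modelled without crossover interference. Genetic distances *d*
(cM) convert to recombination fractions by the Haldane map function
θ = ½(1 − e^(−2d/100)); markers on different chromosomes get θ = ½. For a
parent with phased haplotypes *h⁽¹⁾, h⁽²⁾* ∈ {0,1}^p, the transmitted
gamete *G* satisfies

    E[G_k]      = (h⁽¹⁾_k + h⁽²⁾_k)/2
    E[G_k G_l]  = ((1−θ_kl)/2)(h⁽¹⁾_k h⁽¹⁾_l + h⁽²⁾_k h⁽²⁾_l)
                + (θ_kl/2)(h⁽¹⁾_k h⁽²⁾_l + h⁽²⁾_k h⁽¹⁾_l)

so Cov(G_k, G_l) = ¼ on the diagonal at heterozygous loci, 0 at
homozygous loci, and ±(1−2θ_kl)/4 between double-heterozygous loci
(coupling/repulsion sign). This is validated in the test suite against an
independent Monte-Carlo oracle that simulates an explicit Poisson
crossover process.

### Family designs

- **Half-sib** (sire observed, dams a population): C_i = P(sire_i) + D,
  where D is the gametic covariance matrix of the dam population with
  diagonal p(1−p). D may be supplied as a full matrix plus frequencies or
  with an empty diagonal (then filled from the frequencies).
- **Full-sib** (both parents phased): C_i = P(sire_i) + P(dam_i), the
  plain sum. Cross-terms that would arise for inbred, correlated parental
  gametes are not modelled.
- `parts` can restrict to the paternal or maternal component, e.g. for
  double-haploid progeny where only maternal meioses are informative.

Multiple families combine as C = Σ w_i C_i with w_i the family's progeny
share; since downstream evaluation centers genotypes within family, the
size-weighted within-family covariance is the relevant aggregate. Markers
with a missing required parental allele are dropped. `to_correlation`
removes markers whose total variance is below 10⁻¹² (exact zeros are
expected where all sires are homozygous and no maternal variance exists;
the floor only guards float noise) and returns R with unit diagonal.

## Population LD (r²)

For a marker pair with two-locus gamete frequencies f_AA, f_AB, f_BA,
f_BB and allele frequencies f_k = f_AA + f_AB, f_l = f_AA + f_BA:

    r² = (f_AA f_BB − f_AB f_BA)² / (f_k(1−f_k) f_l(1−f_l))

From unphased diploid genotypes the frequencies are maximum-likelihood
estimates: every genotype pair except the double heterozygote contributes
unambiguous gamete counts; double heterozygotes are split between the
coupling and repulsion resolutions with responsibility
f_AA f_BB / (f_AA f_BB + f_AB f_BA) per EM iteration. The EM starts at
linkage equilibrium and stops when the largest frequency change is below
10⁻⁸ (≤1000 iterations); for two loci the allele frequencies are fixed by
counting, so the likelihood is one-dimensional in f_AA and a single start
suffices (verified against an exhaustive scan). Missing genotypes are
handled pairwise-complete; monomorphic loci yield NaN cells which the
grouping treats as "not associated". For haploid data (double-haploid
lines, gametes) r² is the squared Spearman correlation, which equals the
squared Pearson correlation for binary columns and is computed as such.

## Greedy grouping and tagSNP choice

Given a symmetric dependence matrix (family R, or r²) and threshold
t ∈ [0,1): among unbinned markers, each k collects
C_k = {l unbinned : |R_kl| > t} (k ∈ C_k since |R_kk| = 1); a marker c
with maximal #C_k — smallest index on ties — seeds the group C_c; within
it, T = {k ∈ C_c : |R_kl| > t ∀ l ∈ C_c} and the ⌈#T/2⌉-th candidate in
ascending index order becomes the representative. Binned markers are
removed and the loop repeats. The strict inequality, the tie-break and
the candidate ordering are fixed so identical inputs always produce
identical groupings; an exhaustive brute-force re-implementation verifies
the production path on random matrices up to p = 30.

## Evaluation

Grouping quality is the Calinski–Harabasz index
CH = [B/(K−1)] / [W/(q−K)] over markers-as-points: each marker is its
genotype column, centered within family and scaled to unit variance
(denominator n−1), so K clusters of q markers are judged by Euclidean
between/within dispersion in individual space. Singleton clusters
contribute zero to W; W = 0 returns +inf with a warning. The
implementation agrees with scikit-learn's to 10⁻⁹ relative error.

## SNP-BLUP screen

The regression y = Xβ + e uses within-family standardized y and X
(tagSNPs or all SNPs); no intercept or other fixed effects. The ridge
solution β̂ = (XᵀX + λI)⁻¹Xᵀy is computed by Cholesky solves. λ = σ²_e/σ²_β
is estimated by REML for β ~ N(0, σ²_β I): a bounded 1-D search (tol 10⁻⁶
in log λ, bounds [10⁻⁶, 10⁹]) on the profile restricted likelihood, using
the eigendecomposition of XᵀX; with no fixed effects the restricted and
full likelihoods coincide, and the stationary point equals AI-REML's.
σ̂²_e = RSS/(n − df) with df = tr X(XᵀX+λI)⁻¹Xᵀ.

Effects are screened by T_k = β̂_k / SD(β̂_k) against standard-normal
quantiles (flag if T_k ≥ q_{1−α/2} or T_k < q_{α/2}). Two SD forms are
implemented:

- `pev` (default): σ̂²_e[(XᵀX+λI)⁻¹]_kk, the prediction-error form that
  mixed-model software reports;
- `sandwich`: σ̂²_e[(XᵀX+λI)⁻¹XᵀX(XᵀX+λI)⁻¹]_kk, the exact sampling
  variance of β̂ for fixed λ when y is pure noise.

Under a pure-noise null the sandwich form gives an exactly calibrated
test for any fixed λ; the pev form is conservative by roughly
√(n/(n+λ)), which matters because the REML λ̂ is large when there is no
signal. The type-I calibration test therefore uses the sandwich form;
the default remains `pev` for comparability with mixed-model output.

QTL detection is summarized per type-I level α: a tested marker is
in-window if within ±0.05 cM (default) of a simulated QTL; sensitivity is
the fraction of QTLs with ≥1 significant in-window marker, specificity is
1 − (significant markers outside all windows)/(markers outside). ROC area
adds (0,0)/(1,1) endpoints and integrates by trapezoid over FPR.

## Simulator

The generator emulates a dairy-cattle-like half-sib design: N ∈ {1,5,10}
sires, n = 1000 progeny equally partitioned, 300 SNPs on a 1 cM chunk,
traits with 2 or 5 equal-effect QTLs at heritability 0.3, 100
repetitions by default (20 in the desk-scale acceptance runs; the
reported averages stabilize well before that).

**Founders.** Haplotypes evolve through a discrete Wright–Fisher burn-in
with recombination and symmetric recurrent mutation. Per-locus mutation
rate is u = θ/(4Ne) with θ = 0.22, and initial allele frequencies are
drawn from the stationary Beta(θ, θ) spectrum, so the pool sits at
mutation–drift–recombination equilibrium with a realistic U-shaped
allele-frequency spectrum. Drift rescaling keeps this affordable: the
burn-in runs 150 generations at Ne = 100 on a 12-fold inflated map, which
reproduces the LD profile of 1800 generations at Ne = 1200 on the true
map (4Ne·c and t/Ne invariant). A recent bottleneck epoch (50 generations
at Ne = 100 on the true map) then adds the long-range haplotype sharing
typical of livestock. Loci fixed at the end are re-seeded from a random
segregating locus (rarely triggered in this regime) and alleles are
recoded to founder-major.

**Marker ascertainment.** Three times as many candidate loci as markers
are simulated; the panel keeps 300 with founder MAF ≥ 0.05, evenly along
the map — mimicking SNP-array design. Without this step the equilibrium
spectrum floods the panel with rare variants whose pairwise dependence is
negligible, and the grouping fragments into rare-singleton groups.

**Families.** One extra round of random mating breeds a cohort of N + n
individuals from the pool; the first N are sires, the rest are the n
distinct dams (strict half-sibs, but dams share founder haplotypes as
real dams do). The maternal LD matrix D and frequencies are the empirical
gametic covariance/frequencies of the dam cohort's haplotypes. Each
progeny receives one recombinant gamete from its sire and one from its
dam; meiosis uses per-interval Bernoulli switches with probability θ of
the interval, which is exact under the Poisson (Haldane) model.

**Traits.** QTLs are the markers nearest to evenly spaced target
positions among markers with founder MAF ≥ 0.1; all effects have equal
magnitude and sign; the residual variance is set from the realized
genetic variance so that E[h²] matches the target exactly.

**Calibration.** The founder parameters (θ = 0.22, Ne = 100, 150
generations, scale 12, bottleneck 100 × 50, MAF floor 0.05) were fixed
once so that the family-correlation grouping at t = 0.8 yields ≈60 groups
in the 300-SNP/1 cM design — the magnitude this design is known to
produce — and were not revisited afterwards.

**What the simulator does and does not reproduce.** With these
conditions the package reproduces: ≈60 family groups at t = 0.8 across
N ∈ {1,5,10}; exact agreement of the analytic family covariance with
realized progeny covariance; EM-r² consistency; SNP-BLUP calibration; and
the dominance of the all-SNP fit in ROC area. It does **not** reproduce
three comparative findings about the population-LD baseline that
published analyses of this design report (obtained there on
AlphaSimR/MaCS cattle founder genomes with snpStats-estimated LD): in
our simulations the estimated r² grouping (i) makes *more* groups than
the family approach rather than far fewer, (ii) scores a *higher*
CH index (it is estimated from the very genotypes the index is computed
on), and (iii) its tagSNPs give a slightly larger ROC area (more tags →
better QTL-window coverage). We verified the one mechanism that
demonstrably inflates pooled r² across long distances — minor alleles of
low-MAF loci concentrated within a single sire family give pairwise
r² ≈ 1 regardless of map distance — but it inflates the family matrix
equally, since the family covariance models exactly that paternal
segregation. Reproducing those orderings evidently requires the specific
founder-genome generator and LD toolchain used there, whose settings are
not published. The corresponding checks in `tests/test_acceptance.py`
assert the reported orderings and are expected to fail under this
simulator; they are kept as executable documentation of the discrepancy.

## Numerical choices and degenerate inputs

- Zero-variance detection floor 10⁻¹² (exact zeros expected; float guard).
- Correlations clipped to [−1, 1] after scaling; |R| > 1 + 10⁻¹⁰ raises.
- MAF filter uses strict "<" (a SNP exactly at the threshold is kept);
  ties at frequency 0.5 never flip in major-allele recoding.
- Missing-data sentinel: −1 in memory, "NA" in TSV, "." in VCF.
- Imputation streams one seeded generator in marker-major order.
- Filters are idempotent; call-rate filtering removes individuals first,
  then SNPs (matching the narrative order of the double-haploid
  workflow: call rate → heterozygote masking → imputation → MAF).
- λ = 0 with a rank-deficient design raises rather than silently
  pseudo-inverting.

## Known limitations

- Interference-aware map functions (e.g. Kosambi) are not implemented;
  the Haldane assumption is used consistently in theory and simulation.
- Full-sib covariance assumes non-inbred parents (no cross-term).
- The simulator models a single chromosome segment, no selection,
  dominance or epistasis, and equal family sizes up to rounding.
- Maternal-LD estimation from raw dam data is out of scope; D must be
  supplied or taken from the simulator.
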