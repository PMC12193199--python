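# Methods

This note documents the statistical machinery, the numerical choices, and
what the synthetic data generator does and does not emulate.

## Relationship matrices

**Pedigree (A).** Pedigrees are renumbered topologically (Kahn's algorithm;
parents referenced but never listed are appended as founders). A is built by
the tabular recursion `a_ij = (a_j,s + a_j,d)/2`, `a_ii = 1 + a_sd/2`; the
inbreeding coefficient is `F_i = a_sd/2`. The sparse inverse uses Henderson's
rules with inbreeding: each individual contributes
`δ_i⁻¹ [1, −½, −½][1, −½, −½]'` over (itself, sire, dam), with Mendelian
sampling variance `δ_i = 1 − (a_ss + a_dd)/4` (unknown parents contribute
nothing). Dense matrices are materialized only below a configurable size
limit (6000); the package targets evaluations up to a few thousand
individuals per run, and larger pedigrees are a known limitation of this
version.

**Metafounders (A(Γ)).** Each base population is a pseudo-individual whose
self-relationship γjj measures base homozygosity; pairs carry γjk. Every
unknown-parent slot is rewired to its group's metafounder (mid-pedigree gaps
inherit the dam's origin label — origins propagate down the maternal line in
OP populations). The tabular recursion is seeded with the metafounder block
equal to Γ itself, so a founder of group j emerges with diagonal 1 + γjj/2.
The inverse is the same Henderson assembly (δ from the Γ-seeded diagonals)
plus Γ⁻¹ on the metafounder block; a PSD-but-singular Γ gets a ridge of 1e-8
before inversion, never silently elsewhere.

**Genomic (G).** QC keeps markers with call rate > 0.95 and MAF > 0.05 and
individuals with call rate > 0.80. Because each filter changes the other's
statistics, the marker and individual passes iterate to a fixpoint (a second
full pass removes nothing); residual missingness is mean-imputed (2p̂).
G is VanRaden method 1, `ZZ'/(2Σp(1−p))`; in metafounder mode all allele
frequencies are fixed at 0.5 (`(M−1)(M−1)'/(m/2)`), the reference scale that
A(Γ) is compatible with. Before inversion G is blended with the genotyped
block of the pedigree matrix, `0.95·G + 0.05·A22`, purely as an
invertibility safeguard; rescaling ("tuning") G to match A22's moments is
available (`tune_to_A22`) but off by default, and is forced off in
metafounder mode where Γ is the compatibility device.

**Single-step (H⁻¹).** `H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]` scattered on the
genotyped rows; A22⁻¹ is the inverse of the genotyped *block* of A, not the
block of A⁻¹. The object keeps the sparse pedigree part and the dense
genotyped-block correction separate, so quadratic forms cost one sparse
product plus one small dense product. The dense H used in tests comes from
the conditional-Gaussian joint formula (genotyped block replaced by G, the
rest projected through the pedigree); it is test scaffolding, not a runtime
path.

**Γ estimation.** Method of moments: per-group allele frequencies p̂j from
the genotyped descendants of each group, then `γjk = 8·Cov_markers(p̂j − ½,
p̂k − ½)`. The diagonal subtracts the binomial sampling term
`mean(p̂(1−p̂))/(2n−1)·8`; the result is projected to the nearest PSD matrix.
Groups with fewer than 10 genotyped members trigger a wide-uncertainty
warning. The estimator is deliberately simple and swappable; likelihood-based
alternatives exist but need data structures this package does not assume.

## The threshold–linear Gibbs sampler

Traits: two Gaussian (growth) and two 3-category ordinal (adult-foliage
proportion, consolidated as 1 = none, 2 = up to 50% — the boundary value 50
inclusive, a convention the source scale leaves open — and 3 = more than
50%). Fixed effects are parametrized as one cell mean per block-within-site
(the same column space as site means plus block contrasts with one level
dropped per site, full column rank by construction); plots are random with
covariance P0, additive values have covariance K ⊗ Σ, residuals R0.

**Identification.** Both thresholds are fixed (t1 = 0, t2 = 1) and the
threshold traits' residual variances are sampled — with three categories the
two fixed cut points pin location and scale. The alternative convention
(residual fixed at 1, t2 free) is not implemented; fixing both thresholds
avoids the notoriously slow mixing of threshold updates.

**Augmentation.** Every sweep draws (i) liabilities of scored records from
truncated normals conditional on the record's other traits (Robert's
exponential-rejection sampler in the tails, uniform rejection on narrow
bounded intervals), and (ii) missing trait values from the corresponding
untruncated conditionals. With complete augmented records, all three
covariance updates are conjugate inverse-Wisharts and the location sweep
needs no per-missing-pattern algebra. This full-augmentation scheme is an
exact MCMC algorithm for the same posterior as per-record conditioning of
R0; it was chosen for simplicity and kernel speed.

**Location updates** are single-site: block means (flat prior, closed-form
normal), plot effects, then additive values individual by individual over
the sparse rows of K⁻¹, each a T×T Cholesky solve. The kernels are numba
compiled and allocation-free in the hot loops. Chains are bit-reproducible
given (seed, config, inputs): one integer derived from the seed drives the
kernel RNG and a numpy Generator drives the covariance draws.

**Priors and starting values.** Fixed effects flat; Σ, P0, R0 inverse-Wishart
with df = T + 1 and scale equal to half the starting diagonals. Starting
covariances are moment-based: linear traits from the phenotypic variance;
threshold traits from the probit-scale total variance implied by the observed
category frequencies, `σ_tot = (t2 − t1)/(z(p1+p2) − z(p1))`; the total is
split 40/5/55% into additive/plot/residual. Anchoring the weak prior at the
starting scale matters: a near-zero prior scale lets a threshold trait slide
down the degenerate ridge where the residual variance collapses and h² → 1
(perfect separation of categories by the additive values), which is a prior
artefact, not information.

**Protocol.** Default chain: 300,000 samples, every 50th stored, the first
10,000 raw iterations discarded (a burn-in stated in stored samples is also
accepted). For breeding values at fixed variance components the protocol is
30,000 samples (`fixed_vc` mode). Posterior summaries (h² per Eq.
`σa²/(σa² + σp² + σe²)`, genetic correlations `σij/√(σi²σj²)`) are computed
per stored sample and then summarized by posterior mean and 95% highest
posterior density interval (shortest sorted window; at least 50 stored
samples required). For linear traits at fixed variances an exact sparse
mixed-model solve (`blup_solve`) gives the infinite-chain posterior mean and
doubles as the GLS oracle in tests.

In metafounder mode breeding values are reported for metafounders too, and
can be re-expressed against a chosen group's base (`rebase_ebv`; the natural
baseline is the oldest group).

## LR cross-validation

A focal set is masked to create the partial dataset: either the progeny (and
own records) of the top-N candidate parents ranked by phenotyped-progeny
count, or one complete trial for clone selection. Pedigree and genotypes are
never masked, only phenotypes. Statistics over the genotyped focal
individuals: ρwp (correlation of whole vs partial EBVs), bias μwp (difference
of means, expectation 0), dispersion bwp (slope of whole on partial,
expectation 1), and accuracy `√(cov(ûw, ûp)/((1 − F̄)σu²))` with F̄ the mean
focal inbreeding and σu² the whole-data additive variance. The square root
follows the LR framework's definition of the ratio as a squared accuracy; a
flag reproduces the literal unsquare-rooted ratio. "Standardized bias" is
μwp divided by the additive genetic standard deviation (overridable) — the
quantity is not uniquely defined in the validation literature and users
should check the convention before comparing across studies. Relative gains
are `(1/ρ − 1)·100` with ρwp (phenotypic information) or ρ_A,G, the
correlation between pedigree-only and genomic partial-data EBVs (genomic
information).

## Synthetic populations

The generator emulates the structure of a eucalypt improvement programme:
four base groups (two seed origins and two orchard generations) related by a
known Γ; one large OP half-sib trial whose true sires are drawn uniformly
from the dam's group and then erased from the public pedigree; five CM
full-sib trials with within-group matings; about a quarter of trees
genotyped, parents of the recent orchard nearly completely. Defaults mirror
that census (≈10,400 phenotyped, ≈2,400 genotyped at full scale; `scale`
shrinks family counts proportionally — tests use scales 0.05–0.3, i.e.
roughly 600–3,200 phenotyped trees, chosen as the package's own desk-scale
conditions).

Base allele frequencies satisfy `8·Cov_groups(p − ½) = Γ` exactly: uniform
marginals on [½ − h, ½ + h] with `h = √(3γjj/8)` (feasible for γjj ≤ 2/3)
coupled by a Gaussian copula with correlation `2 sin(πρ/6)`. Genotypes are
gene-dropped down the true pedigree, so hidden OP sires transmit gametes.
Breeding values come from 300 QTL carried on the chip, with effect vectors
linearly rescaled so the founder covariance equals Σ exactly (a pedigree
multivariate-normal mode exists for marker-free studies). Phenotypes add
site and block effects (Gaussian, sd 0.5 and 0.3), plot effects (P0) and
residuals (R0); liabilities are cut at thresholds chosen by the probit
formula from target category proportions (at 14 months most trees in
category 1, by 21 months the middle category dominant). Default targets:
h² = (0.37, 0.84, 0.53, 0.83), genetic correlations 0.51–0.97 with the
age-age foliage correlation at 0.97; Γ diagonal 0.40–0.60, off-diagonals
0.22–0.30 — plausible conventions for related eucalypt landraces, not
estimates from any dataset.

What the generator does **not** emulate: spatial autocorrelation within
trials, selection across generations, linkage/recombination structure (QTL
are in linkage equilibrium given base frequencies), genotyping error, and
pedigree errors other than missing OP sires. Passing tests therefore
demonstrate correctness of the estimation machinery under the stated
generative model, not robustness to those real-data complications.

## Numerical conventions

- Symmetry/PSD tolerances: relationship matrices validated to 1e-10;
  PSD checks at −1e-8 on eigenvalues.
- Γ inversion ridge: 1e-8, only when PSD but singular, never silent in H⁻¹.
- Truncated-normal sampling switches from naive rejection to Robert's
  exponential proposal beyond 0.3 standard deviations, and to uniform
  rejection on bounded intervals not containing the mode.
- Ties in parent ranking for validation designs break by table order
  (stable sort); category boundary ADFO = 50% maps to category 2.
- A record with all four traits missing is dropped with a warning; duplicate
  phenotype records are an error, as are plot labels spanning blocks.
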