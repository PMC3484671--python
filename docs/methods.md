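# Methods

## Relationship matrix on the identity-by-state scale

The package estimates the additive genetic covariance among lines from
marker state, without reference to an ancestral base population.  With
dosages X_ik ∈ [0, 2], allele frequencies p_k = (2n)⁻¹ Σ_i X_ik computed
from the panel itself, and the centered matrix W = X − 2p, the plain
estimator is A = WW′ / (2 Σ_k p_k q_k).  Its scaling convention is that the
mean diagonal element equals 1 + f, where f is the inbreeding coefficient
of the current population; because every column of W sums to zero, the rows
of A also sum to zero, the mean off-diagonal element is −(1+f)/n, and A has
at least one zero eigenvalue.  The singular covariance is deliberate (the
breeding values follow a singular normal) and is handled throughout by
spectral methods rather than dense inversion.

Monomorphic markers are retained: they contribute zero to both the
numerator and the denominator, so they change nothing except keeping m
honest.  Only a panel with *no* polymorphic marker is an error.

## Inbreeding coefficients

Per locus we report the standardized homozygosity excess
f_k = Σ_i (X_ik − 2p_k)² / (2 n p_k q_k) − 1, which for integer dosages is
algebraically the intra-individual gametic correlation (write X = x₁ + x₂
with binary gametes: the squared-gamete terms sum to 2 n p_k q_k and the
cross term carries the correlation).  Per individual,
φ_i = Σ_k (X_ik − 2p_k)² / (2 Σ_j p_j q_j) − 1 is exactly diag(A)_i − 1;
when all p_k = 1/2 it reduces to 2ψ − 1 with ψ the homozygous fraction.
With weights β_k = p_k q_k / Σ_j p_j q_j (zero at monomorphic loci) the two
averages coincide identically — f = Σ_k β_k f_k = n⁻¹ Σ_i φ_i = ⟨A_ii⟩ − 1 —
and this identity holds *exactly* for real-valued (mean-imputed) dosages as
well, which is why the homozygosity-excess form is used rather than a
deterministic gamete-splitting rule: splitting a fractional dosage into two
pseudo-gametes preserves the identity only when the dosages are integers,
because it needs Σ_i (x₁² + x₂²) = Σ_i X_i per column.

## Shrinkage estimator and analytic intensity

At low marker density the line covariance across loci,
S = m⁻¹WW′ − ⟨W·k⟩⟨W·k⟩′, is estimated with too few replicates (m columns
for n(n+1)/2 parameters).  The shrinkage estimator pulls S toward
T = ⟨S_ii⟩I:

A* = [δ⟨S_ii⟩I + (1−δ)S + ⟨W·k⟩⟨W·k⟩′] / (2⟨p_j q_j⟩).

Because T preserves the trace of S, tr(A*) — and therefore f — is the same
for every δ; at δ = 0 the estimator reduces *exactly* to the plain A
(algebraic identity m⁻¹WW′ = S + ⟨W·k⟩⟨W·k⟩′).  The row means ⟨W·k⟩ are
left unshrunk: they are only n parameters and are well estimated even at
96 markers.

The intensity minimizing the expected squared Frobenius error is computed
analytically (Ledoit–Wolf form, Schäfer–Strimmer estimator): with Z the
row-centered W and S = m⁻¹ZZ′,

δ = m⁻² Σ_k ‖Z·k Z·k′ − S‖² / ‖S − ⟨S_ii⟩I‖²,

with the numerator evaluated in O(n²m) via Γ = m⁻¹[Z²][Z²]′ as
m Σ_ij (Γ_ij − S_ij²).  δ is clamped to [0,1]; a zero denominator (S already
proportional to I) yields δ = 0 by convention, since shrinkage would be a
no-op.  Both the raw and clamped values are reported for diagnostics.  The
magnitude heuristic δ ~ n/(m·CV²) is exposed separately; the eigenvalue CV
uses the population (n-divisor) standard deviation over all n eigenvalues.

## GBLUP and REML

The mixed model y = μ1 + a + ε with a ~ N(0, Aσ²), ε ~ N(0, Iσe²) is
fitted by REML on the error contrasts: an orthonormal basis C of the
complement of span(1) is built once, the projected kinship C′A_ttC is
eigendecomposed, and the restricted likelihood is profiled over
λ = σe²/σ² with σ² eliminated analytically.  The search covers
ln λ ∈ [−18.4, 18.4] (λ ∈ [1e−8, 1e8]) with a 64-point grid followed by
golden-section refinement to ~1e−8; an optimum at either end, or a flat
profile (A ≈ I, where only σ² + σe² is identified), sets a boundary flag on
the results object rather than raising.  Eigenvalues of the projected
kinship below zero by round-off are clipped to zero; they represent
directions with no genetic variance and are harmless while σe² > 0.

BLUE and BLUP solutions use the eigenbasis of the training kinship —
V⁻¹ products are never formed by dense inversion:
μ̂ = (1′V̂⁻¹1)⁻¹1′V̂⁻¹y and â = σ̂²A V̂⁻¹(y − μ̂1), with the cross-covariance
rows of A giving predictions for unphenotyped lines.  `logREML` is the
log-likelihood of the orthonormal error contrasts, a quantity the test
suite reproduces independently by dense slogdet/solve grid search.

Two heritability estimators are reported: the regression form
h² = â′(y − μ̂1)/‖y − μ̂1‖², and the large-population component form
h² = σ²(1+f)/(σ²(1+f) + σe²).  The (1+f) factor reflects that the additive
genetic variance of an inbred population exceeds the relationship-matrix
coefficient σ² by exactly that factor; only the stated large-n form is
implemented, without finite-n corrections.

## Synthetic panels

`simulate_population` emulates the diagnostic profile of real breeding
panels — inbreeding level, first-principal-component fraction, eigenvalue
CV, and the shape of the off-diagonal kinship histogram — with a
three-level hierarchical allele-frequency model:

1. ancestral frequencies uniform on [maf_min, 1 − maf_min];
2. optional subpopulations: Balding–Nichols Beta with mean = ancestral
   frequency and variance = divergence·p(1−p);
3. within each subpopulation, `n_pools` drifted founder gene pools
   (Balding–Nichols again, drift `pool_divergence`), with every gamete an
   admixture of the pools through Dirichlet(`admix_alpha`) weights.

Level 3 is what gives lines *continuous relatedness variation*: without it
(genotypes drawn straight from subpopulation frequencies) an unstructured
panel has an essentially diagonal line covariance, the optimal shrinkage is
~1 at every marker density, and the density and recovery experiments are
degenerate.  Inbred lines use one weight vector for both gametes and are
fully homozygous (f = 1 exactly); outbred lines draw two independent gamete
weight vectors, giving f ≈ pool_divergence/n_pools ≈ 0.03–0.08, pig-like.
Defaults n_pools = 12, pool_divergence = 0.9, admix_alpha = 0.2 were chosen
once against the diagnostics of real panels: a 300 × 3000 unstructured
inbred panel gives f = 1.0, first PC ≈ 4%, CV ≈ 1.4 and ≈ 30% shrinkage at
384 markers (maize-like); two subpopulations at divergence 0.5 give first
PC ≈ 37%, CV ≈ 6.5, a clearly bimodal off-diagonal kinship histogram and
< 3% shrinkage (rice-like).  Note that under the pure Balding–Nichols
two-subpopulation model the first-PC fraction is ≈ F/(2−F), so divergence
0.5 — not 0.3 — is what reproduces a > 30% first PC.

Markers are resampled (up to 1000 rounds) until the *realized* panel minor
allele frequency reaches maf_min, so every marker is polymorphic by
construction.

What the generator does **not** emulate: linkage disequilibrium and genetic
maps (markers are exchangeable given the frequency hierarchy), selection,
multi-generation pedigrees, genotyping error, and ascertainment bias of SNP
arrays.  Passing tests therefore demonstrate the estimator's statistical
behavior under realistic *relatedness spectra*, not under realistic LD; on
real data the effective number of independent loci is smaller than m, which
shifts (but does not re-order) the shrinkage-versus-density curve.

Traits are simulated as a ~ N(0, A_full) (eigenvalue square root with
negative round-off clipped at zero, no renormalization; hence σ² = 1) plus
independent N(0, σe²) noise, with no fixed effect (μ = 0; the fitted model
still estimates μ).  "Phenotypic accuracy" is the realized Pearson
correlation between y and the true breeding values within a replicate — the
benchmark that GEBVs must beat to be useful.

## Experiment harnesses and problem sizes

The four harnesses mirror the standard analyses: `intensity_vs_density`
(mean analytic δ over random marker subsets per density),
`shrink_scan` (MSE = n⁻²‖A*₍sub₎ − A₍full₎‖² and GEBV accuracy over a δ
grid; argmin ties break toward smaller δ), `accuracy_vs_heritability`
(σe² = 2^u, u ~ uniform(−1, 7), results binned by realized phenotypic
accuracy into half-open bins centered on multiples of 0.1), and
`holdout_experiment` (random test fraction masked; accuracy reported
separately for phenotyped and unphenotyped lines).  Marker subsets are
drawn uniformly without replacement; all tables carry replicate counts and
standard errors (sd/√reps); everything is deterministic given the seed.

The package's own benchmark sizes are n = 300 lines with 3000–4000 full
markers, 300–384-marker subsets, 20–40 replicates per scan and 300–500
simulations per heritability sweep — large enough that the qualitative
ordering of estimators is stable across seeds, small enough to run on a
laptop in about a minute.  The heritability sweep's bin means are noisier
at the extreme bins (few simulations land below phenotypic accuracy 0.1);
monotonicity assessments use bins with at least 20 observations.

## Known limitations

- One fixed effect (the intercept) only; no covariates or multi-trait
  models.
- The shrinkage target is ⟨S_ii⟩I; alternative targets (e.g. pedigree
  matrices) are not implemented.
- UAR-style standardized-coefficient estimators and dominance/epistatic
  relationship matrices are out of scope.
- VCF/PLINK/HapMap parsing is out of scope; genotypes are plain delimited
  dosage tables.
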