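# shrinkgrm

Shrinkage estimation of the realized (genomic) relationship matrix, with
GBLUP breeding-value prediction and a simulation harness — for plant and
animal breeders and quantitative geneticists working with bi-allelic marker
panels, especially *low-density* panels (e.g. 384-SNP arrays) where the
number of lines can exceed the number of markers.

## The model

For an *n* × *m* dosage matrix **X** (lines × markers, dosages 0/1/2), let
p_k be the allele frequency of marker *k* and **W** = **X** − 2**p** the
centered genotype matrix.  The realized additive relationship matrix on an
identity-by-state scale, with the current population as reference, is

```
A  =  W W′ / (2 Σ_k p_k q_k),        q_k = 1 − p_k,
```

scaled so that the mean diagonal element equals 1 + *f*, where *f* is the
population inbreeding coefficient (*f* ≈ 1 for inbred lines, ≈ 0 for
outbred populations).  This is the right estimator when markers are dense
(*m* ≫ *n*).

At low marker density, the line-by-line covariance across loci,
S = m⁻¹WW′ − ⟨W·k⟩⟨W·k⟩′, is a noisy estimate of its genome-wide
counterpart.  Shrinking it toward the trace-preserving target T = ⟨S_ii⟩I
gives the shrinkage estimator

```
A* =  [ δ⟨S_ii⟩ I  +  (1 − δ) S  +  ⟨W·k⟩⟨W·k⟩′ ]  /  (2⟨p_j q_j⟩),
```

whose trace — hence the inbreeding coefficient — is identical for every
δ ∈ [0, 1].  The intensity δ is computed analytically (Ledoit–Wolf /
Schäfer–Strimmer form) to minimize the expected mean-squared error of the
covariance estimate; the heuristic δ ~ n/(m·CV²) (CV = coefficient of
variation of the eigenvalues of S) explains when shrinkage matters:
unstructured populations with few markers need it, structured populations
(high eigenvalue dispersion) do not.

Breeding values are predicted with the mixed model y = μ**1** + **a** + ε,
**a** ~ N(0, A σ²), ε ~ N(0, I σe²), fitted by REML through a spectral
(eigendecomposition) algorithm that profiles the variance ratio
λ = σe²/σ².  Heritability is reported both as the regression form
h² = â′(y − μ̂1)/‖y − μ̂1‖² and the large-population component form
h² = σ²(1+f) / (σ²(1+f) + σe²).

## Worked example

200 simulated inbred lines with a 2000-marker reference panel; a trait with
σ² = 1, σe² = 3 is simulated from the full-marker relationship matrix, and
prediction is done with a random 384-marker subset:

```python
import numpy as np
import shrinkgrm as sg

panel = sg.simulate_population(sg.PopSimConfig(n_lines=200, n_markers=2000, seed=7))
A_full = sg.kinship_plain(sg.center_genotypes(panel))
trait = sg.simulate_trait(A_full, sigma_e2=3.0, seed=8)

rng = np.random.default_rng(9)
subset = rng.choice(2000, size=384, replace=False)
G384 = sg.GenotypeMatrix(panel.values[:, subset], panel.line_ids,
                         [panel.marker_ids[j] for j in subset])
C = sg.center_genotypes(G384)
print(f"analytic shrinkage intensity: {sg.shrinkage_intensity(C).delta:.3f}")

res = sg.GBLUP(trait.y, sg.kinship_shrunk(C, delta="auto")).fit()
print(res.summary())
print(f"GEBV accuracy (shrunk):   {sg.accuracy(res.gebv, trait.a_true):.3f}")
res0 = sg.GBLUP(trait.y, sg.kinship_shrunk(C, delta=0.0)).fit()
print(f"GEBV accuracy (unshrunk): {sg.accuracy(res0.gebv, trait.a_true):.3f}")
```

Output:

```
analytic shrinkage intensity: 0.329
GBLUP mixed-model fit (REML, spectral algorithm)
================================================
training lines            200
mu_hat                    -0.0774451
sigma2 (genetic)           1.23423
sigma_e2 (residual)        2.66389
lambda = sigma_e2/sigma2   2.15835
log restricted likelihood -439.738
f (from kinship)           1
h2 (regression form)       0.480225
h2 (variance components)   0.48096
GEBV accuracy (shrunk):   0.667
GEBV accuracy (unshrunk): 0.650
```

With 384 of 2000 markers on this unstructured inbred panel the analytic
intensity is ≈ 0.33, the fitted variance components are close to the
simulated (σ² = 1, σe² = 3) after accounting for the subset's sampling
error, both heritability estimators agree (≈ 0.48), and shrinkage improves
the correlation between predicted and true breeding values for these
phenotyped lines from 0.650 to 0.667.

## Command line

The same workflow is available as a console script:

```bash
shrinkgrm --seed 1 simulate pop --n 200 --m 2000 --out panel.csv
shrinkgrm kinship --genotypes panel.csv --method shrunk --delta auto \
    --out A.csv --report-inbreeding inbreeding.csv
shrinkgrm --seed 2 simulate trait --kinship A.csv --sigma-e2 3 --out trait.csv
shrinkgrm predict --genotypes panel.csv --phenotypes pheno.csv \
    --predict-all --out gebv.csv
shrinkgrm --seed 3 experiment shrink-scan --config scan.cfg --out scan.csv
```

Each command writes a diffable `<out>.meta.txt` sidecar with the run summary
(δ, f, variance components, heritabilities).  Experiment configs are plain
`key = value` text; see `shrinkgrm experiment --help`.

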