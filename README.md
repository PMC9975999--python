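# twinfear

Twin-pair variance decomposition of differential fear-conditioning
phenotypes: a tested pipeline from trial-level expectancy ratings to
trivariate ACE/AE Cholesky models fitted by full-information maximum
likelihood (FIML), with a synthetic twin-data generator for calibration and
parameter-recovery studies.

## The scientific problem

Fear conditioning is a laboratory model for the development (acquisition)
and treatment-driven recovery (extinction) of anxiety. Participants see two
neutral stimuli; one (CS+) is paired with an aversive noise on 75% of its 12
acquisition presentations, the other (CS−) never is. In a later extinction
phase both appear 18 times without the noise. On every trial participants
rate, on a 1–9 scale, how much they expect the noise. Discriminative
learning is indexed by **differential scores** — the CS+ minus CS− mean
rating over a trial window:

- *initial development*: first third of acquisition (trials 1–4 per stimulus),
- *consolidation*: last third of acquisition (trials 9–12),
- *extinction*: first third of extinction (trials 1–6).

Administering this task to monozygotic (MZ) and dizygotic (DZ) twins lets
the phenotypic variance of each score, and the covariance between scores, be
decomposed into additive-genetic (A), shared-environment (C) and non-shared
environment (E) components: MZ twins share all segregating genes, DZ twins
about half, and both share their rearing environment, so the excess MZ
resemblance identifies A.

## The model

For the trait vector **y** = (initial, consol, extinct), each component
covariance matrix is parameterized by its Cholesky factor, e.g.
**A** = **L**<sub>A</sub>**L**<sub>A</sub>ᵀ, guaranteeing positive
semi-definiteness. A twin pair's stacked 6-vector is multivariate normal
with within-twin covariance **Σ**<sub>W</sub> = **A** + **C** + **E** and
cross-twin covariance α**A** + **C**, α = 1 (MZ) or ½ (DZ). Families with a
missing co-twin or missing phenotypes contribute the density of their
observed subvector (FIML), so singletons enter naturally. The fitted model
is re-expressed as the **correlated factors solution**: standardized
variance components a², c², e² per trait, component correlation matrices
r<sub>A</sub>, r<sub>C</sub>, r<sub>E</sub>, and the split of each
phenotypic correlation into A/C/E contributions
(e.g. √a²<sub>i</sub>·r<sub>A,ij</sub>·√a²<sub>j</sub>). ACE vs AE is
compared by likelihood ratio (χ², 6 df) and AIC; confidence intervals are
percentile bootstrap over families, stratified by zygosity.

Raw trial data are first passed through compliance exclusions (headphones
removed, volume below 50%, app exited), score derivation, ordinary
least-squares residualization on age and sex (which otherwise inflate twin
correlations), and a signed square-root transform sign(x)·√|x|.

## Worked example

```python
import twinfear as tf

model = tf.paper_generating_model()      # AE truth: a2=(0.15, 0.29, 0.15)
table = tf.simulate_twin_phenotypes(model, seed=1)   # 250 MZ + 288 DZ pairs + 860 singletons

fit_ae  = tf.fit_model(table, "AE")
fit_ace = tf.fit_model(table, "ACE")
cmp = tf.compare_models(fit_ace, fit_ae)
sol = tf.standardize(fit_ae.params, fit_ae.spec)

print("a2 =", sol.a2.round(3), " e2 =", sol.e2.round(3))
print("rA(init,consol) =", round(sol.rA[0, 1], 3))
print("AE vs ACE: chi2=%.2f df=%d p=%.3f dAIC=%.2f"
      % (cmp["chi2"], cmp["df"], cmp["p"], cmp["delta_AIC"]))
```

prints

```
a2 = [0.225 0.316 0.101]  e2 = [0.775 0.684 0.899]
rA(init,consol) = 0.941
AE vs ACE: chi2=0.57 df=6 p=0.997 dAIC=-11.43
```

One simulated dataset at this sample size recovers the generating
heritabilities with sampling error of a few points (here 0.23/0.32/0.10
against the generating 0.15/0.29/0.15), estimates a near-unit genetic
correlation between the two acquisition phenotypes, and — since the data
carry no shared-environment signal — prefers the parsimonious AE model by
AIC (ΔAIC < 0) with no loss of fit (p = 0.997).

The same pipeline runs from the shell:

```sh
twinfear simulate --preset paper --seed 1 --out sim/
twinfear fit --phenotypes sim/phenotypes.csv --model both --boot 100 --seed 7 --out fit/
twinfear run --config run.yaml        # end-to-end with manifest
```

`run.yaml` (exactly one input source — files or generator):

```yaml
generator: {preset: paper, seed: 1, trial_level: false}
model: both
bootstrap: {n_iter: 100, seed: 7, level: 0.95}
seed: 1
out: results/
```

Trial-level CSVs use columns
`participant_id,phase,stimulus,trial_index,rating,reinforced`; the roster
uses `participant_id,family_id,zygosity,sex,age,excluded_headphones,
excluded_volume,excluded_exit`; family-wide phenotype tables use
`family_id,zygosity,t1_initial,...,t2_extinct`.

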