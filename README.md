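# oilbiodeg

Detection of methanogenic hydrocarbon degradation in subsurface
oil-reservoir samples.

Archaea of the candidate genus *Ca.* Methanoliparum couple long-chain
alkane degradation and methane production within a single cell
("alkylotrophic methanogenesis"), without the syntrophic bacterial
partner classically assumed for methanogenic oil biodegradation.
Surveying reservoirs for this process means combining several
independent lines of evidence per sample, each with its own bespoke
computation.  This package implements those computations as a tested,
reusable pipeline for geomicrobiologists and petroleum microbiologists:

* **Chromatogram scoring** (`oilbiodeg.chromatogram`) — grades GC–MS
  total ion chromatograms on the ordinal biodegradation scale 0–4 from
  the unresolved-complex-mixture (UCM) index, the diagnostic ratios
  nC17/pristane and nC18/phytane, and the surviving n-alkane count.
* **Alkyl-CoM MRM screening** (`oilbiodeg.alkylcom`) — builds the
  theoretical MRM transition list for the alkyl-coenzyme M homolog
  series C4–C28 from the generalized fragment-mass formula
  m/z = 12.00055·n + 1.00837·(2n+1) + 79.9 (product ions HSO₃⁻ 80.9,
  C₂H₃SO₃⁻ 106.9, CnH₂n₊₁SO₃⁻), matches observed transitions, applies
  the strict > 2000 intensity threshold on the bisulfite ion pair, and
  reports the per-sample homolog *variety*.
* **Abundance & activity** (`oilbiodeg.abundance`) — qPCR absolute
  quantification through a log-linear standard curve (copies per gram of
  sample), amplicon target-feature fractions, length-normalized MAG
  transcript activity, and gene-level FPKM.
* **Integration & statistics** (`oilbiodeg.integrate`) — classifies each
  sample into the four co-occurrence evidence groups (16S presence ×
  *acrA* transcription × alkyl-CoM detection), summarizes detection
  proportions by degradation degree and oilfield, and fits the
  transformed ridge regression
  Y = X⊤β + k with Xᵢ = ln(FPKM + 1) and Yᵢ = logit((degree + ½)/5),
  quantifying whether the archaeal (*acrA*) or the pooled bacterial
  fumarate-addition (*assA*/*bssA*/*nmsA*) term tracks degradation.
* **Synthetic data** (`oilbiodeg.synthetic`) — generates every pipeline
  input with known ground truth: chromatograms built to satisfy the
  diagnostic criteria of a requested degree, MRM runs with planted
  homologs and mass-disjoint decoys, and molecular profiles
  statistically coupled to the degree.

## Worked example

```python
import oilbiodeg as ob
from oilbiodeg.integrate import fit_ridge, transform_xy

# 1. grade a simulated moderately degraded oil (degree 3)
chrom, truth = ob.simulate_chromatogram(degree=3, seed=42)
score = ob.score_chromatogram(chrom)
d = score.diagnostics
print(f"degree={score.degree}  ucm_index={score.ucm_index:.3f}  "
      f"nC17/Pr={d.c17_pr_ratio:.2f}  nC18/Ph={d.c18_ph_ratio:.2f}  "
      f"surviving n-alkanes={d.n_alkanes_present}")

# 2. screen an MRM run for alkyl-CoM homologs
obs = ob.simulate_mrm_run(planted={13, 16, 18, 20}, intensity=5200.0,
                          decoy_count=10, seed=42)
result, hits = ob.screen(obs)
print(f"variety={result.variety}  chains={sorted(result.detected_chain_lengths)}")

# 3. ridge regression of degradation degree on gene expression
sim = ob.simulate_expression(seed=42)   # truth: beta=(0.01, 0.86), intercept 0.49
t = transform_xy(sim.fpkm, sim.degrees)
fit = fit_ridge(t, penalty=1e-3)
print(f"beta_bacterial={fit.beta[0]:.3f}  beta_acrA={fit.beta[1]:.3f}")
```

prints

```
degree=3  ucm_index=0.782  nC17/Pr=0.36  nC18/Ph=0.32  surviving n-alkanes=3
variety=4  chains=[13, 16, 18, 20]
beta_bacterial=0.014  beta_acrA=0.139
```

The degree-3 trace shows a pronounced UCM (78% of trace area), both
diagnostic ratios below 1, and near-total n-alkane loss — exactly the
moderate-degradation signature.  The screen recovers the four planted
homologs and none of the ten decoys.  In the regression the *acrA*
coefficient dominates the bacterial one; quantizing the response to
integer degrees attenuates the coefficients, so fitting the underlying
continuous response (``sim.latent_response``) recovers the simulation
truth itself: β = (0.022, 0.858), intercept 0.461.

A command-line interface mirrors the stages:

```sh
oilbiodeg simulate --n-samples 50 --seed 1 --outdir study/
oilbiodeg score study/chromatograms/*.tsv
oilbiodeg screen study/mrm/*.csv --threshold 2000
oilbiodeg quantify --qpcr study/qpcr.csv
```

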