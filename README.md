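# ramanmuscle

Analysis of fiber-optic Raman spectra of dystrophic muscle: spectral
preprocessing, PCA-fed linear discriminant analysis, hierarchical (nested)
inference, and windowed cosine similarity between cohorts — plus a
synthetic-cohort generator with ground truth so the whole chain is testable
without instrument data.

## The problem

In vivo intramuscular Raman spectroscopy reads out the biochemical state of
muscle through a needle-housed fiber probe: a molecular fingerprint of
protein secondary structure, nucleic acids and lipids in the 900–1800 cm⁻¹
region. In the *mdx* mouse model of Duchenne muscular dystrophy, bursts of
voluntary wheel running exacerbate muscle necrosis toward the human
phenotype. The analytical question is whether spectra can (1) discriminate
exercised from unexercised dystrophic muscle, (2) track a graded exposure
(distance run), and (3) quantify whether exercise moves mouse spectra closer
to human dystrophic muscle.

The data are hierarchical — four spectra per mouse (both gastrocnemius
heads, both hindlimbs), 15 mice per group — so spectrum-level inference
would pseudo-replicate; the package's inference stage tests group effects
against between-mouse variation.

## The method

1. **Preprocess** each spectrum: window to 900–1800 cm⁻¹ on a 1 cm⁻¹ grid,
   Savitzky-Golay smooth (order 2, 9 points), subtract an airPLS baseline
   (iteratively reweighted Whittaker smoother, λ = 10⁵), SNV-normalize.
2. **Discriminate**: mean-center, PCA; Welch t-tests on the first 10 PC
   score columns with Benjamini–Hochberg FDR at Q = 0.01 select the
   components; Fisher's two-class discriminant w ∝ S_w⁻¹(μ₂−μ₁) on the
   selected scores gives per-spectrum LDF scores, and back-projection
   through the PCA loadings gives the LDF loading — a pseudo-spectrum of
   discriminating bands.
3. **Infer**: nested t-test of LDF scores (spectra nested within mice;
   one-way nested ANOVA, F on (1, S−2) df), and Pearson correlation of
   per-mouse mean scores with distance run.
4. **Compare cohorts**: cosine similarity between mean spectra in nine
   100 cm⁻¹ windows.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import ramanmuscle as rm

cohort, truth = rm.generate_cohort(rm.default_config(seed=1),
                                   ["unexercised", "exercised"])
matrix = rm.preprocess_cohort(cohort)                 # 120 x 901
pca, model = rm.fit_pipeline(matrix)                  # PCA -> FDR -> LDA
res = rm.nested_ttest(model.scores, matrix.subject_ids, matrix.group_labels)
print(f"F(1, {res.df_within}) = {res.f_statistic:.1f}, p = {res.p_value:.3g}")
```

prints

```
F(1, 28) = 553.2, p = 5.54e-20
```

— the exercised/unexercised separation of discriminant scores tested against
between-mouse variation on 28 degrees of freedom (30 mice − 2). On the same
cohort, per-mouse mean LDF scores track the distance each mouse ran
(`rm.correlate_covariate`: r = 0.935, p = 3.3e-07), and the LDF loading's
strongest positive bands sit at 905, 930, 1025, 1045, 1059, 1095, 1220,
1610 and 1642 cm⁻¹ with the most negative at 956 cm⁻¹ — recovering the
band-level changes the generator injected. The `examples/` scripts walk
through each capability (simulation, preprocessing, discrimination,
inference, similarity, and a checksummed end-to-end run) and print the
numbers with one-line interpretations.

A thin CLI mirrors the stages:

```sh
ramanmuscle simulate --seed 1 --out cohort.csv
ramanmuscle preprocess cohort.csv --out processed.csv
ramanmuscle fit processed.csv --out-prefix model
ramanmuscle stats model.scores.csv --out stats.csv
ramanmuscle run --seed 1 --outdir run-output     # everything, checksummed
```

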