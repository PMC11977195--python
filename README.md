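# cortexdev

Analysis pipeline for studying how the cellular composition of the human
cortex changes across childhood and adolescence, by joining three strands of
evidence that are usually analysed separately:

1. **In-vivo microstructure.** Network-averaged diffusion-MRI metrics from
   biophysical models of grey matter — neurite, soma and extracellular signal
   fractions, the apparent soma radius `R_soma`, NODDI and DTI metrics —
   together with cortical morphology (thickness, surface area, volume),
   analysed with standardized general linear age models, AIC model selection
   and test-retest ICC(2,1).
2. **Post-mortem transcriptomics.** Per-gene developmental expression
   trajectories fitted with penalized regression splines (k = 5 basis,
   curvature penalty), age-gene discovery under Benjamini–Hochberg FDR,
   cross-dataset replication, cell-type mean trajectories, peak-growth ages,
   the astrocyte-to-oligodendrocyte expression crossover per region, and
   Fisher-exact gene-set enrichment.
3. **Composition simulation.** A voxel of grey matter as a mixture of cell
   populations with Gaussian radius distributions; the MR apparent soma
   radius of the mixture is moment-weighted,
   `R_soma = sqrt(E[R^5] / E[R^3])`, and cell counts are coupled to age
   through per-type fractional slopes so the simulation predicts the
   developmental trend of `R_soma`.

Because the cohorts and tissue banks behind such studies are not freely
redistributable, the package includes a first-class synthetic-data module
(`cortexdev.synthetic_data`) that generates every pipeline input with the
statistical structure the analyses assume: an imaging cohort of 88 subjects
aged 8–19 y with a packaged effect-size configuration, a 6 × 5 repeatability
table with known variance components, and two bulk expression datasets (a
single-region normalized dialect with n = 214 samples, and a multi-region
log2-RPKM dialect with 20 donors × 11 cortical regions, donor random
effects, sex and RNA-integrity covariates). Every generator is seeded and
byte-reproducible, so all downstream estimators can be validated against
known generating values.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
and write their tables under `results/analysis/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_network_age_models.py
python analysis/03_repeatability_icc.py
python analysis/04_expression_trajectories.py
python analysis/05_soma_composition.py
```

`02_network_age_models.py` prints the strongest standardized age effects,
e.g.

```
48/77 network-metric age effects significant at p<0.005

strongest standardized age effects (beta [95% CI], adjusted R^2):
         f_neurite somatomotor       +0.82 [+0.70, +0.94]  R2=0.67
         f_neurite visual            +0.78 [+0.65, +0.91]  R2=0.61
              v_ic limbic            +0.78 [+0.64, +0.91]  R2=0.60
```

i.e. the neurite signal fraction rises steeply with age in every network
while thickness, soma fraction and apparent soma radius decline — exactly
the structure the generator was configured to produce, recovered by the
standardized fits. `04_expression_trajectories.py` reports the
transcriptomic side:

```
age-genes: 166/210 in the discovery set; 44 replicated in the 20-donor
validation set (26.5%)
regional oligodendrocyte timing (earliest to latest crossover):
      S1: crossover 23.4 y ...
     MFC: crossover 28.2 y ...
```

showing the sensorimotor-to-association gradient: the
oligodendrocyte-over-astrocyte expression crossover arrives years earlier in
primary motor/visual cortex than in medial frontal cortex. And
`05_soma_composition.py` propagates an oligodendrocyte-dominant composition
shift through the moment formula, printing the baseline apparent radius
(9.24 µm — far above the count-weighted mean radius, because the fifth/third
moment ratio is dominated by the largest cells) and a small negative percent
change over ages 8–19.

The same stages are available as a CLI (`cortexdev run-all --seed 1 --out
results/pipeline`, plus per-stage subcommands) with YAML configuration and a
manifest recording the config hash of every output.

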