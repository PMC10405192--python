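# ansbr

Performance, settleability and microbiome analytics for **anaerobic
sequencing batch reactors (AnSBR)** treating high-strength, protein-rich
wastewater (e.g. slaughterhouse effluent).

An AnSBR line — buffer tank, reactor, settling tank, run in fill/react/
settle/decant cycles — is monitored through routine chemistry (COD, solids,
nitrogen, VFA, biogas), batch settling tests and 16S amplicon sequencing.
`ansbr` turns those raw observations into the standard process indicators
and community statistics an operator or researcher reports:

* **Loading and retention** — OLR = C_TCOD·Q / V_r (g COD L⁻¹ d⁻¹),
  SLR = OLR / X_VSS, HRT = V/Q, SRT = M_sludge / M_wasted.
* **Conversion efficiencies** — COD removal 100·(C_in − C_out)/C_in;
  acidification degree 100·VFA_COD/COD_ref; ammonification efficiency
  100·NH₄⁺-N/TKN (a proxy for protein degradation); and the COD-to-methane
  conversion efficiency 100·(CH₄ production as g COD d⁻¹)/(COD fed, g COD
  d⁻¹), with gas volumes converted through the ideal-gas law and the
  stoichiometric 64 g COD per mol CH₄.
* **Settleability** — the Vesilind hindered-settling model *v = v₀·e^(−kX)*
  fitted by its standard log-linear form; settling-distance summaries at
  15/30/45/90/120 min; particle-size-distribution binning.
* **Microbiome** — rarefaction (multivariate hypergeometric), relative
  abundance by rank, observed-ASV richness and Shannon *H = −Σ pᵢ ln pᵢ*,
  unweighted UniFrac, classical PCoA, and a bootstrap core-microbiome
  detector: resample the samples with replacement 1000×, call an ASV *core*
  when it is present in every drawn sample in ≥ 95 % of resamples.
* **Correlation layer** — Pearson r with t-distribution p-values and the
  four-level banding (none / |r| ≤ 0.30 low / ≤ 0.60 moderate / ≤ 1.0 high
  at p ≤ 0.05), and single-factor PERMANOVA of the UniFrac distance matrix
  against operational covariates (Anderson's pseudo-F, permutation p, R²).

A `synthetic` module generates complete study-shaped datasets (reactor time
series inside realistic influent envelopes, settling curves from known
Vesilind parameters, Dirichlet-multinomial ASV tables with a planted core
and a planted community–covariate association), so the entire pipeline is
testable end-to-end without any external data.

## Worked example

Generate a 60-day synthetic campaign and run the full pipeline:

```bash
ansbr simulate --seed 1 --out demo --days 60
cat > demo/config.yaml <<'YAML'
parameters: {rarefaction_depth: 5000, core_resamples: 1000}
inputs:
  measurements: demo/measurements.csv
  operations:   demo/operations.csv
  settling:     demo/settling.csv
  counts:       demo/counts.tsv
  taxonomy:     demo/taxonomy.tsv
  tree:         demo/tree.nwk
  covariates:   demo/covariates.csv
YAML
ansbr report --config demo/config.yaml --out demo/report --seed 1
# -> report written to demo/report (11 tables)
```

`demo/report/phase_summary.csv` then contains per-phase means ± sample SD,
e.g. for the 60-day run (phases I and the start of II):

```
phase,metric,mean,sd,n
I,olr,1.8000000000000003,2.6272671962866383e-16,56
I,tcod_removal,77.97632920060083,0.9672318236430751,56
I,codch4_efficiency,77.73974522111642,3.2597123703205235,56
```

i.e. the start-up phase ran at an OLR of 1.8 g COD L⁻¹ d⁻¹ and recovered
the generator's planted 78 % TCOD removal and 79 % COD-to-CH₄ conversion
within sampling noise, and `demo/report/vesilind_fit.csv` holds the fitted
(v₀, k) of the settling tests. `core_microbiome.csv` lists every ASV's
bootstrap prevalence fraction with the ≥ 0.95 core flag, and
`permanova_table.csv` gives R² and the permutation p for each covariate.

Library use mirrors the CLI:

```python
from ansbr import fit_vesilind, predict_zsv
fit = fit_vesilind([(2, 0.89), (4, 0.66), (6, 0.49), (8, 0.36)])
print(round(fit.v0, 2), round(fit.k, 3))   # 1.21 0.151
```

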