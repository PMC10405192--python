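# Methods

This note documents the models behind `ansbr`, the choices made where the
underlying definitions are open, and what the synthetic-data tests do and do
not demonstrate.

## Reactor performance metrics

All indicators are pointwise algebraic transforms of daily observations;
there is no process model (no ADM1-style simulation) and no interpolation of
missing measurements — gaps propagate as missing values.

* **OLR** (g COD L⁻¹ d⁻¹) = influent TCOD (mg L⁻¹ / 1000) × fed volume
  (L d⁻¹) / reactor working volume (L). **SLR** divides OLR by the reactor
  VSS concentration (g L⁻¹). **HRT** = tank volume / daily flow; the buffer
  tank's HRT uses the buffer-tank volume. **SRT** = total sludge mass (g) /
  daily wastage (g d⁻¹).
* **Removal efficiency** = 100·(influent − effluent)/influent. Effluent
  above influent yields a *negative* value that is reported, never clipped:
  silently clipping would break COD mass-balance audits.
* **Acidification degree** = 100·VFA (as COD)/reference COD. The reference
  may be the raw influent (default) or the buffer-tank liquid — the
  underlying definition ("from the influent TCOD or SCOD") does not pin the
  denominator down, so both are supported via
  `acidification_reference_tank`.
* **Ammonification efficiency** = 100·NH₄⁺-N/TKN, the standard proxy for
  protein-degradation extent. NH₄⁺-N above TKN is physically inconsistent
  but possible through assay noise; values > 100 % are returned with a
  warning.
* **COD-to-CH₄ conversion efficiency** = 100 × (CH₄ production, g COD d⁻¹)
  / (COD fed, g COD d⁻¹). Gas meters report volume, so the CH₄ volume
  (biogas volume × CH₄ fraction) is converted to moles by the ideal-gas law
  at a configurable reference state — default 273.15 K and 1 atm — and each
  mole of CH₄ counts as 64 g COD (CH₄ + 2 O₂ → CO₂ + 2 H₂O, 2 × 32 g O₂).
  This conversion scales *every* efficiency value, which is why the
  reference state is an explicit `ReactorConfig` field rather than a
  constant. The equivalent mass factor is 64/16.043 ≈ 3.99 g COD per g CH₄;
  for reference, full oxidation of glucose gives 6·32/180.16 ≈ 1.07 ≈ 1.1 g
  COD per g, consistent with the conventional carbohydrate factor (1.1),
  while the protein factor (1.5 g COD per g BSA) is empirical.
* **Phase aggregation** uses the arithmetic mean ± *sample* standard
  deviation (ddof = 1); a single observation reports sd = 0 with n = 1.
  The default phase windows are I = days 0–55 (start-up), II = 56–196
  (stable operation), III = 197–260 (loading increase). Windows are closed
  intervals given in whole days; a fractional day between two windows
  belongs to the phase of its whole day, and a day on a shared boundary to
  the earlier phase. Zero-feed days have no loading or efficiency entries
  and therefore drop out of phase means.

## Settling and particle size

The zone settling velocity follows the Vesilind model v = v₀·e^(−kX), with
v₀ (m h⁻¹) the unhindered settling velocity, k (L g⁻¹ TSS) the
compressibility factor and X the sludge concentration. Fitting uses the
standard linearisation ln v = ln v₀ − kX by ordinary least squares: it is
deterministic, exact on noiseless data (which makes parameter recovery
testable to machine precision), and unbiased when measurement noise is
multiplicative. A nonlinear refinement on the untransformed scale is
available behind `nonlinear_refine=True` for users who prefer weighting
large velocities more heavily. The fit requires at least two distinct
concentrations and strictly positive velocities.

Settling-distance tests record interface depth at checkpoints (default 15,
30, 45, 90, 120 min); depth is interpolated linearly between sampled times,
each checkpoint is expressed as a fraction of the final settled distance,
and the final distance as a fraction of the column height. A trajectory that
never moves, or ends at zero depth, is flagged degenerate rather than
producing fractions of a zero denominator.

PSD volume fractions are summed into half-open bins [lo, hi) with default
edges 1, 30, 300, 600 µm; prose bounds like "1 µm < d < 30 µm" are ambiguous
at the edges, so the half-open convention (boundary diameter → upper bin) is
fixed, documented and configurable. Mass outside the outermost edges is
reported separately so the output always sums to the input mass.

## Microbiome statistics

* **Rarefaction** subsamples each sample *without replacement* to the target
  depth (default 50 000 counts), i.e. one multivariate-hypergeometric draw
  per sample, seeded; samples below the depth are dropped with a warning.
* **Shannon index** uses the natural logarithm by default (values around
  4.0–4.3 on anaerobic-digester communities of several hundred ASVs are
  natural-log scaled); the base is configurable.
* **Unweighted UniFrac** between two presence sets is the branch length
  leading exclusively to one set's taxa divided by the branch length leading
  to either set's taxa, computed by one post-order traversal that records
  which query taxa descend from every branch. Zero-length branches
  contribute zero to numerator and denominator alike. The supplied tree is
  used as-is and must be rooted with the relevant ASVs as leaves. The
  matrix variant computes branch descendancy once and reuses it for all
  sample pairs.
* **PCoA** is classical metric scaling: Gower-centre the squared distances,
  eigendecompose, order axes by eigenvalue and scale by √λ. Negative
  eigenvalues (non-Euclidean distances) are reported and their axes dropped;
  explained proportions are taken over the positive spectrum only.
* **Core microbiome** is detected by bootstrap over *samples*: each of
  1000 resamples draws n sample ids with replacement; an ASV "prevails" in a
  resample when its count is positive in every drawn sample, and the core is
  the set of ASVs prevailing in ≥ 95 % of resamples. The resample size
  equals the number of samples. An ASV present everywhere prevails with
  probability 1 regardless of seed; an ASV absent from even one of n
  samples prevails with probability at most ((n−1)/n)ⁿ ≤ 1/e ≈ 0.368, far
  below the 0.95 threshold — the exact reference value (11/12)¹² ≈ 0.352
  for one absence among 12 samples is used as a calibration oracle in the
  tests. Core detection defaults to rarefied counts (prevalence should not
  reflect unequal sequencing effort); raw counts can be passed instead.

## Correlation layer

Pearson r uses pairwise deletion of missing values and a two-sided p from
the t-distribution with n − 2 df (≥ 3 complete pairs required). Series
measured on different days are aligned by a nearest-day join within ± 2 days
(configurable), reflecting irregular weekly/biweekly sampling. The banding
scheme maps p > 0.05 to "none", then |r| ≤ 0.30 / ≤ 0.60 / ≤ 1.0 to low /
moderate / high; published band edges (0.30 vs 0.31) leave the open interval
between them undefined for continuous r, so the bands are treated as
half-open at 0.30 and 0.60, documented and configurable. No
multiple-testing correction is applied.

PERMANOVA is the single-term distance-based linear model: with squared
distances Gower-centred to G and a hat matrix H from an intercept plus the
covariate (standardised if continuous, dummy-coded if categorical),
SS_model = tr(HG), SS_total = tr(G), R² = SS_model/SS_total and the
pseudo-F uses (m − 1, n − m) degrees of freedom. Significance permutes the
sample labels of G; p = (1 + #{F* ≥ F}) / (1 + n_permutations) with 999
permutations by default. When n! does not exceed the requested permutation
count (n ≤ 7 in practice) the test enumerates all relabelings and the p is
exact. Each covariate is tested marginally, one factor at a time.

## Synthetic data

The generators invert the metric definitions above — they emulate the
*structure* of an AnSBR monitoring campaign, not digestion biology.

* **Reactor time series.** Daily influent concentrations are uniform inside
  a protein-rich wastewater envelope (TCOD 4700–6500, SCOD 1500–3800,
  NH₄⁺-N 175–420, protein 500–1150, carbohydrate 100–250, FOG 100–600
  mg L⁻¹). Each phase fixes a true OLR (1.8 / 2.0 / 3.2 g COD L⁻¹ d⁻¹),
  removal, ammonification and COD-to-CH₄ efficiencies, sludge inventory and
  SRT; the feed volume is back-computed from the OLR target, and effluent,
  NH₄⁺ and biogas values from the truths. Measurement noise is
  multiplicative lognormal with unit mean (σ = 0.05 by default) so phase
  means stay unbiased; CODs and gas are daily, nitrogen and VFA weekly.
  At σ = 0 the pipeline inverts the generator exactly — the principal
  end-to-end test.
* **Settling curves** draw v from the Vesilind model with noise applied in
  log space (where the fit is linear) and integrate the interface downwards
  until a hindered plateau at 45 % of the column height.
* **ASV tables** are Dirichlet-multinomial (concentration 200) over three
  ASV classes: a planted **core** at 1–5 % baseline relative abundance
  (present in every sample by construction), low-abundance **responders**
  whose log-abundance shifts by effect × covariate × (±1) and whose
  expected count at the sequencing depth is O(1) — so the covariate moves
  their presence/absence, which is the only signal unweighted UniFrac can
  see — and **background** ASVs subject to an independent per-sample
  structural dropout (probability 0.5), guaranteeing each is absent
  somewhere with high probability, the regime in which bootstrap core
  detection is exact. The "large" effect size is 2.0 on the log scale; 0
  gives the null. The phylogeny is a random coalescent-like topology with
  exponential branch lengths so UniFrac tests sweep tree space; taxonomy
  labels cycle through digester-typical phyla and genera with ~10 %
  unassigned.

**What the tests show — and don't.** Passing the recovery tests shows the
estimators correctly invert their own definitions under the stated noise
model; it does not validate the lognormal noise assumption, the
independence of daily measurements, or any biological claim. Real campaigns
have autocorrelated upsets, feed interruptions and compositional drift the
generators do not emulate. Problem sizes in the test-suite and acceptance
script are scaled down from a full campaign (sequencing depth ~5000 of 80
ASVs over 12 samples instead of 50 000-count libraries of thousands of
ASVs; 200 null PERMANOVA replicates at 999 permutations) — sizes chosen so
the statistical assertions retain power while the whole suite stays quick to
run; the statistics themselves are size-agnostic.

## Numerical choices and limitations

* Ideal-gas constant 0.0820574 L atm mol⁻¹ K⁻¹; CH₄ molar mass 16.043 g.
* PCoA eigenvalue cutoff: |λ| ≤ 1e-9 × max|λ| is treated as zero.
* PERMANOVA uses a pseudo-inverse for the hat matrix, tolerating redundant
  dummy columns; permutation F comparisons use a 1e-12 slack for ties.
* Bootstrap prevalence is a Monte-Carlo estimate: with 1000 resamples its
  standard error near the 0.95 threshold is ~0.007, so ASVs genuinely at
  the threshold can flip between seeds — report the prevalence fractions,
  not just the core set, when near-threshold ASVs matter.
* The correlation layer assumes roughly linear, homoscedastic relations;
  Pearson r under-reports monotone nonlinear association.
* Weighted UniFrac, Faith's PD and differential-abundance testing are out
  of scope, as are sequence processing (the pipeline consumes an ASV table,
  taxonomy and tree) and hydrodynamic settler simulation.
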