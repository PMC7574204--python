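# Methods

`scofuel` implements the computational chain of a single-cell-oil study on
an oleaginous yeast grown on lignocellulosic (pongamia-shell) hydrolysate:
strain screening by Nile-red fluorescence, batch fermentation kinetics,
hydrolysate mass accounting, and biodiesel property estimation from the
oil's FAME composition. This note records the models, the parameter
choices where the design was genuinely open, and the limits of what the
synthetic data can show.

## FAME compositions

A FAME profile is a mapping from fatty-acid species `Cn:D` (n acyl
carbons, D double bonds) to weight percent. Published GC–MS columns for
these oils do not sum to 100 % (the AS-PSH column sums to 96.70 %, the
YNB control to 54.56 %), so profiles carry an explicit `normalized` flag
and every property function accepts either convention. The default is
**raw (as printed)** because nothing in the source tables indicates prior
normalization; pipeline reports always include both modes. Raw profiles
are accepted up to 100.5 % (0.5 absolute slack) and the "sums to 100"
check uses 0.05 absolute tolerance to absorb two-decimal printing.

The methyl-ester molecular weight is the atomic-mass sum of
C(n+1)H(2n+2−2D)O2:

    M = 12.011·(n+1) + 1.008·(2n+2−2D) + 31.998   [g/mol]

Odd-chain species (e.g. C15:0) are valid; chain lengths below 4 and
impossible unsaturation (D > ⌊(n−2)/2⌋) are rejected.

Class summaries partition the profile by double-bond count into SFA /
MUFA / PUFA and derive

* **DU** (degree of unsaturation) = (MUFA + 2·PUFA)/100, in
  mass-fraction units, under which typical biodiesels score 0.5–2;
* **LCSF** (long-chain saturation factor) =
  0.1·C16:0 + 0.5·C18:0 + 1·C20:0 + 1.5·C22:0 + 2·C24:0 (wt%-weighted).

Index sums use exactly-rounded summation (`math.fsum`) so results are
bit-identical under species reordering.

## Fuel-property correlations

Properties are estimated with standard composition-based (QSPR)
correlations, collected into a pluggable registry with two named sets:

| property | form | units |
|---|---|---|
| SV | Σ 560·Ni/Mi | mg KOH/g |
| IV | Σ 254·D·Ni/Mi | g I2/100 g |
| CN (`per-species`) | 46.3 + 5458/SV − 0.225·IV | — |
| CN (`du-regression`) | 62.876 − 6.6684·DU | — |
| HHV | 49.43 − 0.041·SV − 0.015·IV | MJ/kg |
| KV40 | 5.2065 − 0.6316·DU | mm²/s |
| density | 0.8726 + 0.0055·DU | g/cm³ |
| CFPP | 3.1417·LCSF − 16.477 | °C |

No single published equation set regenerates the study's printed property
table exactly: the source cites its equations without printing them, its
profiles do not sum to 100 %, and the YNB column is physically
inconsistent (density 0.47 g/cm³ is below any FAME). The package
therefore treats printed property values as context, not targets, and
validates the implementation structurally instead: per-species SV/IV
against a brute-force per-component oracle (1e−9 on 1000 random
profiles), hand-derived pure-component values (methyl oleate SV 188.9,
IV 85.7, CN 55.9, HHV 40.4; the regression intercepts at DU = LCSF = 0),
monotonicity in DU and LCSF, and the requirement that the AS-PSH oil's
CN falls in [51, 62] and passes IS 15607 — consistent with the study's
qualitative conclusion.

Standards limits ship in `data/standards_v1.json` with two sets. The
`as-printed` default transcribes the study's comparison table (EN 14214
CN ≥ 47, ASTM D6751 and IS 15607 CN ≥ 51; KV EN 1.9–6, ASTM 3.5–5,
IS 2.5–6 mm²/s; density ASTM 0.86–0.90, IS 0.86–0.89 g/cm³; EN IV ≤ 120).
The printed EN/ASTM columns for CN and KV appear swapped relative to the
official standards; the `literature` set carries the official limits
(EN CN ≥ 51, KV 3.5–5.0; ASTM CN ≥ 47, KV 1.9–6.0). Oxidative stability
is excluded from the report: it is discussed only qualitatively in this
literature and no correlation for it is fixed here.

## Batch kinetics

Productivities are **endpoint-based** — (final − initial titre)/elapsed
hours — matching the convention behind published 120-h figures; a
`max-slope` windowed variant exists but is not the default. Lipid content
is 100·L/X at the window end. Sugar consumption rates are
(initial − final)/Δt; when a trajectory lacks a t = 0 sugar sample the
medium recipe can supply it (e.g. 30 g/L glucose for YNB with 3 %
glucose, giving the 0.25 g/L/h rate over 120 h). Net production
(final > initial, e.g. from measurement noise on a depleted sugar) is a
warning, not an error, and yields a negative rate.

Hydrolysate tables carry units per analyte (g/L or mg/L, converted
internally to g/L for totals; utilization percentages are
unit-invariant). "Not detected" entries are explicit missing values, not
zeros: an analyte never measured before cultivation is excluded from
utilization math, while one fully consumed (missing after) counts as
100 % utilized. The mass-balance ledger chains
shells (10·loading % w/v g/L) → DCW → lipid → biodiesel
(= lipid × transesterification fraction) and is non-increasing whenever
all stage efficiencies are ≤ 1.

## Screening

Strains are ranked by descending mean RFU with lexicographic tie-break on
strain id (deterministic output). The oleaginy classifier is a strict
threshold: lipid content > 20 % w/w of DCW. The RFU–gravimetry agreement
is the Pearson product-moment correlation on per-strain replicate means
(four replicates per treatment is the emulated protocol); a
`per_replicate` flag pools replicates instead. Correlation requires at
least three strains with both measurements and is undefined (an error)
under zero variance.

## Synthetic data generator

The generator defines the study conditions the tests run under; its
defaults are fixed to the published endpoints and are not tuning knobs.

**Growth.** Biomass follows a logistic curve
X(t) = K/(1 + ((K−X0)/X0)e^(−μt)). The published data constrain only the
endpoints, so the curve shape is an implementation choice; logistic is
the field's default for carbon-limited batch growth. Lipid follows a
Luedeking–Piret form L(t) = α(X−X0) + β∫X dt, with the β term integrated
by the trapezoid rule on the sampling grid. The per-medium presets use
X0 = 0.1 g/L (an OD-0.2 inoculum), μ = 0.08 h⁻¹ (a realistic doubling
time of ~9 h for red yeasts), β = 0, and solve K and α in closed form so
the noise-free 120-h trajectory hits the printed endpoints exactly
(AS-PSH: 12.56 g/L DCW, 7.02 g/L lipid; AD-PSH: 10.63, 4.48; YNB: 12.26,
6.65). Sugars deplete sequentially glucose → xylose → arabinose (the
observed diauxie preference) at a constant total rate that exhausts them
exactly at harvest — which reproduces the 0.25 g/L/h YNB glucose rate by
construction. Measurement noise is additive Gaussian (default
calibration checks use σ = 0.3 g/L, a realistic gravimetric error),
clipped at zero, with lipid clipped at DCW.

**FAME.** Profiles are Dirichlet draws about a normalized mean with
precision (concentration) 500, giving per-species relative scatter of a
few percent, typical of replicate GC–MS runs.

**Screening.** Lipid titres come from a two-component normal mixture:
an oleaginous mode (mean 1.5, sd 0.25 g/L — the published range of the
top isolates at 72 h) with weight 6/57 (the fraction of high-RFU strains
in the emulated campaign) over a background mode (mean 0.4, sd 0.15
g/L), truncated at 0. RFU is affine in lipid (gain 1000 RFU per g/L,
offset 500) plus Gaussian replicate noise whose variance is solved so
the correlation between true lipid and the 4-replicate mean RFU equals
the target r for the drawn panel:
σ²_mean = gain²·Var(L_panel)·(1−r²)/r². Solving against the realized
panel rather than the mixture's theoretical variance keeps the target
exact per campaign even though the number of oleaginous strains
fluctuates binomially; at target r = 0.94 with 57 strains the sample r
lands inside the exact Fisher-z 95 % interval in ≈98 % of seeds.
Targets are restricted to 0 < r ≤ 1 (r = 1 means zero noise).

**Hydrolysate.** Before-cultivation values are truncated-normal draws
around the printed means with the printed standard deviations;
after-cultivation values apply each analyte's printed retention
fraction, so utilization percentages are invariant to the noise draw and
`noise_scale = 0` reproduces the printed table exactly.

All generators derive every draw from one `numpy` `default_rng(seed)`;
identical seeds give bit-identical outputs.

### What the synthetic data does and does not show

The generators reproduce the *arithmetic structure* of the study —
endpoint ratios, sequential sugar depletion, composition simplexes,
affine RFU response. They do not emulate lag phases, substrate
inhibition, lipid turnover late in the batch, GC–MS peak
misidentification, or plate-position effects in fluorescence. Passing
tests therefore demonstrate that the analysis chain is correct and
calibrated, not that the underlying biology is modelled.

## Numerical choices

* Exactly-rounded sums (`math.fsum`) wherever a result must be invariant
  to input ordering.
* Normalization removes float drift by adjusting the largest component,
  so normalized profiles sum to 100 exactly within 1e−9.
* Endpoint recovery on noise-free simulations is asserted to 1e−9; with
  σ = 0.3 g/L noise on 9 time points the per-seed endpoint-productivity
  error has sd ≈ 6 %, so the calibration check asserts the *mean*
  recovered productivity over 100 seeds within ±10 % of the closed form
  (a per-seed bound at that noise level would be statistically
  unattainable and is not the quantity of interest).
* Degenerate inputs (all-zero profiles, zero DCW, zero standard peak
  area, zero-variance correlations) raise typed errors rather than
  returning NaN.
* Reports serialize with sorted keys and full float precision; two runs
  with the same config and seed are byte-identical.

## Problem sizes

Default analyses run on 9-point time courses, 57-strain campaigns, and
≤ 8-species profiles; the calibration checks use 100 seeds (noisy
recovery), 500 seeds (screening coverage) and 1000 random profiles
(index oracle). Everything completes in seconds on one CPU.

## Known limitations

* The fuel-property registry ships two correlation sets; other published
  variants (e.g. different CN regressions) can be registered but are not
  bundled.
* Growth-curve shape between sampled points is an assumption; kinetics
  functions are deliberately endpoint-based so they do not depend on it.
* The P utilization printed in the source (73.71 %) is not reproducible
  from its own table ((1.51−0.36)/1.51 = 76.2 %); the package computes
  the arithmetic value and documents the discrepancy rather than
  matching the printed one.
* Lipid-class (TLC) handling covers only the fraction arithmetic, not
  densitometry image processing.
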