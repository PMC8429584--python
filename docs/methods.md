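# Methods

## Turnover model

Soil organic carbon is tracked in five pools per unit area (t C/ha):
decomposable plant material (DPM), resistant plant material (RPM), microbial
biomass (BIO), humified organic matter (HUM) and inert organic matter (IOM).
Each active pool decays first-order on a monthly step with rate constant
`k_P · a·b·c / 12`, where the decay constants are

| pool | k (1/yr) |
|------|----------|
| DPM  | 10.0 |
| RPM  | 0.3 |
| BIO  | 0.66 |
| HUM  | 0.02 |

and the dimensionless modifiers are: temperature
`a = 47.91 / (1 + exp(106.06/(T+18.27)))` (zero at or below −18.27 °C);
moisture `b`, equal to 1 while the accumulated topsoil moisture deficit
(TSMD) is below 0.444 of its maximum `(20 + 1.3·clay − 0.01·clay²)·depth/23`
mm and declining linearly to 0.2 at the maximum (bare soil caps the deficit
at max/1.8; the deficit grows by `max(0, 0.75·PET − precip)` and is drawn
down by excess precipitation); and cover `c` = 0.6 under vegetation, 1.0 on
bare soil. Decayed carbon splits CO₂ : (BIO+HUM) as `x : 1` with
`x = 1.67·(1.85 + 1.60·exp(−0.0786·clay))`; the retained share goes 46 % to
BIO and 54 % to HUM. Plant inputs split DPM/RPM by a class decomposability
ratio (1.44 arable, 0.67 grassland, 0.25 forest); farmyard manure splits
49/49/2 % into DPM/RPM/HUM. Within a month the order is decay first, then
input addition (inputs are not decayed in their month of arrival); monthly
mass balance `ΔSOC = inputs − CO₂` holds to rounding. All constants live in
one `RothCParams` object and can be swapped for model variants.

Potential evapotranspiration uses the classic unadjusted Thornthwaite form
with day-length and month-length corrections; months at or below 0 °C
contribute nothing. The inert pool is estimated from the initial total stock
by the power-law pedotransfer `iom = 0.049·SOC^1.139` (clipped to
`[0, SOC]`); the coefficients are configuration parameters. The simulated
topsoil depth is 23 cm for cropland/grassland/urban and 30 cm under forest.

Scope: non-waterlogged mineral soils; no radiocarbon sub-model.

## Equilibria, orbits and the definition of ASOC

Under a repeating annual climate cycle the monthly pool update is affine,
`s → M_m s + v_m`, so the year composes to `s → A s + u` and the equilibrium
is the fixed point `(I − A)s = u`, solved directly (a singular system —
all decay shut off with nonzero inputs — is reported as an error). The
equilibrium of the *monthly* system is a periodic orbit, not a constant: the
stock swings within the year with the input calendar and seasonal decay.
The attainable SOC (ASOC) of a class is therefore defined as the **annual
trapezoidal mean of the equilibrium orbit** plus the inert pool. Two
consequences: (i) the impact integral of a settled curve is exactly zero
over each whole year by construction, and (ii) year-start states differ
from ASOC by the within-year seasonal amplitude (typically a few tenths of
a t C/ha), which is why convergence tests compare phase-aligned samples.

## Transition curves

A land-use transition starts from the source class's equilibrium pools (an
urban source starts from the inert stock alone — its equilibrium, since it
receives no inputs) and evolves under the destination class's dynamics.
Trajectories are evaluated in closed form from the eigendecomposition of
`A` (direct iteration is the fallback for ill-conditioned eigenbases), with
monthly resolution reconstructed from the cumulative within-year maps. The
simulated window ends two years after the deviation from the destination
orbit last exceeded `tol_reg = 0.1 t C/ha`, with a hard horizon of 500
years; `t_reg` is the first monthly crossing of that tolerance. Curves that
do not settle within the horizon (slow cool-climate regeneration) carry a
warning and rely on the analytic tail.

The exponential tail rate k (1/yr) is the negated least-squares slope of
`ln|deficit|` against time over the trailing window (up to 240 monthly
samples) of constant deficit sign above a 1e−9 floor, fitted on the
**deseasonalized** series (raw series minus the destination equilibrium
orbit plus ASOC) so the within-year cycle cannot bias the slope. A constant
curve has no rate and contributes zero impact. When the deficit crosses
zero at the very edge of the window and leaves no usable fit window, the
exact asymptotic rate of the affine system, `−ln λ_max(A)`, is used
instead. Transitions into forest first simulate a growth period (default
20 years) with plant inputs ramped linearly from 10 % to 100 % of the
mature input; because pools decay toward zero and never through it, the
stock can never fall below the inert pool.

## Characterization factors

Per region, the potential natural vegetation (PNV) is the feasible forest
or grassland class with maximum ASOC (exact ties broken by lexicographic
class id). Occupation CF = `ASOC_PNV − ASOC_LU2` (t C/ha). The regeneration
impact of a class is the trapezoidal integral of `ASOC_PNV − SOC(t)` over
the simulated window plus the analytic tail `deficit(t_end)/k`
(t C·yr/ha); the transformation CF from LU1 to LU2 is
`Impact_LU2 − Impact_LU1`, making positive values depletion and reverse
transitions exact negatives. Occupation CFs are non-negative over the PNV
candidate set by the argmax property; cropland classes with higher
attainable stocks than the natural vegetation (e.g. irrigated cereals with
residues retained) legitimately produce negative CFs — SOC gains.

Background transformation CFs (initial class unknown) replace `Impact_LU1`
by `Σ_category share · mean(impact over feasible classes of the category)`,
with shares renormalized over the categories present and feasible, and
unweighted within-category averaging. They are intended for country-level
use: per-region values are area-weighted into country CFs, with spreads
pooled as `sqrt(Σ w_i σ_i²)` (a design choice; spreads across regions are
treated as independent within-region variances, not as between-region
variability). The elementary-flow table resolves each mapped land-use flow
per region — single class, unweighted class-set average, or the
minimum-ASOC forest class (selected on mean ASOC so the mapping is stable
across Monte Carlo runs) — and aggregates the resolved values. Water,
wetland and bare-area flows carry no SOC-depletion CF and raise an explicit
error rather than returning zero.

## Uncertainty propagation

Intra-region input variability is propagated with a Monte Carlo of
`n_runs = 100` by default. Per run, one additive normal draw shifts all
monthly temperatures (sd 1 °C) and one truncated-normal multiplicative draw
each scales precipitation (CV 10 %), clay (CV 10 %, clipped to [0, 100] %),
initial SOC (CV 15 %, with IOM scaled by the same factor so
`0 ≤ iom ≤ soc_init` is preserved exactly) and plant C inputs (CV 10 %).
The magnitudes are plausible defaults and fully configurable. All factors
within a run share the one draw, so per-run identities — antisymmetry, the
zero CF of the PNV class — survive averaging exactly, and zero-variance
configurations reproduce the deterministic pipeline bit for bit. Draw
streams are keyed by (seed, region id, run index): adding regions or
classes never perturbs existing draws. Failed runs are dropped with a
logged reason; more than 20 % failures abort the region. Reported CFs are
means over runs with sample standard deviations (ddof = 1).

## Synthetic worlds

The generator emulates the statistical structure of homogeneous territorial
units: three climate archetypes (tropical 26 ± 2 °C, ~160 mm/month;
temperate 12 ± 9 °C, ~75 mm; boreal 3 ± 14 °C, ~55 mm — sinusoidal
temperature cycles, lognormal monthly precipitation, latitude-driven day
length), clay uniform in 5–45 %, initial SOC uniform in 30–120 t C/ha with
IOM from the pedotransfer, per-region feasible-class subsets that always
contain urban and at least one forest-or-grassland class (so a PNV exists),
land-use shares from a scaled Dirichlet draw, contiguous 2×2-pixel
footprints on a 0.083-degree grid, and areas scaled by cos(latitude).
Cropland carbon inputs derive from archetype- and crop-dependent yields via
residue accounting (`aboveground = yield·slope + intercept`,
`belowground = (yield + aboveground)·root:shoot`,
`C = (aboveground·(1 − removed) + belowground)·C-fraction`); forest and
grassland inputs are archetype constants with lognormal scatter. The
default study size is 25 regions, 5 countries, 12 classes covering every
flow-mapping bucket.

What the generator does **not** emulate: real geographic covariance
(climate–soil–land-use correlation), real class-specific yield gaps, or
observed SOC maps. Passing tests therefore demonstrate correctness of the
calculus and the pipeline's statistical behaviour, not agreement with
field data.

The known-answer oracle region makes every transition curve an exact
exponential by setting all four decay constants equal under constant
climate (total active carbon then decays geometrically regardless of its
distribution over pools); the common constant is solved from the requested
annual rate and the constant inputs are chosen so the equilibria hit the
requested stocks exactly, giving closed-form CFs for end-to-end
verification.

## Numerical choices and degenerate inputs

- Steady state: direct 4×4 solve; eigendecomposition reused for whole
  trajectories; roundoff-negative equilibrium pools are clipped to zero.
- Impact integration: monthly trapezoid plus analytic tail; with ASOC
  defined as the orbit mean, the discretization bias on an exponential
  deficit is `≈ (k/12)²/12` relative (about 1e−6 at k = 0.05/yr).
- `n_runs = 1` yields zero spreads with a warning. All-zero usable land-use
  shares, missing PNV candidates, unmapped flows, overlapping raster
  footprints and duplicate exchange-factor keys raise typed errors.
- The 2000-year equilibrium cross-checks and the urban-decay check are run
  on warm-to-temperate parameterizations, where the slowest pool's
  e-folding time (HUM, `0.02·a·b·c` per year with a small feedback through
  BIO/HUM return) resolves within the horizon; at boreal temperatures
  (a ≈ 0.25 at 2 °C) HUM decays too slowly for a 500-year/1 % statement.

## Known limitations

- The flow-mapping fixture covers the packaged classification rows;
  water/wetland/bare flows are out of scope by design.
- The cropland class composition (which crops are cereals, which admit
  irrigation) is a versioned fixture; real-world per-crop input magnitudes
  are not reproduced.
- Country aggregation assumes each region belongs to exactly one country.
- Rasters are written on the native geographic grid only; no reprojection.
- Organic-fertilization scenarios are encoded as configurable manure rates
  (0 / 1 / 2 t C/ha/yr); the registry ships at the baseline scenario.
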