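# Methods

## The photosynthesis core

Leaf biochemistry follows the Farquhar–von Caemmerer–Berry (FvCB) model
with Bernacchi-type Arrhenius kinetics. Reference constants at 25 °C
(Γ\*₂₅ = 4.332 Pa, Kc₂₅ = 39.97 Pa, Ko₂₅ = 27 480 Pa, with activation
energies 37 830, 79 430 and 36 380 J mol⁻¹) live in one versioned table
(`constants.py`, exportable as JSON). Γ\* additionally scales linearly
with surface pressure. The effective Michaelis–Menten coefficient is
K = Kc(1 + pO₂/Ko). Water viscosity relative to 25 °C (η\*) uses the
Vogel–Fulcher–Tammann correlation; only the ratio matters, so
η\*(25 °C) = 1 holds exactly and the contract is tested through that
identity and monotone decrease with temperature.

The optimal ci/ca ratio comes from the least-cost hypothesis:

    ξ  = sqrt(β (K + Γ*) / (1.6 η*))
    χ  = Γ*/ca + (1 − Γ*/ca) · ξ / (ξ + √D)        D = VPD (Pa)

which gives χ = 1 exactly at D = 0 and χ ∈ (Γ\*/ca, 1] always. CO2
limitation factors are m = (ci − Γ\*)/(ci + 2Γ\*) (electron transport)
and mc = (ci − Γ\*)/(ci + K) (Rubisco); below the compensation point both
are clamped to 0 rather than raising, so cold or very dry months simply
contribute zero GPP and annual sums stay defined. The Jmax-limitation
factor is m′ = m·sqrt(1 − (c\*/m)^(2/3)) for m > c\*, else 0, and

    LUE = φ0 · m′ · Mc          (gC per mol photons)

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| φ0   | 0.05 | mol C mol⁻¹ photons | intrinsic quantum yield; fixed by default, with an optional quadratic temperature-dependence mode normalised to the 25 °C value |
| β    | 146  | –  | unit-cost ratio of carboxylation vs transpiration capacity |
| c\*  | 0.41 | –  | Jmax-limitation cost |
| O₂ fraction | 0.2095 | – | atmospheric mole fraction |
| PPFD/SW | 2.04 | µmol J⁻¹ | PPFD from shortwave energy, configurable |

Defaults are the published calibration of the optimality model; the study
sites give no reason to localise them.

### Optimal Vcmax and coordination

The optimality-predicted capacity is Vcmax = φ0·Iabs·m′/mc (the
Jmax-limitation-adjusted form). We chose this, rather than the simpler
φ0·Iabs·m/mc, as the default because it is the prediction consistent with
the LUE path above and it pairs with a *finite* coordinated Jmax: solving
the saturating electron-transport equation

    J(Iabs, Jmax) = 4 φ0 Iabs / sqrt(1 + (4 φ0 Iabs / Jmax)²)

for J = 4φ0·Iabs·m′/m yields the Jmax at which AJ = (J/4)·m equals
Ac = Vcmax·mc identically. That Ac = AJ coordination is asserted to 1e−6
relative over random forcings; the simple variant remains available
(`vcmax_optimal(..., limited=False)`).

The same saturating J equation is used *everywhere* — in the forward AJ,
in the trait-based LUE, and inverted when deriving Jmax from Amax — so
forward simulation followed by inversion is an exact round trip and the
two LUE routes coincide when traits equal the optimality-implied ones.

## Trait inversion

Records carry net assimilation at 400 µmol mol⁻¹ CO2 and saturating light
(Asat) and at 2000 µmol mol⁻¹ CO2 and 2000 µmol m⁻² s⁻¹ PPFD (Amax), at a
block temperature of 30 °C. Inversions:

* Vcmax from Asat assuming Rubisco limitation:
  Asat = Vcmax·mc − rd at the measurement ci. A post-hoc check that
  Ac ≤ AJ at the fitted traits flags records violating the assumption.
* Jmax from Amax: J = 4(Amax + rd)/m at the 2000-ppm ci, then the
  saturating J equation inverted for Jmax. A required J at or beyond the
  light-limited asymptote 4φ0·Iabs has no solution and flags the record.

Open choices, set as package defaults and configurable:

* **ci at measurement**: ci = 0.7·ca at 400 ppm and 0.9·ca at 2000 ppm
  (stomatal limitation weakens at high CO2); measured ci columns override
  when present.
* **dark respiration**: rd = 0.015·Vcmax, a common ecophysiological
  ratio; rd = 0 or a fixed value are alternatives.
* **growth temperature**: the mean air temperature of the site's forcing
  series; traits are Arrhenius-normalised between leaf, growth and 25 °C
  temperatures with activation energies 65 330 (Vcmax), 43 900 (Jmax) and
  30 000 (rd) J mol⁻¹.
* Records with Amax < Asat or failed inversions are excluded from the
  community mean, with counts logged.

Community means weight species by basal-area fraction, renormalised over
the sampled species (field sampling covers ~80% of plot basal area), sun
leaves only.

The trait-based LUE evaluates gross min(Ac, AJ) at the canopy absorbed
flux and divides by that flux. Monthly photon totals convert to a mean
daytime flux assuming 12-hour tropical days (`DAYLIGHT_SECONDS_PER_MONTH`);
χ and hence ci are still taken from the optimality prediction, so the
trait experiments isolate the capacity difference, not a stomatal one.

## Isotope χ

Δ13C = (δ_air − δ_leaf)/(1 + δ_leaf/1000), then χ = (Δ − a)/(b − a) with
a = 4.4‰ (diffusion) and b = 27‰ (carboxylation), configurable;
atmospheric δ13C defaults to −8‰ with per-record overrides. Out-of-range
χ is clamped and flagged, never silently used.

## fAPAR handling

Satellite records carry a literal two-bit cloud state: 00 clear,
01 significant cloud, 10 mixed cloud, 11 unset (the in-situ placeholder).
Policies: `all` (no filtering), `exclude_significant` (keep 00 and 10 —
the conventional product filtering), `clear_only` (keep 00). In-situ
records always pass. Climatologies are per-calendar-month means across
years; a month with no surviving record is reported missing, never
imputed. Annual means average the available months — deliberately, since
gap-filling against cloudy-season losses is exactly the mechanism that
biases product fAPAR low; the missing-month count is part of the report.
The bias report is 100·(mean_insitu − mean_satellite)/mean_insitu on
annual means, per site and averaged with equal site weights (a
record-weighted average is also reported, since the weighting convention
is a genuine open choice).

## Biometric GPP

Plot GPP is the sum of measured components; uncertainty combines in
quadrature under independence, with an optional full covariance matrix.
Site GPP is the unweighted mean across plots and its uncertainty the mean
of plot sigmas — a measurement error, not a spatial standard error, by
design.

## The experiment engine and ledger

All five experiments run through one code path; only the input bindings
differ. Monthly GPP = fAPAR·LUE·PPFD is summed per calendar year,
averaged over the year range (default 2011–2016), and converted with the
exact factor 0.01 gC m⁻² → MgC ha⁻¹. Climate variables other than PPFD
always come from the canonical (field) forcing; the `product` PPFD source
swaps only the photon flux, and the P-vs-null difference is reported
separately as the PPFD sub-term rather than guessed into the optimisation
term. The product GPP entering the ledger is either the lookup-table
emulator (synthetic mode) or an externally supplied site value
(replication mode); the result records which.

The lookup-table emulator mirrors the classic satellite GPP algorithm:
LUE = εmax·f(Tmin)·f(VPD) with linear ramps clamped to [0, 1]. Defaults
are the published evergreen-broadleaf row (εmax 1.268 gC MJ⁻¹ APAR →
0.2757 gC mol⁻¹ photons at 4.6 µmol photons per J of PAR; Tmin ramp −8 to
9.09 °C; VPD ramp 800 to 3100 Pa). The published ramps are defined on
*daytime* VPD while the forcing carries monthly means, so the emulator
multiplies VPD by a daytime factor (default 1.75) before the ramp;
monthly mean temperature stands in for Tmin, which is inert in the
tropics (the ramp saturates above 9.09 °C).

The ledger telescopes by construction: the four terms sum to
biometric − product exactly, for any inputs.

## Synthetic data design

The generator's defaults are the study conditions. Three sites span the
wet-to-dry gradient (MAP 2050 / 1500 / 1200 mm), with designed biometric
GPP 40.1 / 43.3 / 38.0 MgC ha⁻¹ yr⁻¹ and 3 / 6 / 5 one-hectare plots.
Monthly climate is sinusoidal-seasonal (dry-season VPD peak near January,
mild sunshine seasonality); CO2 trends upward ~2.1 µmol mol⁻¹ yr⁻¹;
"product" forcing adds designed systematic offsets (+5% PPFD, +0.3 °C,
+5% VPD). Canopy fAPAR truth is high and weakly seasonal (0.96 / 0.93 /
0.88 site levels). The cloudy season peaks in August–September with
significant-cloud probability up to 0.9; the remaining probability splits
70/30 between clear and mixed states. Satellite retrievals are the truth
times a clear-sky scale factor (0.60 / 0.745 / 0.70 — chosen so the
designed site-mean filtered bias is ≈34%, strongest at the wet site) and,
in cloudy states, a Beta-distributed multiplicative draw-down (mean 2/3
under significant cloud, 0.1 under mixed cloud).

Community traits are a site-level uplift on the optimality-implied
Vcmax/Jmax (1.70 / 2.60 / 2.65), giving the drier sites the higher
absolute photosynthetic capacity and making the trait-resolved term
dominate there, while fAPAR dominates at the wet site. Species scatter
around the site level (6% relative), gas-exchange records are
forward-simulated from the designed traits at the chamber conditions with
additive noise, GPP components split the designed total (fractions
0.20/0.12/0.10/0.22/0.18/0.18) with independent lognormal errors (σ =
0.06) and 8% reported sigmas, in-situ fAPAR adds 0.01 absolute noise, and
isotope δ13C is consistent with the optimality χ.

`design_attribution` evaluates the same experiment equations on the
noise-free designed inputs (expected satellite climatology in closed
form) — that is the ground truth the end-to-end tests recover within 5%
of biometric GPP. The `neutral_template` is the zero-perturbation
control: constant climate (no seasonality, no CO2 trend), unbiased
uncontaminated satellite, traits exactly the optimality-implied ones, the
lookup emulator calibrated to the optimality LUE with ramps inactive, and
biometric set to the trait-experiment GPP. Under those conditions all
five GPPs coincide analytically and the pipeline must return a zero
ledger to round-off. Constancy is part of the design: with seasonal
forcing a single community trait set cannot equal the month-by-month
optimal traits, so exact zeros only exist at constant conditions.

What the generator does *not* emulate: satellite orbital sampling and
compositing windows, spatially correlated measurement errors, trait
seasonality, interannual fAPAR trends, and any dependence of biometric
component errors on each other. Passing tests therefore demonstrate the
pipeline's internal correctness and its ability to recover designed
biases of realistic magnitude — not the accuracy of any particular field
campaign.

## Problem sizes and numerics

Default runs use 3 sites × 6 years × 12 months, 6 species × 3 trees × 2
leaf classes of gas exchange, and one satellite retrieval per site-month
— small enough that the whole suite and the acceptance script run in
seconds while every code path is exercised. Degenerate inputs are handled
explicitly: sub-compensation ci clamps limitation factors to zero,
ca ≤ Γ\* is an invalid-forcing error, Amax at the light-limited asymptote
is a flagged no-solution, an all-missing fAPAR climatology raises, and
empty component or plot lists raise.

## Known limitations

* Big-leaf canopy only; no sun/shade partitioning, no soil-moisture
  stress, C3 only, monthly time step.
* With the fixed φ0 = 0.05 calibration, matching biometric GPP near
  40 MgC ha⁻¹ yr⁻¹ requires community Vcmax well above typical field
  reports; the synthetic trait uplifts inherit that scale. The
  temperature-dependent φ0 mode does not change this materially.
* The two-point trait inversion is only as good as its ci-at-measurement
  and rd policies; both are exposed rather than hidden.
* The product emulator is a deliberately simple stand-in for a real
  satellite GPP product's LUE pathway; in replication mode external
  product values should be supplied instead.
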