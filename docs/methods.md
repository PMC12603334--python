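# Methods

`oximc` simulates reflectance photoplethysmography (PPG) and pulse oximetry
from first principles: weighted photon packets are transported through a
layered skin model by Monte Carlo sampling, the detected intensities at
systole and diastole give the perfusion index (PI), two wavelengths give the
ratio of ratios (RoR), and a population-level quadratic calibration maps RoR
to an SpO2 estimate whose error and shot-noise SNR can be studied as a
function of sensor geometry and skin pigmentation.

## Tissue model

The skin is a stack of plane-parallel, laterally infinite layers: epidermis
(0.27 mm), capillary loops (0.15 mm), upper plexus (0.08 mm), reticular
dermis (1.2 mm), deep plexus (0.50 mm), hypodermis (0.55 mm), and a
semi-infinite muscle layer. Each layer carries a refractive index n, blood
and water volume fractions C_b and C_w, a vessel diameter v_d (stored; only
used by the optional pigment-packing correction), and a pulsatility flag.
The absorption coefficient of a layer is mixed from chromophore spectra at
the four design wavelengths (624, 660, 850, 940 nm):

    mu_a = C_b_eff (SaO2 mu_a_O2Hb + (1 - SaO2) mu_a_HHb)
         + C_w mu_a_water + C_Mel mu_a_melanin [epidermis]
         + (1 - C_b_eff - C_w - C_Mel[epidermis]) mu_a_baseline

O2Hb/HHb columns are whole-blood coefficients (150 g hemoglobin per litre),
so C_b multiplies them directly. Melanin is confined to the epidermis and
uses the melanosome power law mu_a ~ lambda^-3.48; C_Mel in 2.55-30.5 %
spans Fitzpatrick skin types I-VI. The baseline term closes the volume
fractions with a small bloodless/waterless tissue absorption so no layer is
transparent; it can be disabled. Scattering coefficients derive from
reduced-scattering power laws mu_s' = a (500/lambda)^b divided by (1 - g),
with a dermal anisotropy g = 0.62 + 2.9e-4 lambda and fixed g for
hypodermis (0.80) and muscle (0.90). Muscle absorption comes from a direct
per-wavelength table rather than the mixing rule. All tables ship as
commented CSV and can be replaced wholesale.

**Cardiac phases.** Systole multiplies C_b of the pulsatile layers (all but
epidermis and muscle) by the systolic gain, default 1.10, i.e. a 10 %
relative increase of arterial blood volume. The magnitude of this
modulation is the least-constrained parameter of the whole model and sets
the PI scale almost linearly: to first order PI ≈ (gain - 1) × Σ_i C_b,i
mu_a,blood ⟨L_i⟩ over the pulsatile layers, where ⟨L_i⟩ is the mean detected
path length in layer i. Results for another modulation depth can therefore
be rescaled by (gain - 1) to good accuracy. With the 1.10 default the
simulated PI at 624 nm averages a few percent; literature reports of
simulated reflectance PI span roughly an order of magnitude depending on
this choice.

## Sources and detector

Beam profiles are tabulated angular intensities I(theta): a Lambertian lobe
for LEDs and a Gaussian lobe of ~20-21 deg FWHM for VCSELs (parametric
stand-ins for datasheet curves; editable CSV). Emission is sampled by
inverse-transform lookup of theta with uniform azimuth. The polar density
includes the solid-angle weight, p(theta) ∝ I(theta) sin(theta); a planar
density mode exists for comparison with frameworks that tabulate I as a
per-angle density. VCSEL beams may be tilted ±45 deg about the horizontal
axis perpendicular to the source-detector axis (+45 toward the detector);
the tilt is applied in air and refraction at the surface handles the rest.
The detector is a 1 mm square aperture centred at the source-detector
distance (2-9 mm, centre to centre) with cosine angular sensitivity and
unit spectral sensitivity by default.

## Transport

Packets enter at the origin, lose the specular fraction R_spec =
(R_s + R_p)/2 at the air-epidermis interface, and then repeat: sample a
free path, move (splitting steps at layer boundaries with the remaining
optical depth rescaled by the new layer's coefficient), decide
transmission/reflection at index mismatches by comparing the unpolarized
Fresnel reflectance with a uniform draw, deposit w mu_a/(mu_s + mu_a) of
the weight at each interaction, scatter through a Henyey-Greenstein angle,
and play Russian roulette (threshold 1e-4, survival factor 10) when the
weight is low. Packets escaping the top surface are scored by the detector
if they exit inside the aperture; packets are terminated beyond a 30 mm
lateral radius or depth, or after 1e6 events, with their weight booked to a
signed residual so that specular + absorbed + escaped + residual equals the
launched weight exactly on every run (asserted at 1e-6 relative).

**Step-length modes.** The default "mcml-standard" mode samples the free
path from mu_t = mu_a + mu_s — the classic unbiased estimator paired with
the albedo weight update. The "paper-literal" mode samples from mu_s alone
with the same weight update; for skin (mu_a << mu_s in the vascular layers)
the two agree closely, and the modes are bitwise identical at mu_a = 0.

**Shared-path pairing.** Conditions that differ only in absorption —
systole vs diastole, melanin levels, SaO2 levels — can ride the *same*
photon paths as weight channels of a single pass (valid exactly in the
paper-literal mode, whose step lengths do not depend on mu_a). Roulette is
gated on the largest channel weight, which keeps every channel's
expectation unbiased. Paired this way, PI is a smooth functional of the
common path ensemble and its Monte Carlo variance is tiny even when only a
few hundred packets reach the detector; this is what makes desk-scale
sweeps feasible. Sweeps and the reproduction script therefore use the
paper-literal paired kernel, while single-condition runs default to
mcml-standard.

## Oximetry pipeline

PI = (I_dia - I_sys)/I_sys with I the detected throughput (sum of detected
weights over launched packets; a mean-detected-weight normalization is
available behind a flag — PI is identical under both for paired runs).
RoR = PI_red/PI_IR for the four red/infrared pairings. The population
calibration SpO2 = A RoR² + B RoR + C is an ordinary least-squares fit of
SaO2 in percent on (RoR², RoR, 1), pooling all melanin levels, geometries,
distances and seeds of a sweep; samples with non-positive PI in either band
are excluded and logged, since RoR is undefined there. MAE is the mean
absolute SpO2-SaO2 difference, stratifiable by any subset of grid axes.
SNR follows the Poisson shot-noise model on count-scaled intensities,
SNR = (I_dia - I_sys)/sqrt(I_dia + I_sys), with the count scale defaulting
to the launched packet number and decibels reported as 10 log10 (a 20 log10
amplitude convention is a flag). Paired configurations are compared with
the one-sided Wilcoxon signed-rank test, with Shapiro-Wilk normality
p-values reported alongside.

## Virtual cohort and problem sizes

The full study grid is 4 wavelengths × 4 source configurations × 8
distances × 7 melanin levels × 4 saturations × 2 phases × 25 seeds
(179,200 rows); each seed plays the role of an individual in a virtual
cohort. Per-cell RNG seeds derive deterministically from the grid
coordinates, so any sub-grid reproduces identical rows (resumability).
The package defaults to desk-scale budgets: 1e6 packets per cell for
library sweeps, and 1e5 packets per transport pass in the reproduction
script (`scripts/acceptance.py`), where all physiological conditions of a
cell share one pass. Cluster-scale budgets (5e8 packets × 25 seeds) are
expressible through the same interfaces.

## What the simulator does and does not capture

Passing tests certify the transport core against engine-independent
oracles (closed-form Fresnel, Henyey-Greenstein moments and density,
exponential step statistics, ballistic Beer-Lambert transmission, exact
weight audits, bitwise determinism) and the pipeline against exact
algebraic cases. They do not certify agreement with any particular device:
beam profiles and detector sensitivities are parametric stand-ins, the
optical-constant tables are literature transcriptions at four wavelengths
only, and the systolic modulation depth is conventional rather than
measured. Known limitations: PI magnitude scales almost linearly with the
weakly-constrained systolic gain; the sign of the PI-melanin relation at
fixed geometry is delicate (it reflects a correlation between epidermal and
vascular path lengths and can flip with source-detector distance at modest
statistics); no motion artefacts, no source spectral bandwidth, no
time-resolved waveform (systole/diastole endpoints only); unpolarized
Fresnel averages throughout; planar layer geometry.
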