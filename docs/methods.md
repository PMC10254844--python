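# Methods

This note records the model, the numerical choices, and what the synthetic
data do and do not establish. It documents procedure, not results; every
number quoted as recoverable is computed by the test suite or
`scripts/acceptance.py` at run time.

## Detector response model

All quantitation rests on four linear response equations relating detector
peak areas (mV·mL over retention volume) to physical properties:

| detector | area | constant determined from |
|---|---|---|
| RI | K_RI·(dn/dc)·m | standard's dn/dc and injected mass |
| UV | K_UV·(dA/dc)·m | standard's dA/dc |
| RALS/LALS | K_LS·Mw·(dn/dc)²·m | standard's Mw |
| viscometer | K_Visc·IV·m | standard's IV |

with m the injected mass (concentration × injection volume; mg/mL × µL =
µg). Units are fixed at module boundaries — mL, µL, µg, mV, kDa, mL/g for
dn/dc, dL/g for IV, nm for Rh — with conversions centralized in the
functions that need them (`hydrodynamic_radius` converts dL/g → cm³/g and
kDa → g/mol internally).

Slice-level Mw and IV are signal ratios (LS/RI and Visc/RI), so they are
invariant to any common rescaling of signals and constants, and they
diverge where RI approaches zero; hence the signal floor below.

## Calibration

`calibrate_from_standard` inverts the response equations on a
baseline-corrected standard run, integrating over a monomer window. Default
standard properties are literature values for BSA (Mw 66.4 kDa, dn/dc
0.185 mL/g, dA/dc 0.667 mL/(mg·cm), IV 0.041 dL/g) and are overridable; no
claim is made about the concentration or window any particular laboratory
used. The monomer window matters when the standard contains dimer: the
dimer's doubled mass biases K_LS specifically, while windowing shifts all
constants by the same in-window mass fraction — a common factor that
cancels in the K_RI/K_LS and K_RI/K_Visc ratios that set the Mw and IV
scales. Areas are trapezoidal; on the default 0.01 mL grid the quadrature
error for Gaussian peaks is far below every stated tolerance, and
constants change by < 0.1% between 0.01 and 0.005 mL grids (tested).

The whole-sample dn/dc is estimated as total corrected RI area /
(K_RI × injected mass), assuming full mass recovery; supplying a fixed
dn/dc through the configuration bypasses this. One dn/dc per sample is the
implemented convention for heterogeneous samples; with a single sample-wide
value, RI-area shares and mass shares coincide.

## Trace preparation

Baseline: straight line through the points inside user-specified (or
automatic outer-7%) blank windows, removed per detector. A linear baseline
under-models real drift but matches the generator's drift structure; a
window whose local slope is inconsistent with the fitted line (beyond 6×
the quietest window's residual noise, with a relative floor of 1e-4 of the
trace amplitude) triggers a warning that it may overlap a peak.

Peak detection runs on the RI trace — the concentration channel — because
light scattering over-weights aggregates. Apexes are local maxima above 2%
of the global maximum with ≥ 0.3 mL separation (both configurable; the
defaults resolve every bundled fixture). Boundaries: the deepest valley
between adjacent apexes when that valley stays above an edge floor of 0.5%
of the global maximum; when the inter-peak signal dips below the floor,
each peak is bounded at its own floor crossing and the sub-floor gap is
excluded. A pure argmin over a near-zero noise plateau would place the
boundary arbitrarily, which is why the floor branch exists. Valley-based
integration (rather than tangent skimming or curve-fit deconvolution) is
the conventional choice for overlapping SEC peaks; deconvolution is out of
scope.

Detector alignment shifts traces by per-detector volume offsets (serial
plumbing delay) via linear interpolation, retaining the common grid region.

## Slice quantitation and per-peak summaries

Slices with RI below `max(3 × blank-window noise SD, 1% of the RI maximum)`
keep their mass but get undefined Mw/IV (ratios explode on flanks). The
hybrid light-scattering signal is the mean of RALS and LALS; either channel
alone is selectable. Per peak: Mw is the mass-weighted mean over defined
slices, Mn/Mz the standard moment ratios, IV the mass-weighted mean, share
the RI-mass fraction over all integrated regions (sums to 100), and Rh is
computed from the peak's (Mw, IV).

The equivalent-sphere relation Rh = (3[η]M/(10πN_A))^(1/3) was chosen
because it reproduces published monomer and conjugate rows (IgG 152.5
kDa/0.042 dL/g → 4.67 nm; 156.6 kDa/0.046 → 4.85 nm; 55.6 kDa/0.034 →
3.11 nm; 43.1 kDa/0.032 → 2.80 vs 2.79 printed, within input-rounding).
It is a monodisperse-sphere idealization: for broad aggregate populations
(Pd > 1.2) whose tabulated Mw is a distribution average, computed and
instrument-reported Rh differ by up to ~0.4 nm, and the tests only assert
agreement for narrow peaks.

`peak_moments` requires at least three defined slices and strictly positive
slice masses/Mw inside the region; Pd ≥ 1 holds by the Cauchy–Schwarz
inequality and is verified as a property test.

## Conjugation QC

Classification tolerances: ±10% relative Mw around the free-enzyme and
free-antibody references (wide enough to span species-to-species IgG
variation, ~145–157 kDa). A peak above antibody×1.1 is an aggregate if
Pd ≥ 1.15 **or** Mw exceeds antibody + 6×enzyme — six being the classical
upper bound on HRP molecules coupled per IgG — and otherwise a conjugate
with n = nearest integer to (Mw−antibody)/enzyme. The Pd threshold sits
deliberately below the ≥ 1.2 polydispersity typical of aggregate
populations, with the Mw rule as backstop because a narrow synthetic
aggregate species can have Pd ≈ 1. A stoichiometry residual above 0.35 is
reported as a pair ("conjugate 1:4 or 1:5"). Stage comparison flags any
aggregate-share increase above 5 points (configurable) — the signature of
aggregation during ultrafiltration.

## Synthetic chromatograms

The generator emulates Gaussian elution of each species with detector areas
given exactly by the response equations, identical ideal RALS and LALS
(isotropic small-particle limit; all analytes here have Rh ≤ ~12 nm, far
below the laser wavelength), additive white Gaussian noise per detector
(default 0.05 mV against peak heights of tens to hundreds of mV), optional
linear drift, and optional per-detector volume offsets. Default grid:
5–14 mL at 0.01 mL, the useful separation window of the emulated column.

Fixture compositions (species Mw, retention volumes, shares) follow the
published characterization of the emulated samples: an IgG preparation
(92/2/6% monomer/dimer/aggregate), an HRP preparation (~94% monomer), the
pre-/post-reduction conjugation mixtures and the ultrafiltered final
product (61.82/32.06/6.12% aggregate/conjugate/unidentified), three
commercial IgG–HRP reagents, and BSA standards (pure, and a 10%-dimer
variant). Peak widths are plausibility choices — no widths are published —
mostly 0.12–0.25 mL; the closely spaced (0.5 mL) conjugate peaks of the
commercial fixtures use σ = 0.10 mL so that valley integration keeps
cross-contamination of neighbouring peak Mw below the 0.5% recovery
tolerance. All species within a fixture share dn/dc = 0.185 mL/g: the
analysis path applies one whole-sample dn/dc, so species-specific values
would bias recovered Mw by the ratio of species to sample dn/dc; modelling
that instrument-inherent approximation is out of scope for the recovery
oracle. Injected masses follow the stated sample concentrations (1.5–3
mg/mL at 50 µL).

What passing recovery tests show: the estimator chain is algebraically
correct, unbiased under the modelled noise, and stable under baseline
drift. What they do not show: robustness to tailing/fronting peak shapes,
inter-detector band broadening, nonlinear baselines, detector saturation,
or dn/dc heterogeneity — all absent from the generator by design.

## Problem sizes

Stochastic recovery quantities use 20 independently seeded simulate →
calibrate → analyze replicates (each ~900-point, five-detector run); the
calibration-bias property uses 100 replicates. These sizes put Monte-Carlo
scatter well below the asserted tolerances while keeping the whole suite
in seconds.

## Known limitations

- Gaussian-only peak shapes; no deconvolution of fused peaks.
- One dn/dc per sample (per-peak overrides possible via configuration, but
  the default mirrors routine practice).
- Rh is an equivalent-sphere construct; it is not a measured DLS radius
  and degrades in meaning for broad distributions.
- The two-component composition solver is linear in dn/dc and cannot
  separate more than two components.
- No angular extrapolation of light scattering: invalid for analytes
  approaching the Zimm regime (not the case for antibody conjugates).
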