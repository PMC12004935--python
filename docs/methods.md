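# Methods

## Binding model and estimators

The probe–membrane association is modelled as a two-state Langmuir
process. Bound probe is expressed as a molar percentage,
`[DNA]_mem = 100 · (bound DNA)/(lipid)`, saturating at `[DNA]_max`;
the concentration that drives binding is the free solution concentration
attenuated by the Boltzmann factor of the electrostatic repulsion
`ε_elec` between the anionic duplex and the membrane,
`[DNA]_adj = [DNA]_free · exp(−ε_elec/kT)`. Folding the Boltzmann factor
into the constant gives the effective `K_B = K_B,int · exp(−Δε_elec/kT)`,
which is what a titration measures. All energies are in kT at 298 K;
`K_B` is per µM.

**Isotherm fit** (`binding.fit_isotherm`). The fit target is the
per-concentration-level *mean* bound fraction against the per-level mean
free concentration — the population-mean curve — with `K_B` and
`[DNA]_max` both free. We deliberately fit means rather than a per-vesicle
likelihood: the population mean of saturating curves drawn from a
heterogeneous K distribution is the directly observable quantity, and
fitting it requires no distributional assumption. (A consequence worth
knowing: with a log-normal K spread of CV c, the mean curve's effective K
sits between the median and the mean `median·exp(σ²/2)`, i.e. up to ~4 %
above the median at c = 0.3. This is a property of the estimand, not a
bug, and is well inside the reference uncertainties.) Optimisation is
Levenberg–Marquardt via `scipy.optimize.curve_fit` with positivity bounds;
initialisation takes `[DNA]_max` as 1.2× the largest observed mean and
`K_B` from the low-concentration secant, with five seeded log-normally
jittered restarts, keeping the lowest SSE. Non-convergence from all
restarts raises with diagnostics. Uncertainties come from a vesicle-level
bootstrap (resampling vesicles with replacement within each level,
default 1000 replicates, seeded) — assumption-light and matched to the
sampling unit.

**Per-vesicle inversion** (`binding.per_vesicle_kb`). For a single vesicle
`K_B,i = [DNA]_mem / ([DNA]_free · ([DNA]_max − [DNA]_mem))` with
`[DNA]_max` fixed at 0.4 mol % (composition-independent within error;
overridable). The inversion is ill-conditioned near saturation (the
denominator vanishes) and at vanishing free concentration; the pipeline
therefore inverts at the titration level closest to half-saturation
(`K_B·[DNA] ≈ 1`, chosen from the isotherm fit), masks records above 75 %
of `[DNA]_max`, and uses the *level-mean* free concentration — free DNA is
a bath property shared by all vesicles in a well, so per-vesicle
background noise should not enter the denominator. Saturated or
zero-free-DNA records map to NaN in vectorised use and raise for scalars.

**Charge law** (`binding.fit_charge_law`). `K_B(n_PG) = K_B0·exp(−B·n_PG)`
is fit as a straight line in log K_B, optionally weighted by inverse
squared relative SEs; a point at n_PG = 0 is required so the intercept is
anchored at the zero-charge reference. The fit stores its parameter
covariance so downstream consumers can propagate prediction uncertainty.

**Repulsion energies** (`binding.delta_eps_from_kb`).
`Δε_elec = −kT·ln(K_B/K_B,ref)` with the n_PG = 0 population as reference;
reported in kT and Joules.

## Electrostatics

Debye length of a symmetric 1:1 electrolyte in water (ε_r = 78.4, 298 K):
`λ = sqrt(ε_r ε_0 kT / (2 N_A e² I))`; 0.785 nm at 150 mM. The surface
charge density of a bilayer with anionic fraction n_PG is
`σ = −e·n_PG/a_L` with one elementary charge per PG headgroup and area per
lipid a_L = 0.70 nm² (standard fluid-phase PC/PG value). The Grahame
equation `σ = sqrt(8 c₀ ε ε₀ kT)·sinh(eφ/2kT)` is inverted analytically
for the surface potential: linear in σ below ~25 mV, sublinear (asinh)
beyond.

The probe–membrane interaction is a screened point charge:
`Δε = −q_DNA·e·Δφ·exp(−κd)/kT` with q_DNA = 24 the *magnitude* of the
duplex charge in elementary charges. The sign convention is chosen so
that the physically anionic probe (−24e) in the negative potential of an
anionic membrane yields a positive (repulsive) energy, matching the
positive measured Δε against negative zeta potentials; the model is odd
and exactly linear in Δφ at fixed d.

**Probe-distance fit** (`electrostatics.fit_probe_distance`). With q_DNA
and κ fixed, d only rescales the Δε-vs-φ_z slope, so the fit is a bounded
1-D minimisation on d ∈ [0, 10] nm (tolerance 1e-10 nm). The default
objective minimises *fractional* residuals: repulsion energies derived
from binding-constant ratios carry approximately constant relative error,
and absolute residuals would concentrate nearly all weight on the
largest-|φ_z| pairs (the slope estimate then rests on 2–3 points and its
pairs-bootstrap SE becomes unreliable). Zero-energy pairs (the reference
composition) carry no slope information under this scaling and are
excluded; an `loss="absolute"` mode is available. SEs come from a pairs
bootstrap (default 1000, seeded).

## Image quantification

The annulus measurement reproduces the standard FIJI workflow: a circle
along the inside perimeter of the membrane, expanded into a band of 1 µm
physical thickness. Band membership uses the pixel-centre distance with a
half-open interval `r_in ≤ r < r_in + w` — the closest exactly-testable
analogue of ImageJ's "Make band"; no subpixel area weighting. The local
background is an offset annulus 2–6 px beyond the outer band radius (the
exact experimental background ROI is a free choice; a nearby annulus keeps
it local to each vesicle). Vesicle selection is annotation-driven, not
automated. Batch processing routes failing rows (missing image,
out-of-bounds annulus) to a skip table with reasons instead of aborting.

## Calibration

Intensity↔concentration conversion is a free-intercept ordinary
least-squares line per channel (membrane channel in intensity per mol %,
solution channel per µM). The background-subtracted membrane signal has
its additive offset cancelled, so membrane conversions use a zero net
offset by default. Negative conversions — legitimate products of
background-subtraction noise — are floored at zero and flagged rather
than rejected; conversions outside the calibrated concentration range are
flagged but returned. Whether the membrane gain is per-area or per-mole is
ambiguous in principle; we define it in intensity per mol % throughout.

## Synthetic data

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes:

- **Populations.** Vesicle-to-vesicle heterogeneity is placed on K_B —
  each vesicle draws K from a log-normal with median K_B_true and chosen
  CV (default 0.3, a free parameter: the empirical spread behind the
  observed broad single-vesicle distributions is not quantified anywhere
  we can import it from). The rationale for putting the spread on K_B is
  that per-vesicle surface differences (e.g. residual solvent altering
  surface charge) act through the binding constant, not the packing limit.
  Free DNA is fixed per level at the added concentration (incubation
  volume ≫ membrane capacity, so depletion is negligible). Intensities
  are forward calibrations plus optional Gaussian noise; measured
  concentrations are recovered through the same calibrations, so zero
  noise and zero CV reproduce the Langmuir curve exactly and population
  means converge to it as n grows. Draws that would reach `[DNA]_max`
  are resampled with an iteration bound — with the pure Langmuir
  evaluation the bound is unreachable (bound fractions are strictly below
  saturation), so the guard only matters for user-supplied samplers.
- **Images.** One vesicle per square tile (64 px at 0.25 µm/px by
  default): a radially Gaussian ring (σ = 0.4 µm) over a flat background,
  with the peak amplitude scaled so the *band-mean* equals the record's
  net intensity; annulus re-measurement recovers the record to ~2 %
  (profile discretisation plus the faint tail the background annulus picks
  up). Tiles write as 16-bit single-channel TIFFs with a pixel-accurate
  annotations CSV.
- **Zeta tables.** φ_z = Grahame surface potential of σ(n_PG) plus
  Gaussian noise. This idealisation ignores counterion binding and the
  surface-to-slipping-plane offset, so its potentials are substantially
  more negative than experimental zeta potentials of equivalent vesicles —
  which is why the demo pipeline's fitted probe distance (~3 nm) exceeds
  the reference value recovered when pairs are generated from the screened
  model itself.
- **Mixing runs.** Per-vesicle dye intensities share a log-normal
  brightness factor (size/illumination) with mean-one multiplicative
  channel scatter, so the population mean of I_NBD/I_Rhod is exactly
  proportional to Q_A/Q_B.

What passing tests on these data do *not* show about real micrographs:
no instance segmentation or focus selection is exercised (annotations are
ground truth), detector nonlinearity/bleaching are absent, vesicle size
variation enters only as a brightness factor, and the K_B spread is
modelled, not measured.

## Pipeline

Stages (simulate → quantify → calibrate → fit → electro → mixing) exchange
CSV/JSON artifacts in a run directory so each is independently re-runnable;
per-stage seeds derive deterministically from the global seed (seed +
stage index), making runs byte-reproducible. The simulated ground truth
follows the empirical exponential charge law (K_B0 = 4.7 per-µM, B = 3.2),
which keeps all compositions within one titration grid's dynamic range.
The on-chip/off-chip comparison standardises each composition's mean K_B
against the law prediction including the law's own prediction SE, with a
pass flag at max |z| ≤ 2 — a deliberately strict gate that flags ~10–15 %
of law-consistent runs with three groups.

## Reference study sizes

Recovery studies (`vescharge.studies`, also used by
`scripts/acceptance.py`) run at 6 titration levels × 300 vesicles with
30 % CV for isotherm recovery; five compositions × 300 vesicles × two
levels (sub-saturating and saturating, K·[DNA] of 0.3 and 3) for the
charge law; 8 zeta/energy pairs spanning −5 to −40 mV with 5 %
multiplicative noise for the probe distance. Titration grids are
{0.05, 0.1, 0.2, 0.5, 1, 2} µM (zwitterionic) and
{0.1, 0.25, 0.5, 1, 2, 5} µM (1:1 anionic), each bracketing the
composition's 1/K_B. Each study completes in seconds on one CPU.

## Known limitations

- The exponent placement of ε_elec and the concrete form of the screened
  interaction are adopted as the minimal forms consistent with the
  effective-constant relation and the observed Δε–φ_z linearity; both are
  isolated behind single functions.
- Only equilibrium constants are modelled — no binding kinetics, no
  DNA–DNA interaction or mechanical-coupling corrections at high coverage.
- The Grahame layer assumes a symmetric 1:1 electrolyte; mixed buffers
  (phosphate + NaCl) are represented by an equivalent ionic strength.
- No full Poisson–Boltzmann, Stern-layer capacitance or ion-specific
  corrections; the width→flow conversion assumes equal mean stream
  velocities (matched viscosities) and no diffusive broadening at the
  junction.
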