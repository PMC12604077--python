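# Methods

## Spin simulation

Each metabolite is a system of n ≤ 8 spin-½ nuclei with chemical shifts δᵢ
(ppm) and a symmetric scalar-coupling matrix Jᵢⱼ (Hz), taken from the
standard literature compilation of brain-metabolite constants and shipped as
a versioned JSON file with a provenance string. Equivalent protons that are
uncoupled (Gly CH₂, Cr/PCr CH₃ and CH₂, N(CH₃)₃ groups, scyllo-inositol)
are collapsed to one spin with an integer weight; equivalent protons whose
couplings matter (the lactate CH₃ against its CH) are kept as explicit
identical-shift spins. Two deliberate reductions: choline-family CH₂–CH₂
fragments are modeled as a weighted two-spin pair (their A₂B₂ fine structure
is irrelevant at 8 Hz linewidth and 3T), and glutathione/NAAG are omitted
(documented in the library file) because no ≤8-spin reduction represents
them faithfully; both are minor contributors in the 3.4–3.7 ppm window this
package is about.

The rotating-frame Hamiltonian is

    H = Σᵢ 2π νᵢ Iᵢz + Σᵢ<ⱼ 2π Jᵢⱼ Iᵢ·Iⱼ ,   νᵢ = (δᵢ − ref) · f₀ ,

with the full isotropic coupling term retained — the mI ring protons are
strongly coupled at 3T (Δν/J of order 1–10) and the pseudo-singlet effect
*is* a strong-coupling phenomenon. Defaults: f₀ = 127.7 MHz (3 T),
reference at water, 4.7 ppm. The sequence model is an ideal 90°ₓ excitation
followed by instantaneous 180°ᵧ refocusing rotations separated by free
evolution; no relaxation anywhere, so all TE dependence is pure
J-modulation. Acquisition starts exactly at the echo center; the FID is
evaluated exactly as a sum over single-quantum coherences in the eigenbasis
of H and normalized so an uncoupled weighted spin contributes
w·exp(+i2πνt).

### Echo-time partition

Vendor PRESS places the first refocusing pulse as early as the hardware
allows; the first sub-echo is short and roughly TE-independent while the
second absorbs the rest of the echo time. We use TE1 = min(TE/2, 26 ms),
TE2 = TE − TE1 (segments TE1/2, TE1/2 + TE2/2, TE2/2). For sLASER the first
inter-pulse gap is min(TE/6, 6 ms) with the remaining four refocusing
intervals in equal CPMG spacing; both satisfy the echo condition
(alternating-sign segment sum zero) so chemical shift is fully refocused at
acquisition. This asymmetry matters for strongly coupled spins: it is what
makes the simulated mI multiplet collapse to a positive pseudo-singlet at
3.56 ppm at TE 135 ms and invert with a ~4–5× reduced residual at TE
280 ms. A symmetric (TE/4, TE/2, TE/4) split — tempting on paper — moves
the TE-135 extremum to ~3.66 ppm and suppresses the long-TE polarity
inversion, i.e. it does not reproduce the behavior vendor sequences show.
The outputs are robust over the physically plausible first-echo range
(TE1 ≈ 12–30 ms changes the long-TE Gly/mI ratio only between ~3.7 and
~4.4). Both partition parameters are exposed as `make_timing` keyword
arguments. Exact vendor timings and shaped/adiabatic pulse waveforms are
not modeled; line-by-line amplitude agreement with shaped-pulse simulators
is therefore approximate by construction (ideal pulses slightly understate
sLASER intensity at long TE).

### Known accuracy limits

Hard 180° pulses applied to both partners of a coupled pair mix coherences
at first order in J/Δν. Consequently the textbook weak-coupling echo law
(doublet modulation cos(πJ·TE)) is approached only asymptotically: at
Δν/J ≈ 100 the deviation is still ~1%, first order in J/Δν. The test suite
pins this envelope explicitly and verifies the closed form at 1e-6 in the
deep weak-coupling regime (J/Δν ≲ 1e-7); correctness at realistic couplings
is established against an independently coded brute-force two-spin oracle
(agreement ~1e-13).

## Lineshape and acquisition

Apodization realizes the requested full-width-at-half-maximum: exponential
`exp(−π·lw·t)` for Lorentzian, `exp(−(π·lw·t)²/(4 ln 2))` for Gaussian. The
spectrum is the plain FFT of the apodized FID (Parseval holds exactly), on
an ascending ppm axis `ref + f/f₀`. Default grid 4000 Hz / 8192 complex
points; desk-scale analyses use 2500 Hz / 4096 points (0.61 Hz resolution,
still covering 0–10 ppm at 3T).

## Synthetic data

Phantom spectra are concentration-weighted sums of simulated metabolite
FIDs (the shipped recipe is the standard six-metabolite QA phantom: 12.5 mM
NAA, 10 creatine, 3 choline, 7.5 mI, 5 lactate, 12.5 glutamate). In-vivo-like
spectra use tCr-relative concentrations anchored on literature averages
(mI/tCr = 0.74; Gly set via the target mI/Gly ratio, default 9, or absent),
with the remaining levels chosen once as neonatal-plausible: NAA 1.0,
Cr/PCr 0.5 each, GPC/PCho 0.15 each, Glu 0.8, Gln 0.3, Lac 0.3 (mild
elevation), Tau 0.5.

Noise model: the linewidth envelope is applied to the *signal* (it stands
in for T2*/shim decay), then i.i.d. complex Gaussian noise is added in the
time domain — so the spectral noise floor is white, as in a real receiver.
`noise_sigma` is the spectral noise SD as a fraction of the noiseless NAA
peak height; the generator converts it analytically to the time-domain SD,
which makes the noise level directly verifiable from the signal-free
9–10 ppm region. The in-vivo baseline is the sum of three broad Gaussians
with seeded random centers (0.5–4.5 ppm), widths (0.3–1 ppm) and signed
amplitudes, scaled by `baseline_amplitude` × NAA peak (default 0.1), added
to the real part. Every spectrum carries a truth record with the exact
generator inputs.

What the generator does **not** emulate: macromolecule resonances, eddy
currents and frequency drift, voxel compartmentation, non-Lorentzian
lineshapes, and T1/T2 relaxation. Passing recovery tests therefore
demonstrate properties of the estimator under a well-specified model, not
in-vivo accuracy; in real data the mI/Gly confound can only be worse.

## Fitting

The model for the real part over the fit window (default 0.2–4.2 ppm) is

    Re{ e^{iφ} Σₘ cₘ Bₘ(f; Δf, γ) } + Σₖ bₖ Pₖ(x) ,

with cₘ ≥ 0 the metabolite amplitudes, Δf a global frequency shift
(±10 Hz), φ a zero-order phase, γ ≥ 0 extra Lorentzian broadening applied
to the basis (≤ 20 Hz), and Pₖ Legendre polynomials of order ≤ 4 on the
window (LCModel's regularized spline baseline is out of scope; a low-order
polynomial captures the same smooth nuisance at this scale). Basis
transforms are done in the time domain and resampled onto the data axis
when axes differ.

Optimization is by variable projection: amplitudes and baseline solve a
bounded linear least-squares subproblem (BVLS) inside a trust-region
nonlinear solve over (Δf, φ, γ), started from three fixed points
(0,0,0), (+2 Hz, 0, 3 Hz), (−2 Hz, 0, 3 Hz) to avoid local minima; cost
tolerance 1e-10. A basis condition number above 1e8 is recorded as a
warning in the result rather than an error (Cr/PCr are intentionally
near-collinear; their sum tCr is the meaningful quantity, and ratio tables
are reported against tCr, with mI/Gly left undefined when the Gly estimate
is zero).

Uncertainty: σ is the SD of the real part in 9–10 ppm (signal-free; if that
region is identically zero — fully synthetic inputs — a nominal unit σ is
used, which leaves the CMC unchanged and only rescales CRLBs). The Fisher
information F = JᵀJ/σ² uses the analytic Jacobian over all parameters
(amplitudes, active nuisances, baseline); C = F⁻¹ (pseudo-inverse with a
flag if rank-deficient). CRLB%ₘ = 100·√Cₘₘ/cₘ (undefined at cₘ = 0), and
the CMC is the correlation matrix of the amplitude block — nuisance
parameters are profiled out by inclusion in J, which matches the intent of
"interaction between two model parameters within a single dataset". The
white-noise assumption behind F is satisfied by the generator's noise model
above.

## Separability pipeline

Similarity is the Pearson correlation of the unit-normalized mI and Gly
basis real parts restricted to 3.4–3.7 ppm — a scalar operationalization of
"indistinguishable by visual inspection"; no diagnostic cutoff is attached
to it. The amplitude-ratio curve reports max|Re| of Gly over max|Re| of mI
in the window at equal concentration, with the sign of the mI extremum kept
separately so the "~5× smaller and inverted" long-TE statement can be read
directly. Recovery experiments fit n ≥ 10 seeded replicates per TE with the
11-metabolite default basis and aggregate fitted mI/Gly (over replicates
with nonzero Gly), CRLB%, mean CMC(mI, Gly), and the spurious-Gly fraction
when the truth contains no glycine. The default noise level is calibrated
at run time so the NAA CRLB is ≈ 5% at short TE (CRLB is linear in σ, so
one noiseless Fisher evaluation fixes it; the calibrated value is ~0.096 of
the NAA peak for the default recipe), mirroring routine clinical quality.

Problem sizes used by the shipped analyses: 2500 Hz / 4096-point grids,
50 replicates per TE for the sign-structure experiments, 11-metabolite
basis — small enough to run on a laptop in minutes while leaving the
sign structure and ratio estimates stable across seeds.

## Design choices that were genuinely open

* **TE partition** — see above; asymmetric vendor-like splits, exposed as
  parameters.
* **CMC definition** — normalized covariance from the inverse Fisher matrix
  over amplitudes with nuisances profiled out; proprietary implementations
  may normalize differently, so only the sign structure (negative at short
  TE, positive at long TE) is treated as comparable across software.
* **Gly reference value** — the library stores the literature shift
  (3.548 ppm); displays round to 3.55.
* **Noise placement** — signal-side broadening with white receiver noise
  (see Synthetic data), chosen so the Fisher model is exact for the
  generator and noise is verifiable from the data.
* **Spurious-Gly threshold** — a replicate counts as spurious if the fitted
  Gly amplitude exceeds 1e-6 (BVLS returns exact zeros at the bound, so
  this is effectively "nonzero").

## Limitations

Ideal pulses overstate refocusing fidelity; no spatial localization or
chemical-shift displacement; no relaxation (long-TE SNR loss in practice is
therefore not represented — real long-TE spectra are noisier than the
simulated ones at equal σ); literature constants carry their own small
uncertainties; the in-vivo recipe is a plausible neonatal composition, not
a reconstruction of any patient.
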