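# spinfit

Density-matrix simulation of clinical ¹H-MRS echo sequences, linear-combination
spectral fitting, and Fisher-information diagnostics of metabolite
separability — built around one concrete clinical question: **when can
glycine (Gly) be distinguished from myo-inositol (mI) in brain MRS at 3T?**

Gly is a two-proton singlet at 3.55 ppm, elevated in nonketotic
hyperglycinemia and some tumors. mI has six strongly coupled protons
(3.27–4.05 ppm) whose multiplet evolves with echo time (TE) through scalar
(J) coupling. At intermediate TE (~135 ms) the mI multiplet collapses into a
narrow "pseudo-singlet" at ~3.55 ppm that closely mimics Gly; a reader (or a
fit with a poorly conditioned basis) can mistake one for the other. At long
TE (~280 ms) most of the mI signal has dephased and the small residual has
polarity *opposite* to Gly, so the two become visually separable. This
package quantifies that behavior end to end, on synthetic data with known
ground truth.

## What it computes

* **Spin simulation** (`spinfit.sequence_sim`): ideal-pulse PRESS (2 refocusing
  pulses) and semi-LASER (4) echo trains for arbitrary coupled spin systems,
  propagating the density operator under
  `H = Σᵢ 2π νᵢ Iᵢz + Σᵢ<ⱼ 2π Jᵢⱼ Iᵢ·Iⱼ` with the full (strong-coupling)
  scalar term and no relaxation; FIDs are apodized to a target Lorentzian or
  Gaussian linewidth and Fourier transformed.
* **Spin constants** (`spinfit.spin_library`): literature chemical shifts and
  J-couplings for the standard brain-MRS basis compounds, validated on load.
* **Linear-combination fitting** (`spinfit.lc_fit`): non-negative amplitudes ×
  basis spectra, global frequency shift, zero-order phase, extra broadening,
  polynomial baseline; solved by variable projection. At the optimum it
  reports **CRLB%** (minimum achievable relative SD of each amplitude, from
  the inverse Fisher information `C = (JᵀJ/σ²)⁻¹`) and the **CMC** matrix
  (coefficient of model covariance, `C_ij/√(C_ii C_jj)` over the amplitude
  block) — a strongly negative CMC(mI, Gly) means the fit can trade one
  metabolite for the other.
* **Synthetic data** (`spinfit.synthetic`): a multi-metabolite QA-phantom
  recipe and neonatal in-vivo-like spectra with literature-anchored
  concentrations, seeded white noise and a smooth random baseline, each with
  an exact truth record.
* **Separability pipeline** (`spinfit.pitfall`): TE-resolved mI–Gly spectral
  similarity, signed Gly/mI amplitude-ratio curves, and recovery experiments
  (fit many noisy replicates, aggregate fitted mI/Gly, CRLB%, CMC and the
  spurious-Gly fraction).

## Worked example

```python
from spinfit import (default_library, amplitude_ratio_curve,
                     default_invivo_recipe, recovery_experiment,
                     calibrate_noise_sigma)

curve = amplitude_ratio_curve(default_library(), "press", [35.0, 135.0, 280.0])
print(curve[["te_ms", "similarity", "gly_to_mi_ratio",
             "mi_sign", "mi_extremum_ppm"]].round(3))
```

```
 te_ms  similarity  gly_to_mi_ratio  mi_sign  mi_extremum_ppm
  35.0       0.936            1.214      1.0            3.548
 135.0       0.704            2.741      1.0            3.562
 280.0      -0.734            3.931     -1.0            3.562
```

Reading: at TE 35 and 135 ms the mI extremum sits at the Gly position with
the same polarity (`mi_sign = 1`) and an amplitude comparable to Gly — the
pseudo-singlet regime. At TE 280 ms the windowed correlation turns negative,
the residual mI is ~4× smaller than an equal concentration of Gly, and its
polarity is inverted: long TE separates the two.

Fitting noisy Gly-free spectra (so any fitted Gly is spurious) at a noise
level calibrated to ~5% NAA CRLB:

```python
sigma = calibrate_noise_sigma()             # 0.096 of the NAA peak height
truth = default_invivo_recipe(mi_gly_ratio=None, noise_sigma=sigma)
df = recovery_experiment(truth, "press", [35.0, 280.0], n_reps=20, seed=17)
print(df[["te_ms", "mean_cmc_mi_gly", "spurious_gly_fraction",
          "mean_crlb_gly"]].round(3))
```

```
 te_ms  mean_cmc_mi_gly  spurious_gly_fraction  mean_crlb_gly
  35.0           -0.854                   0.60        237.644
 280.0            0.795                   0.45        370.159
```

CMC(mI, Gly) is strongly negative at short TE (near-collinear basis
functions: the fit reports a spurious Gly in 60% of replicates even though
the truth contains none) and positive at long TE (opposite-polarity
overlap). Triple-digit Gly CRLBs say the Gly estimate is essentially
unconstrained at this spectral quality — the pitfall in numbers.

The same analyses are available from the shell:

```bash
spinfit pitfall-report --sequence press --te 35,135,280 --reps 50 --seed 17 --out report/
spinfit simulate-basis --metabolites mI,Gly --sequence press --te 135 --linewidth 8 --out basis/
spinfit synth --te 135 --mi-gly-ratio 9 --seed 1 --out spec.csv
spinfit fit --data spec.csv --basis basis/ --out fit.json
```

## Scope notes

Refocusing pulses are ideal instantaneous rotations: shaped/adiabatic
waveform effects, spatial localization, chemical-shift displacement and
T1/T2 relaxation are out of scope (see `docs/methods.md` for the full model
description and its limitations).
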