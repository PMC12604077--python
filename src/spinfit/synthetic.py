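"""Synthetic phantom and in-vivo-like spectra with known ground truth.

Every downstream analysis in this package is exercised on data produced
here: concentration-weighted sums of density-matrix simulated metabolite
signals, i.i.d. complex Gaussian noise added in the time domain, and (for
the in-vivo generator) a smooth random baseline of broad Gaussians. Each
generated spectrum is paired with a truth record holding the exact inputs,
so generator output is fully reproducible from its sidecar.

Noise model: line broadening is part of the *signal* (it stands in for
the physical T2*/field-inhomogeneity decay), while receiver noise is
i.i.d. complex Gaussian in the time domain added after the decay — so
the spectral noise floor is white, as in a real acquisition.
``noise_sigma`` is expressed as a fraction of the reference (NAA) peak
height of the noiseless spectrum: the standard deviation of the real
part in a signal-free region equals ``noise_sigma × NAA peak``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_sim import (
    FID,
    AcquisitionGrid,
    SequenceKind,
    SequenceTiming,
    Spectrum,
    fid_to_spectrum,
    make_timing,
    simulate_echo,
)
from .spin_library import SpinLibrary, default_library, get_system

__all__ = [
    "PhantomRecipe",
    "InVivoRecipe",
    "BRAINO_RECIPE",
    "default_invivo_recipe",
    "SpectrumSampler",
    "make_phantom_spectrum",
    "make_invivo_spectrum",
    "make_te_series",
]


@dataclass(frozen=True)
class PhantomRecipe:
    """Metabolite concentrations (mM) of a quality-assurance phantom."""

    concentrations: dict[str, float]
    temperature_note: str = "room temperature"

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c <= 0:
                raise ValueError(f"concentration of {name} must be > 0, got {c}")


#: The GE "braino" multi-metabolite phantom composition.
BRAINO_RECIPE = PhantomRecipe(
    concentrations={
        "NAA": 12.5,
        "Cr": 10.0,
        "Cho": 3.0,
        "mI": 7.5,
        "Lac": 5.0,
        "Glu": 12.5,
    }
)


@dataclass(frozen=True)
class InVivoRecipe:
    """Ground-truth recipe for an in-vivo-like brain spectrum.

    Concentrations are in tCr-relative arbitrary units (Cr + PCr = 1).
    Glycine is not listed directly: its level is mI / ``mi_gly_ratio``,
    or zero when ``mi_gly_ratio`` is None (the hypoxic-ischemic
    encephalopathy scenario in which any 3.55 ppm signal is pure mI).
    """

    concentrations: dict[str, float]
    mi_gly_ratio: float | None = 9.0
    noise_sigma: float = 0.02
    baseline_amplitude: float = 0.1
    linewidth_hz: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.mi_gly_ratio is not None and self.mi_gly_ratio <= 0:
            raise ValueError("mi_gly_ratio must be > 0 or None")

    def effective_concentrations(self) -> dict[str, float]:
        conc = dict(self.concentrations)
        mi = conc.get("mI", 0.0)
        conc["Gly"] = mi / self.mi_gly_ratio if self.mi_gly_ratio else 0.0
        return conc

    @property
    def true_mi_gly(self) -> float | None:
        """True mI/Gly ratio; None (undefined) when Gly is absent."""
        return self.mi_gly_ratio


def default_invivo_recipe(
    mi_gly_ratio: float | None = 9.0,
    noise_sigma: float = 0.02,
    baseline_amplitude: float = 0.1,
    linewidth_hz: float = 8.0,
    seed: int = 0,
) -> InVivoRecipe:
    """Neonatal-brain-like recipe anchored on literature tCr ratios.

    mI/tCr = 0.74 is the gray-matter literature average; the default
    mI/Gly of 9 matches the literature consensus for normal brain. The
    remaining levels are textbook-plausible for a term neonate: NAA lower
    and choline/taurine higher than in the adult brain, with a mild
    lactate elevation.
    """
    conc = {
        "Cr": 0.5,
        "PCr": 0.5,
        "NAA": 1.0,
        "GPC": 0.15,
        "PCho": 0.15,
        "Glu": 0.8,
        "Gln": 0.3,
        "Lac": 0.3,
        "Tau": 0.5,
        "mI": 0.74,
    }
    return InVivoRecipe(
        concentrations=conc,
        mi_gly_ratio=mi_gly_ratio,
        noise_sigma=noise_sigma,
        baseline_amplitude=baseline_amplitude,
        linewidth_hz=linewidth_hz,
        seed=seed,
    )


# ---------------------------------------------------------------------------


class SpectrumSampler:
    """Draws noisy realizations of one fixed composition/sequence/TE.

    The expensive density-matrix simulation of the noiseless
    concentration-weighted FID happens once at construction; each
    :meth:`draw` then adds a fresh complex Gaussian noise realization in
    the time domain (and, optionally, a smooth random baseline in the
    frequency domain) and returns the broadened spectrum with its truth
    record.
    """

    def __init__(
        self,
        concentrations: dict[str, float],
        timing: SequenceTiming,
        grid: AcquisitionGrid,
        linewidth_hz: float = 8.0,
        noise_sigma: float = 0.0,
        baseline_amplitude: float = 0.0,
        lib: SpinLibrary | None = None,
        lineshape: str = "lorentzian",
        reference_metabolite: str = "NAA",
    ):
        if noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lib = lib or default_library()
        self.concentrations = dict(concentrations)
        self.timing = timing
        self.grid = grid
        self.linewidth_hz = linewidth_hz
        self.lineshape = lineshape
        self.noise_sigma = noise_sigma
        self.baseline_amplitude = baseline_amplitude

        fid_sum = np.zeros(grid.n_points, dtype=complex)
        for name, c in concentrations.items():
            if c == 0.0:
                continue
            sys = get_system(lib, name)
            fid_sum += c * simulate_echo(sys, timing, grid).samples
        self._meta = {
            "sequence": timing.kind.value,
            "te_ms": timing.te_ms,
            "f0_mhz": grid.f0_mhz,
            "linewidth_hz": linewidth_hz,
            "lineshape": lineshape,
        }
        # broaden the signal once: the decay envelope models T2*/shim losses
        # and belongs to the signal, not to the receiver noise
        fid = FID(samples=fid_sum, grid=grid, meta=dict(self._meta))
        broadened = fid_to_spectrum(fid, linewidth_hz, lineshape)
        self._fid_sum = np.fft.ifft(np.fft.ifftshift(broadened.values))

        clean = self._spectrum(self._fid_sum)
        ref = clean.window(1.9, 2.1) if reference_metabolite == "NAA" else clean
        peak = float(np.abs(ref.values.real).max())
        if peak <= 0:
            peak = float(np.abs(clean.values.real).max())
        self.reference_peak = peak
        # white time-domain noise gives a flat spectral noise floor with
        # Var(Re S) = n * sigma_time^2 under the unnormalized FFT
        self.sigma_spectral = noise_sigma * peak
        self._sigma_time = (
            self.sigma_spectral / np.sqrt(grid.n_points) if noise_sigma else 0.0
        )

    def _spectrum(self, samples: np.ndarray) -> Spectrum:
        vals = np.fft.fftshift(np.fft.fft(samples))
        return Spectrum(ppm=self.grid.ppm_axis, values=vals, meta=dict(self._meta))

    def _baseline(self, rng: np.random.Generator) -> np.ndarray:
        """Sum of 3 broad random Gaussians over 0.5-4.5 ppm (real part)."""
        ppm = self.grid.ppm_axis
        base = np.zeros(ppm.size)
        for _ in range(3):
            center = rng.uniform(0.5, 4.5)
            width = rng.uniform(0.3, 1.0)
            amp = rng.uniform(-1.0, 1.0)
            base += amp * np.exp(-0.5 * ((ppm - center) / width) ** 2)
        return self.baseline_amplitude * self.reference_peak * base

    def draw(self, seed: int) -> tuple[Spectrum, dict]:
        rng = np.random.default_rng(seed)
        samples = self._fid_sum
        if self.noise_sigma > 0:
            n = self.grid.n_points
            noise = self._sigma_time * (
                rng.standard_normal(n) + 1j * rng.standard_normal(n)
            )
            samples = samples + noise
        spec = self._spectrum(samples)
        if self.baseline_amplitude > 0:
            spec.values = spec.values + self._baseline(rng)
        truth = {
            "concentrations": dict(self.concentrations),
            "sequence": self.timing.kind.value,
            "te_ms": self.timing.te_ms,
            "linewidth_hz": self.linewidth_hz,
            "lineshape": self.lineshape,
            "noise_sigma": self.noise_sigma,
            "sigma_spectral": self.sigma_spectral,
            "baseline_amplitude": self.baseline_amplitude,
            "seed": seed,
            "grid": {
                "f0_mhz": self.grid.f0_mhz,
                "sweep_width_hz": self.grid.sweep_width_hz,
                "n_points": self.grid.n_points,
                "ref_ppm": self.grid.ref_ppm,
            },
        }
        gly = self.concentrations.get("Gly", 0.0)
        mi = self.concentrations.get("mI", 0.0)
        truth["mi_gly"] = mi / gly if gly > 0 else None
        return spec, truth


def make_phantom_spectrum(
    recipe: PhantomRecipe,
    timing: SequenceTiming,
    grid: AcquisitionGrid | None = None,
    linewidth_hz: float = 8.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    lib: SpinLibrary | None = None,
) -> tuple[Spectrum, dict]:
    """Concentration-weighted phantom spectrum plus truth record."""
    grid = grid or AcquisitionGrid()
    sampler = SpectrumSampler(
        recipe.concentrations,
        timing,
        grid,
        linewidth_hz=linewidth_hz,
        noise_sigma=noise_sigma,
        lib=lib,
    )
    spec, truth = sampler.draw(seed)
    truth["temperature_note"] = recipe.temperature_note
    return spec, truth


def make_invivo_spectrum(
    recipe: InVivoRecipe,
    timing: SequenceTiming,
    grid: AcquisitionGrid | None = None,
    lib: SpinLibrary | None = None,
) -> tuple[Spectrum, dict]:
    """In-vivo-like spectrum: metabolites + noise + smooth baseline."""
    grid = grid or AcquisitionGrid()
    sampler = SpectrumSampler(
        recipe.effective_concentrations(),
        timing,
        grid,
        linewidth_hz=recipe.linewidth_hz,
        noise_sigma=recipe.noise_sigma,
        baseline_amplitude=recipe.baseline_amplitude,
        lib=lib,
    )
    return sampler.draw(recipe.seed)


def make_te_series(
    recipe: PhantomRecipe | InVivoRecipe,
    kind: SequenceKind | str,
    te_list_ms: Sequence[float],
    grid: AcquisitionGrid | None = None,
    lib: SpinLibrary | None = None,
    **phantom_kwargs,
) -> list[tuple[Spectrum, dict]]:
    """One spectrum per echo time, shared truth, independent noise draws.

    Per-TE seeds are derived deterministically from the recipe seed via a
    seed sequence, so the series is reproducible as a whole.
    """
    if not te_list_ms:
        raise ValueError("te_list_ms must be non-empty")
    grid = grid or AcquisitionGrid()
    base_seed = (
        recipe.seed if isinstance(recipe, InVivoRecipe) else phantom_kwargs.get("seed", 0)
    )
    children = np.random.SeedSequence(base_seed).spawn(len(te_list_ms))
    out = []
    for te, child in zip(te_list_ms, children):
        timing = make_timing(kind, te)
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        if isinstance(recipe, InVivoRecipe):
            sub = InVivoRecipe(
                concentrations=recipe.concentrations,
                mi_gly_ratio=recipe.mi_gly_ratio,
                noise_sigma=recipe.noise_sigma,
                baseline_amplitude=recipe.baseline_amplitude,
                linewidth_hz=recipe.linewidth_hz,
                seed=sub_seed,
            )
            out.append(make_invivo_spectrum(sub, timing, grid, lib=lib))
        else:
            kw = dict(phantom_kwargs)
            kw["seed"] = sub_seed
            out.append(make_phantom_spectrum(recipe, timing, grid, lib=lib, **kw))
    return out
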