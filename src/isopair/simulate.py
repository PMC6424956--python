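"""Seeded synthetic MALDI-TOF profile spectra for light/heavy peptide pairs.

The instrument model is deliberately simple: every (species, adduct,
isotopologue) combination contributes a Gaussian whose area is proportional
to molar abundance x adduct fraction x isotopologue abundance, with FWHM set
by a single resolving power m/dm.  A flat baseline and additive Gaussian
noise (optionally with an intensity-proportional component) complete the
model.  Desorption/ionization efficiency is identical for light and heavy
species — the premise that makes the labelled peptide a valid internal
standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .chem import PeptideSpecies, adduct_mz, compose_peptide, isotope_pattern

__all__ = ["SimConfig", "Spectrum", "simulate_spectrum", "simulate_dilution_series"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default relative adduct propensities, qualitatively matching reflector
#: MALDI spectra of peptides in an alpha-cyano matrix.
DEFAULT_ADDUCT_ABUNDANCES: Dict[str, float] = {"H": 1.0, "Na": 0.3, "K": 0.1}


@dataclass(frozen=True)
class Spectrum:
    """Profile mass spectrum: strictly increasing m/z, non-negative intensity."""

    mz: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz must be strictly increasing")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)

    def __len__(self) -> int:
        return self.mz.size

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.mz, self.intensity * factor, dict(self.metadata))


@dataclass(frozen=True)
class SimConfig:
    """Instrument and acquisition parameters for the simulator.

    resolution
        FWHM resolving power m/dm (dimensionless).  10000 approximates a
        reflector TOF in the 1-2 kDa peptide range.
    mz_range, mz_step
        Acquisition window and sampling step in Da.  The step should be at
        most FWHM/10 for the area-conservation guarantees to hold.
    adduct_abundances
        Relative propensity of the H+/Na+/K+ cationized forms; identical
        for light and heavy species.
    baseline_level, noise_sd, noise_proportional
        Flat chemical baseline, additive Gaussian noise sd, and an optional
        intensity-proportional noise coefficient, all in intensity units.
    intensity_scale
        Counts per unit molar abundance (per uM here).
    """

    resolution: float = 10000.0
    mz_range: Tuple[float, float] = (700.0, 1300.0)
    mz_step: float = 0.01
    adduct_abundances: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADDUCT_ABUNDANCES)
    )
    baseline_level: float = 0.0
    noise_sd: float = 0.0
    noise_proportional: float = 0.0
    intensity_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.mz_step <= 0:
            raise ValueError("mz_step must be positive")
        if self.mz_range[1] <= self.mz_range[0]:
            raise ValueError("mz_range must be an increasing (min, max) pair")
        if any(v < 0 for v in self.adduct_abundances.values()):
            raise ValueError("adduct abundances must be non-negative")
        if self.adduct_abundances.get("H", 0.0) <= 0:
            raise ValueError("the protonated adduct fraction must be positive")

    def grid(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(np.floor((hi - lo) / self.mz_step)) + 1
        return lo + self.mz_step * np.arange(n)


def simulate_spectrum(
    species_list: Sequence[Tuple[PeptideSpecies, float]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Simulate one profile spectrum of a peptide mixture.

    ``species_list`` pairs each :class:`~isopair.chem.PeptideSpecies` with a
    molar abundance (uM).  Identical inputs and seed give a bit-identical
    spectrum.  If every theoretical peak falls outside ``mz_range`` a
    warning is recorded in the metadata and a baseline-only spectrum is
    returned.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mz = config.grid()
    signal = np.zeros_like(mz)
    lo, hi = config.mz_range
    n_in_range = 0
    n_peaks = 0
    for species, abundance in species_list:
        if abundance < 0:
            raise ValueError("abundances must be non-negative")
        if abundance == 0:
            continue
        pattern = isotope_pattern(compose_peptide(species))
        for adduct, frac in config.adduct_abundances.items():
            if frac <= 0:
                continue
            for _, mass, iso_ab in pattern.items():
                center = adduct_mz(mass, adduct)
                area = abundance * frac * iso_ab * config.intensity_scale
                n_peaks += 1
                if not lo <= center <= hi:
                    continue
                n_in_range += 1
                sigma = (center / config.resolution) * _FWHM_TO_SIGMA
                # evaluate only within +-8 sigma of the center
                i0, i1 = np.searchsorted(mz, [center - 8 * sigma, center + 8 * sigma])
                window = mz[i0:i1]
                signal[i0:i1] += (
                    area / (sigma * np.sqrt(2 * np.pi))
                ) * np.exp(-0.5 * ((window - center) / sigma) ** 2)
    intensity = signal + config.baseline_level
    if config.noise_sd > 0 or config.noise_proportional > 0:
        sd = np.sqrt(config.noise_sd**2 + (config.noise_proportional * intensity) ** 2)
        intensity = intensity + rng.normal(0.0, 1.0, size=mz.size) * sd
    intensity = np.clip(intensity, 0.0, None)
    metadata = {
        "species": [
            {"name": sp.name or sp.sequence, "label": sp.label_state, "abundance": ab}
            for sp, ab in species_list
        ],
        "seed": config.seed,
        "n_theoretical_peaks": n_peaks,
        "n_peaks_in_range": n_in_range,
    }
    if n_peaks and not n_in_range:
        metadata["warning"] = "mz_range excludes all theoretical peaks; baseline-only spectrum"
    return Spectrum(mz, intensity, metadata)


def _child_seed(seed: int, index: int) -> int:
    """Deterministic child seed for series member ``index``."""
    ss = np.random.SeedSequence([int(seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_dilution_series(
    light: PeptideSpecies,
    heavy: PeptideSpecies,
    start_conc: float,
    fold: float,
    n_dilutions: int,
    config: SimConfig,
    heavy_to_light: float = 2.0,
) -> List[Tuple[float, Spectrum]]:
    """Simulate a serial-dilution series of a light/heavy mixture.

    Member ``i`` (i = 0..n_dilutions) holds the light peptide at
    ``start_conc * fold**-i`` with the heavy internal standard co-diluted at
    ``heavy_to_light`` times that concentration (the standard is mixed in
    before dilution, so the true light/heavy ratio is constant along the
    series).  Each member's spectrum uses a seed derived deterministically
    from ``(config.seed, i)``.
    """
    if start_conc <= 0:
        raise ValueError("start_conc must be positive")
    if fold <= 1:
        raise ValueError("dilution fold must exceed 1")
    if n_dilutions < 1:
        raise ValueError("n_dilutions must be at least 1")
    series: List[Tuple[float, Spectrum]] = []
    for i in range(n_dilutions + 1):
        conc = start_conc * fold ** (-i)
        member_cfg = replace(config, seed=_child_seed(config.seed, i))
        spec = simulate_spectrum(
            [(light, conc), (heavy, heavy_to_light * conc)], member_cfg
        )
        series.append((conc, spec))
    return series
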