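"""Energy-dependent attenuation of body materials and x-ray source spectra.

Attenuation is handled on a uniform 1 keV energy grid.  Mass-attenuation
coefficients for water, elemental iodine, cortical bone (ICRU-44) and
aluminium are embedded as CSV resources on the standard NIST energy grid
and interpolated log-log onto the working grid.  Iodine solutions follow
the dilute mixture rule

    mu(E; c) = mu_water(E) + c * 1e-3 * (mu/rho)_iodine(E)        [1/cm]

with ``c`` in mgI/ml, so attenuation is affine in concentration at every
energy.

Polyenergetic tube spectra are modelled as a filtered Kramers
bremsstrahlung continuum (tungsten anode): the unfiltered photon fluence
is proportional to (kVp - E)/E, hardened by an aluminium filtration slab.
The model is deliberately generic — the correction downstream is
calibration free, so only a realistic degree of spectral hardening
matters, not scanner-exact fidelity.  Monoenergetic (single bin) spectra
provide the beam-hardening-free reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "EnergyGrid",
    "Material",
    "SourceSpectrum",
    "WATER",
    "IODINE",
    "CORTICAL_BONE",
    "ALUMINUM",
    "iodine_solution",
    "linear_attenuation",
    "make_spectrum",
    "monoenergetic_spectrum",
    "effective_monoenergy",
    "spectrum_from_table",
]

#: Densities, g/cm3.
_DENSITY = {"water": 1.0, "bone_cortical": 1.92, "aluminum": 2.699}

SUPPORTED_KVP = (80, 120, 140)


def _load_table(name: str) -> tuple[np.ndarray, np.ndarray]:
    path = resources.files("abhc.data") / f"{name}.csv"
    raw = np.loadtxt(str(path), delimiter=",", comments="#")
    return raw[:, 0], raw[:, 1]


def _loglog_interp(e: np.ndarray, e_tab: np.ndarray, mu_tab: np.ndarray) -> np.ndarray:
    """Log-log interpolation of a tabulated attenuation curve."""
    e = np.asarray(e, dtype=float)
    if np.any(e < e_tab[0]) or np.any(e > e_tab[-1]):
        raise ValueError(
            f"energy outside tabulated range [{e_tab[0]}, {e_tab[-1]}] keV"
        )
    return np.exp(np.interp(np.log(e), np.log(e_tab), np.log(mu_tab)))


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform energy grid, 1 keV bins by default."""

    e_min: float = 10.0
    e_max: float = 150.0
    bin_width: float = 1.0
    energies: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.e_min <= 0 or self.e_max <= self.e_min or self.bin_width <= 0:
            raise ValueError("invalid energy grid bounds")
        e = np.arange(self.e_min, self.e_max + 0.5 * self.bin_width, self.bin_width)
        object.__setattr__(self, "energies", e)

    def __len__(self) -> int:
        return len(self.energies)

    def index_of(self, energy: float) -> int:
        i = int(round((energy - self.e_min) / self.bin_width))
        if not (0 <= i < len(self.energies)) or abs(self.energies[i] - energy) > 1e-9:
            raise ValueError(f"{energy} keV is not on the grid")
        return i


DEFAULT_GRID = EnergyGrid()


@dataclass(frozen=True)
class Material:
    """A material with tabulated mass attenuation and a density.

    ``iodine_mg_ml`` > 0 marks an aqueous iodine solution built from the
    water + elemental iodine tables via the dilute mixture rule.
    """

    name: str
    table: str
    density: float
    iodine_mg_ml: float = 0.0

    def mass_attenuation(self, energies) -> np.ndarray:
        e_tab, mu_tab = _load_table(self.table)
        return _loglog_interp(energies, e_tab, mu_tab)

    def linear_attenuation(self, energies) -> np.ndarray:
        """mu(E) in 1/cm."""
        mu = self.density * self.mass_attenuation(energies)
        if self.iodine_mg_ml:
            e_tab, mu_tab = _load_table("iodine")
            mu = mu + self.iodine_mg_ml * 1e-3 * _loglog_interp(
                energies, e_tab, mu_tab
            )
        return mu


WATER = Material("water", "water", _DENSITY["water"])
IODINE = Material("iodine", "iodine", 4.93)
CORTICAL_BONE = Material("bone_cortical", "bone_cortical", _DENSITY["bone_cortical"])
ALUMINUM = Material("aluminum", "aluminum", _DENSITY["aluminum"])


def iodine_solution(concentration_mg_ml: float) -> Material:
    """Aqueous iodine solution at the given concentration (mgI/ml)."""
    if concentration_mg_ml < 0:
        raise ValueError("concentration must be >= 0")
    return Material(
        f"iodine_{concentration_mg_ml:g}mg_ml",
        "water",
        1.0,
        iodine_mg_ml=concentration_mg_ml,
    )


def linear_attenuation(material: Material, energy) -> np.ndarray | float:
    """Linear attenuation mu(E) of ``material`` in 1/cm."""
    out = material.linear_attenuation(np.atleast_1d(energy))
    return float(out[0]) if np.isscalar(energy) else out


@dataclass(frozen=True)
class SourceSpectrum:
    """Normalized polyenergetic weight function Omega(E) for one tube setting.

    Invariant: sum(weights * bin_width) == 1 and weights vanish above kvp.
    ``total_fluence`` is the unattenuated photon count per detector bin
    (I0) used by the Poisson noise model.
    """

    kvp: float
    grid: EnergyGrid
    weights: np.ndarray
    total_fluence: float = 1e6
    name: str = ""

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != self.grid.energies.shape:
            raise ValueError("weights must match grid")
        if np.any(w < 0):
            raise ValueError("negative spectral weights")
        norm = float(np.sum(w) * self.grid.bin_width)
        if norm <= 0:
            raise ValueError("empty spectrum")
        object.__setattr__(self, "weights", w / norm)

    @property
    def mean_energy(self) -> float:
        e = self.grid.energies
        return float(np.sum(self.weights * e) / np.sum(self.weights))

    def with_fluence(self, total_fluence: float) -> "SourceSpectrum":
        return SourceSpectrum(
            self.kvp, self.grid, self.weights, total_fluence, self.name
        )


def make_spectrum(
    kvp: float,
    filtration_mm_al: float = 9.0,
    grid: EnergyGrid = DEFAULT_GRID,
    total_fluence: float = 1e6,
) -> SourceSpectrum:
    """Filtered Kramers tungsten-anode spectrum at a supported tube potential.

    Parameters
    ----------
    kvp
        Tube potential; one of 80, 120, 140 kV.  Other potentials require a
        user-supplied spectrum table (`spectrum_from_table`).
    filtration_mm_al
        Aluminium-equivalent total filtration in mm.  More filtration
        strictly hardens the beam (raises the mean energy).
    """
    if int(kvp) not in SUPPORTED_KVP:
        raise ValueError(
            f"kvp {kvp} unsupported; use one of {SUPPORTED_KVP} or "
            "spectrum_from_table() for a custom spectrum"
        )
    if filtration_mm_al < 0:
        raise ValueError("filtration must be >= 0")
    e = grid.energies
    w = np.clip(kvp - e, 0.0, None) / e  # Kramers continuum
    mu_al = ALUMINUM.linear_attenuation(e)  # 1/cm
    w = w * np.exp(-mu_al * filtration_mm_al * 0.1)
    return SourceSpectrum(kvp, grid, w, total_fluence, name=f"{int(kvp)}kvp")


def monoenergetic_spectrum(
    energy: float,
    grid: EnergyGrid = DEFAULT_GRID,
    total_fluence: float = 1e6,
) -> SourceSpectrum:
    """Single-bin (delta) spectrum — the beam-hardening-free reference."""
    w = np.zeros(len(grid))
    w[grid.index_of(energy)] = 1.0
    return SourceSpectrum(energy, grid, w, total_fluence, name=f"{energy:g}kev")


def effective_monoenergy(
    spectrum: SourceSpectrum, water_path_cm: float = 8.0
) -> float:
    """Energy at which a monoenergetic beam matches the spectrum's iodine contrast.

    Solves  mu_I(E)/mu_w(E) = <mu_I>_t / <mu_w>_t  where <.>_t is the
    transmission-weighted spectral average behind ``water_path_cm`` of
    water.  Reconstructed at this reference energy, a water-precorrected
    polyenergetic image reproduces dilute-iodine HU to first order — the
    virtual-monoenergetic alignment that makes a single-energy image the
    natural beam-hardening-free comparator for that tube setting.
    Rounded to the energy grid.
    """
    from scipy.optimize import brentq

    e = spectrum.grid.energies
    mu_w = WATER.linear_attenuation(e)
    mu_i = IODINE.mass_attenuation(e)
    w = spectrum.weights * np.exp(-mu_w * water_path_cm)
    w = w / w.sum()
    target = (w @ mu_i) / (w @ mu_w)

    def mismatch(E):
        return (
            IODINE.mass_attenuation(np.atleast_1d(E))[0]
            / WATER.linear_attenuation(np.atleast_1d(E))[0]
            - target
        )

    e_eff = brentq(mismatch, 35.0, min(140.0, spectrum.kvp - 1e-6))
    return float(np.round(e_eff))


def spectrum_from_table(
    energies_kev,
    weights,
    grid: EnergyGrid = DEFAULT_GRID,
    total_fluence: float = 1e6,
    name: str = "custom",
) -> SourceSpectrum:
    """Build a spectrum from a user-supplied (energy, weight) table.

    The table is linearly interpolated onto the working grid and
    renormalized; the same CSV dialect as the embedded resources
    (two columns: energy_kev, weight) can be loaded with ``np.loadtxt``.
    """
    e_tab = np.asarray(energies_kev, dtype=float)
    w_tab = np.asarray(weights, dtype=float)
    if np.any(w_tab < 0):
        raise ValueError("negative spectral weights")
    w = np.interp(grid.energies, e_tab, w_tab, left=0.0, right=0.0)
    return SourceSpectrum(float(e_tab.max()), grid, w, total_fluence, name=name)
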