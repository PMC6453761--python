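"""Analytic digital phantoms and dynamic contrast-enhanced series.

Phantoms are lists of elliptical primitives with attached materials, in
physical coordinates (x right, y up, millimetres, origin at the image
centre).  Later primitives override earlier ones where they overlap and
must be fully contained in their "parent" (the latest earlier primitive
that encloses them), which keeps analytic line integrals exact: each
primitive contributes chord_length * (mu_self - mu_parent).

Two study phantoms are provided:

* a water cylinder with four iodine-solution inserts at 90 degree
  spacing (the static beam-hardening test object), and
* a cardiac phantom — thorax ellipse, LV cavity, myocardial annulus,
  RV cavity, descending aorta and spine/sternum bone — whose chambers
  follow an arterial input function (AIF) and whose myocardium follows
  the tissue curve of the perfusion model at a known ground-truth flow.

`simulate_dynamic_series` turns the cardiac phantom plus a
`PerfusionGroundTruth` into a reconstructed HU time series through the
full polyenergetic pipeline (projection, water pre-correction, Poisson
noise, FBP), which is the synthetic stand-in for a dynamic CT
myocardial perfusion acquisition.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import (
    Material,
    SourceSpectrum,
    WATER,
    CORTICAL_BONE,
    iodine_solution,
)

__all__ = [
    "Ellipse",
    "PhantomDefinition",
    "PerfusionGroundTruth",
    "DynamicSeries",
    "make_cylinder_phantom",
    "make_cardiac_phantom",
    "gamma_variate_aif",
    "simulate_dynamic_series",
    "CYLINDER_INSERT_CONCENTRATIONS",
]

#: Default iodine concentrations (mgI/ml) of the four cylinder inserts;
#: chosen so every insert clears the 200 HU HAM threshold while the
#: pre-correction inter-insert streak sits in the low-tens-of-HU regime
#: of a digital (rather than high-concentration physical) phantom.
CYLINDER_INSERT_CONCENTRATIONS = (7.0, 10.5, 14.0, 17.5)


@dataclass
class Ellipse:
    """Elliptical primitive: center (mm), semi-axes (mm), rotation (deg)."""

    center: tuple[float, float]
    axes: tuple[float, float]
    material: Material
    rotation_deg: float = 0.0
    label: str = ""

    def contains(self, x, y) -> np.ndarray:
        t = np.deg2rad(self.rotation_deg)
        dx = np.asarray(x) - self.center[0]
        dy = np.asarray(y) - self.center[1]
        u = dx * np.cos(t) + dy * np.sin(t)
        v = -dx * np.sin(t) + dy * np.cos(t)
        return (u / self.axes[0]) ** 2 + (v / self.axes[1]) ** 2 <= 1.0

    def boundary(self, n: int = 256) -> np.ndarray:
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        t = np.deg2rad(self.rotation_deg)
        u = self.axes[0] * np.cos(phi)
        v = self.axes[1] * np.sin(phi)
        x = self.center[0] + u * np.cos(t) - v * np.sin(t)
        y = self.center[1] + u * np.sin(t) + v * np.cos(t)
        return np.stack([x, y], axis=1)

    def chords(self, angles_rad: np.ndarray, s_mm: np.ndarray) -> np.ndarray:
        """Chord lengths (mm) for parallel rays s = x cos(th) + y sin(th).

        Returns an array of shape (n_angles, n_detectors); closed form,
        no ray marching.
        """
        th = angles_rad[:, None]
        s = s_mm[None, :]
        # ray: p(t) = s*(cos th, sin th) + t*(-sin th, cos th)
        px = s * np.cos(th) - self.center[0]
        py = s * np.sin(th) - self.center[1]
        vx = -np.sin(th) * np.ones_like(s)
        vy = np.cos(th) * np.ones_like(s)
        rot = np.deg2rad(self.rotation_deg)
        cr, sr = np.cos(rot), np.sin(rot)
        pu = px * cr + py * sr
        pv = -px * sr + py * cr
        vu = vx * cr + vy * sr
        vv = -vx * sr + vy * cr
        a, b = self.axes
        A = (vu / a) ** 2 + (vv / b) ** 2
        B = 2 * (pu * vu / a**2 + pv * vv / b**2)
        C = (pu / a) ** 2 + (pv / b) ** 2 - 1.0
        disc = B**2 - 4 * A * C
        out = np.zeros_like(disc)
        hit = disc > 0
        out[hit] = np.sqrt(disc[hit]) / A[hit]
        return out


@dataclass
class PhantomDefinition:
    """Ordered elliptical primitives on a vacuum background.

    Each primitive must be fully contained in its parent (the latest
    earlier primitive enclosing it) or lie on the background; partial
    overlap is rejected so analytic chord-based projection stays exact.
    """

    primitives: list[Ellipse]
    name: str = "phantom"

    def __post_init__(self):
        self._parents = self._resolve_parents()

    def _resolve_parents(self) -> list[int]:
        parents = []
        for i, prim in enumerate(self.primitives):
            pts = prim.boundary(64) * (1 - 1e-9)
            parent = -1
            for j in range(i - 1, -1, -1):
                outer = self.primitives[j]
                inside = outer.contains(pts[:, 0], pts[:, 1])
                if inside.all():
                    parent = j
                    break
                if inside.any() and not _same_shape(prim, outer):
                    raise ValueError(
                        f"primitive {i} ({prim.label!r}) partially overlaps "
                        f"{j} ({outer.label!r}); only full containment is allowed"
                    )
            parents.append(parent)
        return parents

    @property
    def extent_mm(self) -> float:
        """Radius of the smallest origin-centred circle containing everything."""
        r = 0.0
        for p in self.primitives:
            b = p.boundary(128)
            r = max(r, float(np.max(np.hypot(b[:, 0], b[:, 1]))))
        return r

    def delta_attenuations(self, energies: np.ndarray) -> np.ndarray:
        """(n_primitives, n_energies) array of mu_self - mu_parent in 1/cm."""
        if not self.primitives:
            return np.zeros((0, len(np.atleast_1d(energies))))
        mus = np.stack(
            [p.material.linear_attenuation(energies) for p in self.primitives]
        )
        out = np.empty_like(mus)
        for i, parent in enumerate(self._parents):
            out[i] = mus[i] - (mus[parent] if parent >= 0 else 0.0)
        return out

    def rasterize_mu(self, energy: float, geometry) -> np.ndarray:
        """Pixel map of mu(E) in 1/cm (nearest-primitive-wins, exact nesting)."""
        x, y = geometry.pixel_coords()
        mu = np.zeros(x.shape)
        for p in self.primitives:
            mask = p.contains(x, y)
            mu[mask] = p.material.linear_attenuation(np.atleast_1d(energy))[0]
        return mu

    def region_mask(self, label: str, geometry) -> np.ndarray:
        """Pixels belonging to the labelled primitive (minus nested children)."""
        idx = [i for i, p in enumerate(self.primitives) if p.label == label]
        if not idx:
            raise KeyError(f"no primitive labelled {label!r}")
        x, y = geometry.pixel_coords()
        mask = np.zeros(x.shape, dtype=bool)
        for i in idx:
            m = self.primitives[i].contains(x, y)
            # later primitives override in overlap (they are nested children)
            for j in range(i + 1, len(self.primitives)):
                m &= ~self.primitives[j].contains(x, y)
            mask |= m
        return mask

    def with_materials(self, updates: dict[str, Material]) -> "PhantomDefinition":
        prims = []
        for p in self.primitives:
            if p.label in updates:
                p = replace(p, material=updates[p.label])
            else:
                p = copy.copy(p)
            prims.append(p)
        return PhantomDefinition(prims, name=self.name)


def _same_shape(a: Ellipse, b: Ellipse) -> bool:
    return (
        np.allclose(a.center, b.center)
        and np.allclose(a.axes, b.axes)
        and np.isclose(a.rotation_deg % 180, b.rotation_deg % 180)
    )


def make_cylinder_phantom(
    diameter_mm: float = 100.0,
    insert_concentrations=CYLINDER_INSERT_CONCENTRATIONS,
    insert_radius_mm: float = 8.0,
    insert_offset_mm: float | None = None,
) -> PhantomDefinition:
    """Water cylinder with iodine-solution inserts at 90 degree spacing.

    The four-insert layout mirrors the classic beam-hardening test
    object: dark streaks form between the inserts of a polyenergetic
    reconstruction and vanish in the monoenergetic reference.
    """
    R = diameter_mm / 2.0
    if insert_offset_mm is None:
        insert_offset_mm = 0.55 * R
    prims = [Ellipse((0.0, 0.0), (R, R), WATER, label="background")]
    n = len(insert_concentrations)
    for k, c in enumerate(insert_concentrations):
        ang = 2 * np.pi * k / max(n, 1)
        cx = insert_offset_mm * np.cos(ang)
        cy = insert_offset_mm * np.sin(ang)
        if insert_offset_mm + insert_radius_mm > R:
            raise ValueError("insert extends outside the cylinder")
        if n > 1 and 2 * insert_offset_mm * np.sin(np.pi / n) < 2 * insert_radius_mm:
            raise ValueError("inserts overlap")
        prims.append(
            Ellipse(
                (cx, cy),
                (insert_radius_mm, insert_radius_mm),
                iodine_solution(c),
                label=f"insert_{k}",
            )
        )
    return PhantomDefinition(prims, name="cylinder")


def make_cardiac_phantom(scale_mm: float = 55.0) -> PhantomDefinition:
    """Cardiac phantom: thorax, LV, myocardium, RV, aorta, spine, sternum.

    These are the structures that generate myocardial beam-hardening
    streaks in contrast-enhanced cardiac CT — the iodine-filled
    ventricles and aorta plus nearby bone.  ``scale_mm`` is the thorax
    semi-major axis; everything scales with it.
    """
    s = scale_mm / 55.0
    water = WATER
    prims = [
        Ellipse((0.0, 0.0), (55 * s, 42 * s), water, label="body"),
        # outer myocardial boundary first, LV cavity nested inside it
        Ellipse((-8 * s, 4 * s), (24 * s, 24 * s), water, label="myocardium"),
        Ellipse((-8 * s, 4 * s), (14 * s, 14 * s), water, label="lv"),
        Ellipse((-42 * s, 6 * s), (8 * s, 8 * s), water, label="rv"),
        Ellipse((14 * s, -24 * s), (7 * s, 7 * s), water, label="aorta"),
        Ellipse((0.0, -34 * s), (8 * s, 6 * s), CORTICAL_BONE, label="spine"),
        Ellipse((-6 * s, 38 * s), (10 * s, 3 * s), CORTICAL_BONE, label="sternum"),
    ]
    return PhantomDefinition(prims, name="cardiac")


@dataclass(frozen=True)
class PerfusionGroundTruth:
    """Ground truth for a simulated perfusion acquisition.

    mbf is the homogeneous myocardial blood flow in ml/min/100 g unless a
    ``sector_flow_scale`` map introduces a regional deficit; the AIF is a
    gamma variate in iodine concentration units.
    """

    mbf: float = 100.0
    frame_times_s: np.ndarray = field(
        default_factory=lambda: np.arange(40, dtype=float)
    )
    aif_onset_s: float = 4.0
    aif_peak_time_s: float = 12.0
    aif_peak_mg_ml: float = 10.0  # ~400 HU peak LV enhancement at 120 kVp
    aif_shape: float = 3.0
    recirculation_fraction: float = 0.15
    itt_s: float = 2.0
    extraction: float = 0.6
    decay_k_per_s: float = 0.1
    deficit_sector_deg: tuple[float, float] | None = None
    deficit_scale: float = 1.0

    def aif(self, t) -> np.ndarray:
        return gamma_variate_aif(
            np.asarray(t, dtype=float),
            onset_s=self.aif_onset_s,
            peak_time_s=self.aif_peak_time_s,
            peak_value=self.aif_peak_mg_ml,
            shape=self.aif_shape,
            recirculation_fraction=self.recirculation_fraction,
        )

    def tissue_curve(self, t, mbf: float | None = None, dt: float = 0.1) -> np.ndarray:
        """Myocardial iodine concentration via the kinetic model (mgI/ml)."""
        from .perfusion import IRFParams, model_tissue_curve

        t = np.asarray(t, dtype=float)
        fine = np.arange(0.0, t.max() + dt, dt)
        params = IRFParams(
            delay_s=0.0,
            flow=self.mbf if mbf is None else mbf,
            itt_s=self.itt_s,
            extraction=self.extraction,
            k_per_s=self.decay_k_per_s,
        )
        ct = model_tissue_curve(fine, self.aif(fine), params, dt=dt, times_out=t)
        return ct


def gamma_variate_aif(
    t,
    onset_s: float = 4.0,
    peak_time_s: float = 12.0,
    peak_value: float = 15.0,
    shape: float = 3.0,
    recirculation_fraction: float = 0.0,
    recirculation_delay_s: float = 14.0,
):
    """Gamma-variate arterial input function, zero before onset.

    Parameterised by its peak: c(t) = peak * tau^shape * exp(shape*(1-tau))
    with tau = (t-onset)/(peak_time-onset), so the stated peak value is
    attained exactly at ``peak_time_s``.  An optional recirculation bump
    adds a delayed, scaled copy.
    """
    t = np.asarray(t, dtype=float)
    if peak_time_s <= onset_s:
        raise ValueError("peak time must follow onset")
    if shape <= 0 or peak_value < 0:
        raise ValueError("nonphysical AIF parameters")
    tau = (t - onset_s) / (peak_time_s - onset_s)
    first = np.where(
        tau > 0, peak_value * np.power(np.clip(tau, 0, None), shape)
        * np.exp(shape * (1.0 - tau)), 0.0,
    )
    out = first
    if recirculation_fraction:
        tau2 = (t - onset_s - recirculation_delay_s) / (peak_time_s - onset_s)
        out = out + recirculation_fraction * np.where(
            tau2 > 0,
            peak_value * np.power(np.clip(tau2, 0, None), shape)
            * np.exp(shape * (1.0 - tau2)),
            0.0,
        )
    return out


@dataclass
class DynamicSeries:
    """Ordered stack of HU frames with acquisition times."""

    frames: np.ndarray  # (n_frames, n, n) HU
    times_s: np.ndarray
    geometry: "object" = None
    protocol: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        if len(self.frames) != len(self.times_s):
            raise ValueError("frames/times length mismatch")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


def _angular_scale(gt: PerfusionGroundTruth, phantom: PhantomDefinition, geometry):
    """Per-pixel flow scale implementing an optional sector deficit."""
    if gt.deficit_sector_deg is None:
        return None
    lv = next(p for p in phantom.primitives if p.label == "lv")
    x, y = geometry.pixel_coords()
    ang = np.rad2deg(np.arctan2(y - lv.center[1], x - lv.center[0])) % 360
    lo, hi = gt.deficit_sector_deg
    in_sector = (ang >= lo) & (ang < hi) if lo <= hi else (ang >= lo) | (ang < hi)
    return np.where(in_sector, gt.deficit_scale, 1.0)


def simulate_dynamic_series(
    phantom: PhantomDefinition,
    truth: PerfusionGroundTruth,
    spectrum: SourceSpectrum,
    geometry,
    noise_seed: int | None = 0,
    target_snr: float | None = 9.8,
    reference_energy: float = 70.0,
) -> DynamicSeries:
    """Simulate a dynamic contrast-enhanced cardiac series in HU.

    Per frame the LV, RV and aorta take the AIF concentration (the RV
    leads by 3 s, as contrast arrives there first), the myocardium takes
    the kinetic-model tissue curve at the ground-truth flow, and the
    frame goes through polyenergetic projection, water pre-correction,
    optional Poisson noise and FBP.  When ``target_snr`` is set, the
    photon fluence is calibrated so the peak-frame myocardial SNR
    (mean enhancement / noise SD) is approximately that value.

    Chord geometry is computed once for the series; only the iodine
    concentrations change between frames.
    """
    from . import simulator

    t = truth.frame_times_s
    aif = truth.aif(t)
    aif_rv = truth.aif(t + 3.0)
    tissue = truth.tissue_curve(t)
    deficit = _angular_scale(truth, phantom, geometry)
    tissue_low = (
        truth.tissue_curve(t, mbf=truth.mbf * truth.deficit_scale)
        if deficit is not None
        else None
    )

    labels = [p.label for p in phantom.primitives]
    chords = simulator.chord_table(phantom, geometry)  # cached geometry

    # fluence calibration on the peak frame
    spec = spectrum
    if noise_seed is not None and target_snr is not None:
        k = int(np.argmax(aif))
        clean = _frame(
            phantom, labels, chords, aif[k], aif_rv[k], tissue[k], spec,
            geometry, None, None, reference_energy,
        )
        trial = spec.with_fluence(1e5)
        noisy = _frame(
            phantom, labels, chords, aif[k], aif_rv[k], tissue[k], trial,
            geometry, 12345, None, reference_energy,
        )
        myo = phantom.region_mask("myocardium", geometry)
        signal = float(np.mean(clean[myo]))
        sd = float(np.std((noisy - clean)[myo]))
        if signal <= 0 or sd <= 0:
            raise RuntimeError("fluence calibration failed: no enhancement")
        # noise SD scales ~ 1/sqrt(I0)
        i0 = 1e5 * (sd * target_snr / signal) ** 2
        spec = spec.with_fluence(i0)

    frames = []
    for k in range(len(t)):
        seed_k = None if noise_seed is None else int(noise_seed) + k
        frames.append(
            _frame(
                phantom, labels, chords, aif[k], aif_rv[k], tissue[k], spec,
                geometry, seed_k,
                None if tissue_low is None else (deficit, tissue_low[k]),
                reference_energy,
            )
        )
    return DynamicSeries(
        np.stack(frames), t, geometry=geometry,
        protocol=spec.name, seed=noise_seed,
    )


def _frame(
    phantom, labels, chords, c_aif, c_rv, c_tissue, spectrum, geometry,
    seed, deficit_info, reference_energy,
):
    from . import simulator

    updates = {
        "lv": iodine_solution(float(c_aif)),
        "aorta": iodine_solution(float(c_aif)),
        "rv": iodine_solution(float(c_rv)),
        "myocardium": iodine_solution(float(c_tissue)),
    }
    ph = phantom.with_materials({k: v for k, v in updates.items() if k in labels})
    sino = simulator.project_poly(ph, spectrum, geometry, chords=chords)
    sino = simulator.water_precorrect(sino, spectrum, reference_energy)
    if seed is not None:
        sino = simulator.add_poisson_noise(sino, spectrum, seed)
    img = simulator.reconstruct_fbp(sino, geometry, reference_energy)
    hu = img.values
    if deficit_info is not None:
        deficit, c_low = deficit_info
        # paint the reduced-flow sector in image space (post-recon delta)
        myo = phantom.region_mask("myocardium", geometry)
        delta = _hu_of_concentration(c_low, reference_energy) - _hu_of_concentration(
            float(c_tissue), reference_energy
        )
        hu = hu + np.where(myo & (deficit < 1.0), delta, 0.0)
    return hu


def _hu_of_concentration(c_mg_ml: float, reference_energy: float) -> float:
    mu_w = WATER.linear_attenuation(np.atleast_1d(reference_energy))[0]
    mu = iodine_solution(c_mg_ml).linear_attenuation(
        np.atleast_1d(reference_energy)
    )[0]
    return 1000.0 * (mu - mu_w) / mu_w
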