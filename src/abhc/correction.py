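"""Polynomial residual beam-hardening correction in the image domain.

The residual correction works on the projection of the highly
attenuating material (HAM: bone and concentrated iodine) alone,

    dP = a * lambda + b * lambda**2,      lambda = R{HAM},

and by linearity of filtered back projection the error image is

    I_E = a * FBP(lambda) + b * FBP(lambda**2) = a*I_ham + b*I_ham2,
    I_C = I - I_E.

The two base images are computed once per input image; evaluating a
candidate (a, b) is then a cheap linear combination, which is what makes
iterative optimization of the parameters affordable.  The linear term
can only rescale HAM intensity and cupping; streaks between HAMs are
carried by the quadratic term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulator import (
    CTImage,
    Geometry,
    Sinogram,
    forward_project_image,
    hu_to_mu,
    mu_to_hu,
    reconstruct_fbp,
)

__all__ = [
    "CorrectionParams",
    "HAMDecomposition",
    "segment_ham",
    "compute_base_images",
    "apply_correction",
]

DEFAULT_HAM_THRESHOLD_HU = 200.0


@dataclass(frozen=True)
class CorrectionParams:
    """Weights of the linear and quadratic HAM-projection terms."""

    a: float = 0.0
    b: float = 0.0

    def as_tuple(self) -> tuple[float, float]:
        return (float(self.a), float(self.b))


@dataclass
class HAMDecomposition:
    """Segmented HAM plus the two fixed base images.

    base_1 = FBP(lambda) reproduces the HAM image; base_2 = FBP(lambda**2)
    lives along the lines joining HAM structures — where the streaks
    are.  Both are expressed on the HU scale of the input so that the
    parameters (a, b) are dimensionless weights of HU-scale images; any
    fixed unit choice for lambda is absorbed into (a, b), so parameter
    magnitudes are comparable only within one convention.
    """

    ham_image: np.ndarray  # HU, zero outside mask
    ham_mask: np.ndarray
    lambda_sino: np.ndarray
    base_1: np.ndarray  # HU scale
    base_2: np.ndarray  # HU scale
    geometry: Geometry
    threshold_hu: float
    reference_energy_kev: float = 70.0

    @property
    def empty(self) -> bool:
        return not self.ham_mask.any()


def segment_ham(
    image: CTImage, threshold_hu: float = DEFAULT_HAM_THRESHOLD_HU
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold out bones and high-iodine regions.

    Returns (ham_image, mask): pixels at or above the threshold keep
    their HU value (HU above water, water being 0), all others are zero.
    An empty mask means there is nothing to correct; the caller degrades
    to the identity correction.
    """
    hu = image.values
    mask = hu >= threshold_hu
    if not mask.any():
        warnings.warn(
            "empty HAM mask: no pixel reaches the threshold; "
            "correction degenerates to identity",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.where(mask, hu, 0.0), mask


def compute_base_images(
    image: CTImage,
    threshold_hu: float = DEFAULT_HAM_THRESHOLD_HU,
) -> HAMDecomposition:
    """Segment HAM, forward-project it, and FBP the lambda and lambda^2 sinograms.

    lambda is formed in attenuation units (HU-excess converted through
    mu_water at the reference energy, integrated in cm) and both base
    images are converted back to the HU scale, so ``apply_correction``
    is a pure HU-space linear combination.
    """
    geometry = image.geometry
    ref = image.reference_energy_kev
    ham_hu, mask = segment_ham(image, threshold_hu)
    if not mask.any():
        zero = np.zeros_like(ham_hu)
        return HAMDecomposition(
            ham_hu, mask, np.zeros((geometry.n_angles, geometry.n_pixels)),
            zero, zero.copy(), geometry, threshold_hu, ref,
        )
    # HU excess over water -> linear attenuation excess, 1/cm
    mu_excess = hu_to_mu(ham_hu, ref) - hu_to_mu(0.0, ref)
    lam = forward_project_image(mu_excess, geometry)
    mu_w = hu_to_mu(0.0, ref)

    def _fbp_to_hu_scale(sino_vals: np.ndarray) -> np.ndarray:
        img = reconstruct_fbp(Sinogram(sino_vals, geometry), geometry, ref)
        return img.values + 1000.0  # undo the air offset: FBP(0) -> 0

    base_1 = _fbp_to_hu_scale(lam)
    base_2 = _fbp_to_hu_scale(lam**2 / np.maximum(lam.max(), 1e-12))
    # base_2 rescaled by max(lambda) so b has a magnitude comparable to a
    return HAMDecomposition(
        ham_hu, mask, lam, base_1, base_2, geometry, threshold_hu, ref
    )


def apply_correction(
    image: CTImage, decomp: HAMDecomposition, params: CorrectionParams
) -> CTImage:
    """I_C = I - a*base_1 - b*base_2 (exact linearity in a and b)."""
    corrected = (
        image.values - params.a * decomp.base_1 - params.b * decomp.base_2
    )
    return CTImage(
        corrected, image.geometry, image.reference_energy_kev,
        image.slice_thickness_mm,
    )
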