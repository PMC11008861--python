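"""Spectral axis conventions and conversions.

The spectrometer records intensity against detector wavelength (nm); Raman
features live on the Raman-shift axis (cm^-1), defined relative to the
excitation line.  Because the shift axis depends on the excitation
wavelength, a 1 nm step of the laser (784 nm vs 785 nm) translates every
Raman line by a nearly constant ~16.3 cm^-1 while leaving the
wavelength-anchored fluorescence in place — the physical lever of
shifted-excitation Raman difference spectroscopy (SERDS).
"""

from __future__ import annotations

import numpy as np

#: Default acquisition geometry: dual excitation at 784/785 nm, detector
#: spanning 800-940 nm (Raman shifts of roughly 200-2000 cm^-1).
EXCITATION_PAIR_NM: tuple[float, float] = (784.0, 785.0)
DETECTOR_MIN_NM: float = 800.0
DETECTOR_MAX_NM: float = 940.0
DETECTOR_PIXELS: int = 1024

#: Fingerprint window used for classification, and the uniform grid the
#: purifier operates on (1024 points keeps the length divisible by 2**depth).
FINGERPRINT_LOW_CM1: float = 550.0
FINGERPRINT_HIGH_CM1: float = 1800.0
PURIFIER_POINTS: int = 1024


def wavelength_to_shift(wavelength_nm, excitation_nm):
    """Convert detector wavelength (nm) to Raman shift (cm^-1).

    shift = 1e7 * (1/excitation - 1/wavelength); positive for Stokes
    scattering (wavelength longer than the excitation line).
    """
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0) or excitation_nm <= 0:
        raise ValueError("wavelength and excitation must be positive")
    return 1e7 * (1.0 / excitation_nm - 1.0 / wavelength_nm)


def shift_to_wavelength(shift_cm1, excitation_nm):
    """Inverse of :func:`wavelength_to_shift`."""
    shift_cm1 = np.asarray(shift_cm1, dtype=float)
    if excitation_nm <= 0:
        raise ValueError("excitation must be positive")
    inv = 1.0 / excitation_nm - shift_cm1 * 1e-7
    if np.any(inv <= 0):
        raise ValueError("shift maps beyond infinite wavelength for this excitation")
    return 1.0 / inv


def excitation_step_shift(excitation_a_nm: float = EXCITATION_PAIR_NM[0],
                          excitation_b_nm: float = EXCITATION_PAIR_NM[1]) -> float:
    """Raman-shift displacement (cm^-1) induced by the excitation step.

    For 784 -> 785 nm this is 1e7*(1/784 - 1/785) ~ 16.25 cm^-1, constant in
    wavelength to first order.
    """
    if excitation_a_nm <= 0 or excitation_b_nm <= 0:
        raise ValueError("excitations must be positive")
    return 1e7 * (1.0 / excitation_a_nm - 1.0 / excitation_b_nm)


def detector_grid(n_pixels: int = DETECTOR_PIXELS,
                  low_nm: float = DETECTOR_MIN_NM,
                  high_nm: float = DETECTOR_MAX_NM) -> np.ndarray:
    """Uniform detector wavelength grid (nm)."""
    if n_pixels < 2 or low_nm >= high_nm:
        raise ValueError("need >= 2 pixels and low < high")
    return np.linspace(low_nm, high_nm, n_pixels)


def purifier_shift_axis(n_points: int = PURIFIER_POINTS,
                        low_cm1: float = FINGERPRINT_LOW_CM1,
                        high_cm1: float = FINGERPRINT_HIGH_CM1) -> np.ndarray:
    """Uniform Raman-shift grid (cm^-1) shared by purifier and classifier."""
    if n_points < 2 or low_cm1 >= high_cm1:
        raise ValueError("need >= 2 points and low < high")
    return np.linspace(low_cm1, high_cm1, n_points)
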