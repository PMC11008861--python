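"""Deterministic SERDS arithmetic.

Implements the fixed processing order of the acquisition protocol: average
the 50 repeats of each excitation block, z-score each mean spectrum, and
subtract the two normalized means to obtain the difference spectrum in which
the excitation-insensitive fluorescence background cancels.  A classic
(non-neural) shift-and-integrate reconstruction is provided as the
comparison baseline for the neural purifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _linear_detrend

from . import axes


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum has no variance (z-score undefined)."""


@dataclass
class RawBlock:
    """One locus' repeated acquisition at a single excitation wavelength."""

    wavelength_nm: np.ndarray          # (pixels,), strictly increasing
    intensities: np.ndarray            # (repeats, pixels), counts
    excitation_nm: float
    locus_id: str = ""
    label: str | None = None
    clip_fraction: float = 0.0         # Raman intensity mass mapped off-grid

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.intensities.shape[1] != self.wavelength_nm.shape[0]:
            raise ValueError("intensity matrix width must equal grid length")
        if self.intensities.shape[0] < 1:
            raise ValueError("block needs at least one repeat")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def n_repeats(self) -> int:
        return self.intensities.shape[0]


@dataclass
class MeanSpectrum:
    wavelength_nm: np.ndarray
    values: np.ndarray
    excitation_nm: float
    n_repeats: int

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelength_nm.shape:
            raise ValueError("values must match the wavelength grid")


@dataclass
class DifferenceSpectrum:
    """z-score difference of the two mean spectra on the shared pixel grid."""

    wavelength_nm: np.ndarray
    values: np.ndarray
    excitations_nm: tuple[float, float]
    locus_id: str = ""
    label: str | None = None

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.wavelength_nm.shape:
            raise ValueError("values must match the wavelength grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("difference values must be finite")


@dataclass
class PurifiedSpectrum:
    """Background-free Raman intensity on a Raman-shift axis."""

    shift_cm1: np.ndarray
    values: np.ndarray
    locus_id: str = ""
    label: str | None = None
    purifier_id: str = ""

    def __post_init__(self) -> None:
        self.shift_cm1 = np.asarray(self.shift_cm1, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.shift_cm1.shape:
            raise ValueError("values must match the shift axis")
        if np.any(np.diff(self.shift_cm1) <= 0):
            raise ValueError("shift axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


def mean_block(block: RawBlock) -> MeanSpectrum:
    """Pixelwise arithmetic mean over the repeats of a block."""
    return MeanSpectrum(
        wavelength_nm=block.wavelength_nm,
        values=block.intensities.mean(axis=0),
        excitation_nm=block.excitation_nm,
        n_repeats=block.n_repeats,
    )


def zscore(values: np.ndarray) -> np.ndarray:
    """Population z-score (divisor N): output has mean 0 and sd 1."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("z-score needs at least two pixels")
    sd = values.std()
    mean = values.mean()
    # guard against exactly-constant input and float-roundoff pseudo-variance
    if sd <= 1e-13 * max(1.0, abs(mean)):
        raise DegenerateSpectrumError("constant spectrum has no z-score")
    return (values - mean) / sd


def serds_difference(mean_a: MeanSpectrum, mean_b: MeanSpectrum,
                     locus_id: str = "", label: str | None = None) -> DifferenceSpectrum:
    """zscore(mean_a) - zscore(mean_b) on the shared pixel grid.

    ``mean_a`` is conventionally the lower-excitation (784 nm) spectrum.
    Antisymmetric under swapping the inputs.
    """
    if not np.array_equal(mean_a.wavelength_nm, mean_b.wavelength_nm):
        raise ValueError("mean spectra must share one pixel grid")
    if mean_a.excitation_nm == mean_b.excitation_nm:
        raise ValueError("difference requires two distinct excitations")
    return DifferenceSpectrum(
        wavelength_nm=mean_a.wavelength_nm,
        values=zscore(mean_a.values) - zscore(mean_b.values),
        excitations_nm=(mean_a.excitation_nm, mean_b.excitation_nm),
        locus_id=locus_id,
        label=label,
    )


def resample_difference(diff: DifferenceSpectrum,
                        shift_axis: np.ndarray | None = None,
                        axis_offset_cm1: float = 0.0) -> np.ndarray:
    """Linear resampling of a difference spectrum onto a uniform shift grid.

    The shift axis is referenced to the higher (second) excitation
    wavelength, 785 nm by convention.  Points mapping outside the detector
    span are filled with zero.
    """
    if shift_axis is None:
        shift_axis = axes.purifier_shift_axis()
    reference = max(diff.excitations_nm)
    pixel_shift = axes.wavelength_to_shift(diff.wavelength_nm, reference)
    return np.interp(np.asarray(shift_axis, float) + axis_offset_cm1,
                     pixel_shift, diff.values, left=0.0, right=0.0)


def classic_reconstruct(diff: DifferenceSpectrum,
                        shift_axis: np.ndarray | None = None) -> PurifiedSpectrum:
    """Shift-and-integrate SERDS recovery (the non-neural baseline).

    The difference spectrum of a single Raman line is a +/- doublet
    separated by the excitation step delta ~ 16.25 cm^-1; cumulative
    summation along the shift axis turns it back into a single band whose
    apex sits midway between the two lobes.  Sampling the difference at
    (axis - delta/2) before integrating centres the recovered band on the
    true line position; a least-squares line is subtracted afterwards to
    remove the integration drift.  Every step is linear.
    """
    if shift_axis is None:
        shift_axis = axes.purifier_shift_axis()
    shift_axis = np.asarray(shift_axis, dtype=float)
    step = np.diff(shift_axis)
    if shift_axis.size < 3 or np.any(step <= 0):
        raise ValueError("shift axis must be strictly increasing with >= 3 points")
    lo, hi = sorted(diff.excitations_nm)
    delta = axes.excitation_step_shift(lo, hi)
    sampled = resample_difference(diff, shift_axis, axis_offset_cm1=-delta / 2.0)
    integrated = np.cumsum(sampled) * float(np.mean(step))
    values = _linear_detrend(integrated, type="linear")
    return PurifiedSpectrum(shift_cm1=shift_axis, values=values,
                            locus_id=diff.locus_id, label=diff.label,
                            purifier_id="classic")
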