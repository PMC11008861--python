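"""Synthetic dual-excitation Raman cohorts with known ground truth.

No raw spectra are published for the surgical cohort this pipeline targets,
so this module generates labelled stand-ins with the statistical structure
the analysis relies on: six tissue classes whose Raman fingerprints are
sums of Lorentzian bands at literature positions, an autofluorescence
background 20x stronger than the Raman signal that is identical at both
excitation wavelengths (Kasha insensitivity taken as exact), and Poisson
shot noise per pixel per repeat.  The default cohort reproduces the study
composition: 82 measurement loci (9 cutaneous neurofibroma, 12 skin,
6 nerve, 13 fat, 15 bone, 27 mucosa), 50 repeats at each of 784 and 785 nm,
hence 8,200 raw spectra.

Class fingerprints are designed so that bone carries the 960 cm^-1
phosphate marker absent elsewhere, fat and nerve are lipid-dominated
(1073, 1305, 1440-1470 cm^-1), neurofibroma is protein/nucleic-acid rich
(1004, 1095, 1338, 1378, amide I/III), and skin and mucosa share the
protein pattern with different weightings, deliberately the hardest pair to
separate from the tumour class.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import axes
from .core import RawBlock

CLASS_NAMES: tuple[str, ...] = (
    "neurofibroma", "skin", "nerve", "fat", "bone", "mucosa")

#: Loci per class, as reported for the 82-locus cohort (specimen counts in
#: parentheses in the source table: 9, 4, 2, 5, 5, 9).
DEFAULT_LOCUS_COUNTS: dict[str, int] = {
    "neurofibroma": 9, "skin": 12, "nerve": 6, "fat": 13, "bone": 15, "mucosa": 27}
DEFAULT_SPECIMEN_COUNTS: dict[str, int] = {
    "neurofibroma": 9, "skin": 4, "nerve": 2, "fat": 5, "bone": 5, "mucosa": 9}


@dataclass(frozen=True)
class RamanPeak:
    center_cm1: float
    fwhm_cm1: float
    mean_amplitude: float      # expected apex height, counts
    inter_locus_cv: float = 0.2

    def __post_init__(self) -> None:
        if not (200.0 <= self.center_cm1 <= 2000.0):
            raise ValueError(f"peak center {self.center_cm1} outside [200, 2000] cm^-1")
        if self.fwhm_cm1 <= 0:
            raise ValueError("fwhm must be positive")
        if self.mean_amplitude < 0 or self.inter_locus_cv < 0:
            raise ValueError("amplitude and cv must be nonnegative")


@dataclass(frozen=True)
class BackgroundModel:
    """Smooth autofluorescence profile: two wide Gaussians in wavelength."""

    centers_nm: tuple[float, float] = (832.0, 885.0)
    sigmas_nm: tuple[float, float] = (24.0, 42.0)
    weights: tuple[float, float] = (1.0, 0.65)
    amplitude_ratio: float = 20.0      # peak background / strongest Raman peak
    ratio_cv: float = 0.3              # per-locus lognormal spread of the ratio

    def profile(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """Unit-maximum fluorescence shape on the detector grid."""
        wavelength_nm = np.asarray(wavelength_nm, dtype=float)
        out = np.zeros_like(wavelength_nm)
        for c, s, w in zip(self.centers_nm, self.sigmas_nm, self.weights):
            out += w * np.exp(-0.5 * ((wavelength_nm - c) / s) ** 2)
        peak = out.max()
        return out / peak if peak > 0 else out


@dataclass(frozen=True)
class ClassTemplate:
    """Generative recipe for one tissue class."""

    class_name: str
    peaks: tuple[RamanPeak, ...]
    background: BackgroundModel = field(default_factory=BackgroundModel)
    noise_scale: float = 50.0          # constant dark/readout offset, counts

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")

    @property
    def max_mean_amplitude(self) -> float:
        return max((p.mean_amplitude for p in self.peaks), default=0.0)


@dataclass(frozen=True)
class CohortConfig:
    locus_counts: tuple[tuple[str, int], ...] = tuple(DEFAULT_LOCUS_COUNTS.items())
    repeats: int = 50
    excitations_nm: tuple[float, float] = axes.EXCITATION_PAIR_NM
    detector_pixels: int = axes.DETECTOR_PIXELS
    detector_min_nm: float = axes.DETECTOR_MIN_NM
    detector_max_nm: float = axes.DETECTOR_MAX_NM
    seed: int = 0
    #: sinusoidal etaloning ripple, fixed in pixel space (relative amplitude)
    etalon_amplitude: float = 0.0
    etalon_period_px: float = 48.0
    #: imperfect Kasha insensitivity: the 784 nm background is evaluated at
    #: wavelength + this offset, leaving a residual in the difference
    background_drift_nm: float = 0.0

    def __post_init__(self) -> None:
        counts = dict(self.locus_counts)
        if set(counts) - set(CLASS_NAMES):
            raise ValueError(f"unknown classes: {sorted(set(counts) - set(CLASS_NAMES))}")
        if any(n <= 0 for n in counts.values()):
            raise ValueError("all locus counts must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.excitations_nm[0] == self.excitations_nm[1]:
            raise ValueError("the two excitation wavelengths must differ")
        if self.detector_min_nm >= self.detector_max_nm or self.detector_pixels < 2:
            raise ValueError("detector grid must be strictly increasing")

    @property
    def counts(self) -> dict[str, int]:
        return dict(self.locus_counts)

    @property
    def n_loci(self) -> int:
        return sum(dict(self.locus_counts).values())

    def detector_grid(self) -> np.ndarray:
        return axes.detector_grid(self.detector_pixels,
                                  self.detector_min_nm, self.detector_max_nm)


@dataclass
class GroundTruthPair:
    """One locus: clean Raman truth plus the two rendered raw blocks."""

    shift_cm1: np.ndarray
    clean: np.ndarray
    block_a: RawBlock              # lower excitation (784 nm)
    block_b: RawBlock              # higher excitation (785 nm)
    locus_id: str
    label: str
    specimen_id: str = ""

    def __post_init__(self) -> None:
        if np.any(self.clean < 0):
            raise ValueError("clean spectrum must be nonnegative")
        if not np.array_equal(self.block_a.wavelength_nm, self.block_b.wavelength_nm):
            raise ValueError("blocks must share the detector grid")


def _peaks(*rows: tuple[float, float, float]) -> tuple[RamanPeak, ...]:
    return tuple(RamanPeak(c, w, a) for c, w, a in rows)


# Apex heights in counts; strongest band per class ~ 1000 counts so that the
# default 20x fluorescence ratio puts backgrounds near 2e4 counts.
_DEFAULT_PEAKS: dict[str, tuple[RamanPeak, ...]] = {
    # protein / nucleic-acid rich connective tumour tissue
    "neurofibroma": _peaks(
        (937, 18, 420), (1004, 12, 1000), (1038, 12, 380), (1095, 16, 350),
        (1126, 14, 230), (1245, 45, 500), (1290, 45, 420), (1338, 18, 520),
        (1378, 14, 300), (1450, 24, 600), (1620, 40, 380), (1655, 35, 900)),
    # keratinised epithelium: shared protein pattern, stronger C-H, weak DNA
    "skin": _peaks(
        (937, 18, 540), (1004, 12, 600), (1038, 12, 250), (1095, 16, 120),
        (1245, 45, 380), (1290, 45, 300), (1338, 18, 300), (1378, 14, 150),
        (1450, 24, 880), (1655, 35, 760)),
    # myelinated nerve: lipid CH2 dominated
    "nerve": _peaks(
        (1004, 12, 250), (1073, 16, 520), (1296, 22, 480), (1338, 18, 200),
        (1440, 26, 1000), (1465, 22, 520), (1655, 35, 640)),
    # adipose: triglyceride bands incl. ester carbonyl
    "fat": _peaks(
        (1073, 16, 650), (1265, 20, 420), (1305, 18, 600), (1440, 26, 1200),
        (1465, 22, 620), (1655, 30, 480), (1745, 20, 320)),
    # mineralised: phosphate nu1 at 960 cm^-1, unique to bone
    "bone": _peaks(
        (937, 18, 250), (960, 14, 1200), (1004, 12, 300), (1070, 16, 400),
        (1245, 45, 280), (1450, 24, 380), (1655, 35, 420)),
    # non-keratinised epithelium: protein pattern with carotenoid traces
    "mucosa": _peaks(
        (937, 18, 400), (1004, 12, 720), (1038, 12, 280), (1095, 16, 180),
        (1126, 14, 200), (1160, 14, 250), (1245, 45, 420), (1290, 45, 350),
        (1338, 18, 380), (1378, 14, 200), (1450, 24, 700), (1532, 18, 220),
        (1655, 35, 820)),
}


def build_class_library(overrides: dict[str, dict] | None = None
                        ) -> dict[str, ClassTemplate]:
    """Default six-class template library, optionally with per-class overrides.

    ``overrides`` maps class name -> keyword replacements for the template
    (e.g. ``{"bone": {"peaks": ()}}``).  Unknown class names raise.
    """
    overrides = overrides or {}
    unknown = set(overrides) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown class name(s) in overrides: {sorted(unknown)}")
    library: dict[str, ClassTemplate] = {}
    for name in CLASS_NAMES:
        template = ClassTemplate(class_name=name, peaks=_DEFAULT_PEAKS[name])
        if name in overrides:
            template = replace(template, **overrides[name])
        library[name] = template
    return library


def blend_library(library: dict[str, ClassTemplate], contrast: float
                  ) -> dict[str, ClassTemplate]:
    """Interpolate class amplitudes toward the class-averaged fingerprint.

    ``contrast=1`` returns the library unchanged; ``contrast=0`` gives every
    class the same pooled peak set, removing all between-class signal.  Used
    to probe how classification accuracy scales with class separation.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError("contrast must lie in [0, 1]")
    pooled: dict[tuple[float, float], list[float]] = {}
    for template in library.values():
        for p in template.peaks:
            pooled.setdefault((p.center_cm1, p.fwhm_cm1), []).append(p.mean_amplitude)
    n_classes = len(library)
    mean_amp = {key: sum(amps) / n_classes for key, amps in pooled.items()}
    blended = {}
    for name, template in library.items():
        own = {(p.center_cm1, p.fwhm_cm1): p for p in template.peaks}
        peaks = []
        for (c, w), m in sorted(mean_amp.items()):
            a_own = own[(c, w)].mean_amplitude if (c, w) in own else 0.0
            cv = own[(c, w)].inter_locus_cv if (c, w) in own else 0.2
            amp = contrast * a_own + (1.0 - contrast) * m
            if amp > 0:
                peaks.append(RamanPeak(c, w, amp, cv))
        blended[name] = replace(template, peaks=tuple(peaks))
    return blended


def _lognormal_factor(cv: float, rng: np.random.Generator, size=None):
    """Multiplicative lognormal noise with mean 1 and the given cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def truth_shift_axis() -> np.ndarray:
    """Dense shift grid covering the detector span at both excitations."""
    return np.arange(150.0, 2150.0 + 0.5, 0.5)


def sample_clean_spectrum(template: ClassTemplate, shift_axis: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw one locus' clean Raman spectrum: a sum of Lorentzian lines.

    Each line's apex amplitude is lognormal with the template mean and
    inter-locus coefficient of variation; the line shape is a Lorentzian
    with value ``amplitude`` at the centre and half that at +/- fwhm/2.
    """
    shift_axis = np.asarray(shift_axis, dtype=float)
    if np.any(np.diff(shift_axis) <= 0):
        raise ValueError("shift axis must be strictly increasing")
    out = np.zeros_like(shift_axis)
    for peak in template.peaks:
        amp = peak.mean_amplitude * _lognormal_factor(peak.inter_locus_cv, rng)
        gamma = peak.fwhm_cm1 / 2.0
        out += amp * gamma ** 2 / ((shift_axis - peak.center_cm1) ** 2 + gamma ** 2)
    return out


def expected_intensity(shift_axis: np.ndarray, clean: np.ndarray,
                       excitation_nm: float, template: ClassTemplate,
                       config: CohortConfig,
                       background: np.ndarray | None = None,
                       include_background: bool = True
                       ) -> tuple[np.ndarray, float]:
    """Noise-free expected counts on the detector grid, plus clip fraction.

    Raman features are placed at lambda = 1/(1/lambda_ex - shift*1e-7) so
    they move with the excitation; the fluorescence profile is a function of
    detector wavelength only and therefore identical for both excitations of
    a locus when the same ``background`` array is passed.
    """
    if excitation_nm not in config.excitations_nm:
        raise ValueError(f"excitation {excitation_nm} nm not in config {config.excitations_nm}")
    grid = config.detector_grid()
    pixel_shift = axes.wavelength_to_shift(grid, excitation_nm)
    shift_axis = np.asarray(shift_axis, dtype=float)
    clean = np.asarray(clean, dtype=float)
    raman = np.interp(pixel_shift, shift_axis, clean, left=0.0, right=0.0)

    # report how much Raman intensity mass falls outside the detector span
    visible = (shift_axis >= pixel_shift[0]) & (shift_axis <= pixel_shift[-1])
    total = float(np.trapezoid(clean, shift_axis))
    clip_fraction = 0.0
    if total > 0:
        inside = float(np.trapezoid(np.where(visible, clean, 0.0), shift_axis))
        clip_fraction = max(0.0, 1.0 - inside / total)

    expected = raman + template.noise_scale
    if include_background:
        if background is None:
            background = (template.background.amplitude_ratio
                          * template.max_mean_amplitude
                          * template.background.profile(grid))
        expected = expected + np.asarray(background, dtype=float)
    if config.etalon_amplitude != 0.0:
        ripple = 1.0 + config.etalon_amplitude * np.sin(
            2.0 * np.pi * np.arange(grid.size) / config.etalon_period_px)
        expected = expected * ripple
    return np.clip(expected, 0.0, None), clip_fraction


def render_raw_block(shift_axis: np.ndarray, clean: np.ndarray,
                     excitation_nm: float, template: ClassTemplate,
                     config: CohortConfig, rng: np.random.Generator,
                     background: np.ndarray | None = None,
                     noise: bool = True,
                     include_background: bool = True) -> RawBlock:
    """Render a clean shift-axis spectrum into a detector-space raw block.

    Poisson noise is drawn independently per pixel per repeat.
    """
    expected, clip_fraction = expected_intensity(
        shift_axis, clean, excitation_nm, template, config,
        background=background, include_background=include_background)
    grid = config.detector_grid()
    if noise:
        intensities = rng.poisson(expected, size=(config.repeats, grid.size)).astype(float)
    else:
        intensities = np.tile(expected, (config.repeats, 1))
    return RawBlock(wavelength_nm=grid, intensities=intensities,
                    excitation_nm=excitation_nm, label=template.class_name,
                    clip_fraction=clip_fraction)


def render_mean_spectrum(shift_axis: np.ndarray, clean: np.ndarray,
                         excitation_nm: float, template: ClassTemplate,
                         config: CohortConfig, rng: np.random.Generator,
                         background: np.ndarray | None = None,
                         noise: bool = True):
    """Render the repeat-averaged spectrum without materialising repeats.

    The mean of ``repeats`` independent Poisson(lambda) draws has the exact
    distribution Poisson(repeats * lambda) / repeats, so a single draw per
    pixel reproduces the statistics of averaging a full block.  Used for
    bulk training-pair generation.
    """
    from .core import MeanSpectrum
    expected, _ = expected_intensity(shift_axis, clean, excitation_nm,
                                     template, config, background=background)
    if noise:
        values = rng.poisson(config.repeats * expected) / config.repeats
    else:
        values = expected.copy()
    return MeanSpectrum(wavelength_nm=config.detector_grid(), values=values,
                        excitation_nm=excitation_nm, n_repeats=config.repeats)


def locus_background_amplitude(template: ClassTemplate, clean_max: float,
                               rng: np.random.Generator) -> float:
    """Per-locus fluorescence apex amplitude, scaled off the realized Raman max.

    Scaling off the realized (not nominal) strongest line keeps the
    background >= amplitude_ratio times the Raman maximum for every locus.
    """
    bg = template.background
    ratio = bg.amplitude_ratio * float(_lognormal_factor(bg.ratio_cv, rng))
    return max(ratio, 1.0) * clean_max


def generate_cohort(config: CohortConfig | None = None,
                    library: dict[str, ClassTemplate] | None = None
                    ) -> list[GroundTruthPair]:
    """Generate a labelled cohort of dual-excitation ground-truth pairs.

    Deterministic given (config, library): all randomness flows from
    ``config.seed``.  Loci are assigned to pseudo-specimens round-robin to
    mirror the study's specimen counts.
    """
    config = config or CohortConfig()
    library = library or build_class_library()
    rng = np.random.default_rng(config.seed)
    shift_axis = truth_shift_axis()
    grid = config.detector_grid()
    ex_lo, ex_hi = sorted(config.excitations_nm)
    pairs: list[GroundTruthPair] = []
    for name, count in config.locus_counts:
        template = library[name]
        n_specimens = DEFAULT_SPECIMEN_COUNTS.get(name, count)
        for i in range(count):
            clean = sample_clean_spectrum(template, shift_axis, rng)
            clean_max = float(clean.max()) if clean.size else 0.0
            amp = locus_background_amplitude(
                template, clean_max if clean_max > 0 else 1.0, rng)
            bg = amp * template.background.profile(grid)
            if config.background_drift_nm != 0.0:
                # imperfect Kasha insensitivity: lower-excitation background
                # is the same profile evaluated at a slightly shifted axis
                bg_lo = amp * template.background.profile(
                    grid + config.background_drift_nm)
            else:
                bg_lo = bg
            locus_id = f"{name}-{i + 1:03d}"
            specimen_id = f"{name}-sp{(i % n_specimens) + 1:02d}"
            block_a = render_raw_block(shift_axis, clean, ex_lo, template,
                                       config, rng, background=bg_lo)
            block_b = render_raw_block(shift_axis, clean, ex_hi, template,
                                       config, rng, background=bg)
            block_a.locus_id = block_b.locus_id = locus_id
            pairs.append(GroundTruthPair(shift_cm1=shift_axis, clean=clean,
                                         block_a=block_a, block_b=block_b,
                                         locus_id=locus_id, label=name,
                                         specimen_id=specimen_id))
    return pairs
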