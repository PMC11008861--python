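"""End-to-end orchestration: cohort -> difference -> purify -> classify.

Thin glue over the stage modules so the command-line interface, the
analysis drivers and the test suite all run exactly the same computation.
"""

from __future__ import annotations

import numpy as np

from . import axes, classify, core, purifier, synthetic
from .io import RunConfig


def cohort_config_from_run(rc: RunConfig, seed: int | None = None
                           ) -> synthetic.CohortConfig:
    return synthetic.CohortConfig(
        locus_counts=tuple(rc.locus_counts().items()),
        repeats=rc.repeats, detector_pixels=rc.detector_pixels,
        seed=rc.seed if seed is None else seed)


def purifier_config_from_run(rc: RunConfig, seed: int | None = None
                             ) -> purifier.PurifierConfig:
    return purifier.PurifierConfig(
        epochs=rc.epochs, batch_size=rc.batch_size,
        learning_rate=rc.learning_rate,
        seed=rc.seed if seed is None else seed)


def difference_for_pair(pair: synthetic.GroundTruthPair) -> core.DifferenceSpectrum:
    """Average both blocks, z-score, subtract (lower minus higher excitation)."""
    return core.serds_difference(core.mean_block(pair.block_a),
                                 core.mean_block(pair.block_b),
                                 locus_id=pair.locus_id, label=pair.label)


def purify_cohort(trained: purifier.TrainedPurifier,
                  cohort: list[synthetic.GroundTruthPair]
                  ) -> list[core.PurifiedSpectrum]:
    return [purifier.purify(trained, difference_for_pair(p)) for p in cohort]


def classify_cohort(trained: purifier.TrainedPurifier,
                    cohort: list[synthetic.GroundTruthPair],
                    k: int = 5, seed: int = 0,
                    low: float = axes.FINGERPRINT_LOW_CM1,
                    high: float = axes.FINGERPRINT_HIGH_CM1):
    """Purify every locus then run the cross-validated PCA-LDA panels."""
    spectra = purify_cohort(trained, cohort)
    data = classify.assemble_dataset(
        spectra, low=low, high=high,
        specimen_ids=[p.specimen_id for p in cohort])
    return classify.cross_validate(data, k=k, seed=seed)


def offpeak_mask(template: synthetic.ClassTemplate,
                 shift_axis: np.ndarray) -> np.ndarray:
    """Bins at least two FWHMs away from every Raman line of the class."""
    shift_axis = np.asarray(shift_axis, dtype=float)
    mask = np.ones_like(shift_axis, dtype=bool)
    for p in template.peaks:
        mask &= np.abs(shift_axis - p.center_cm1) >= 2.0 * p.fwhm_cm1
    return mask


def benchmark_purifier(trained: purifier.TrainedPurifier,
                       n_test: int = 200, seed: int = 12345,
                       library: dict | None = None) -> dict:
    """Held-out synthetic benchmark of the neural purifier vs the classic baseline.

    Generates fresh (difference, truth) test pairs, runs both
    reconstructions, and reports per-pair Pearson correlation with the
    clean truth, apex-position error of the strongest peak, off-peak
    residuals (bins >= 2 FWHM from any true line) and mean squared errors.
    All outputs and truths are compared on unit-maximum scale.
    """
    library = library or synthetic.build_class_library()
    cohort_config = synthetic.CohortConfig(seed=seed)
    pur_config = trained.config
    shift_axis = axes.purifier_shift_axis(pur_config.input_len)
    truth_axis = synthetic.truth_shift_axis()
    grid = cohort_config.detector_grid()
    ex_lo, ex_hi = sorted(cohort_config.excitations_nm)
    rng = np.random.default_rng(seed)
    names = list(library)

    r_unet, peak_err, off_unet, off_classic = [], [], [], []
    mse_unet, mse_classic = [], []
    for _ in range(n_test):
        template = library[names[rng.integers(len(names))]]
        clean = synthetic.sample_clean_spectrum(template, truth_axis, rng)
        amp = synthetic.locus_background_amplitude(template, float(clean.max()), rng)
        bg = amp * template.background.profile(grid)
        m_lo = synthetic.render_mean_spectrum(truth_axis, clean, ex_lo,
                                              template, cohort_config, rng,
                                              background=bg)
        m_hi = synthetic.render_mean_spectrum(truth_axis, clean, ex_hi,
                                              template, cohort_config, rng,
                                              background=bg)
        diff = core.serds_difference(m_lo, m_hi, label=template.class_name)
        truth = np.interp(shift_axis, truth_axis, clean)
        truth = truth / truth.max()

        recon_u = purifier.purify(trained, diff, shift_axis).values
        recon_c = core.classic_reconstruct(diff, shift_axis).values
        um = np.max(np.abs(recon_u))
        cm = np.max(np.abs(recon_c))
        u = recon_u / um if um > 0 else recon_u
        c = recon_c / cm if cm > 0 else recon_c

        r_unet.append(float(np.corrcoef(u, truth)[0, 1]))
        # strongest-peak location audit
        visible = [p for p in template.peaks
                   if shift_axis[0] <= p.center_cm1 <= shift_axis[-1]]
        strongest = max(visible, key=lambda p: p.mean_amplitude)
        window = np.abs(shift_axis - strongest.center_cm1) <= 3 * strongest.fwhm_cm1
        apex = shift_axis[window][np.argmax(u[window])]
        true_apex = shift_axis[np.argmin(np.abs(shift_axis - strongest.center_cm1))]
        peak_err.append(float(abs(apex - true_apex)))

        mask = offpeak_mask(template, shift_axis)
        off_unet.append(float(np.median(np.abs(u[mask]))))
        off_classic.append(float(np.median(np.abs(c[mask]))))
        mse_unet.append(float(np.mean((u - truth) ** 2)))
        mse_classic.append(float(np.mean((c - truth) ** 2)))

    return {
        "n_test": n_test,
        "pearson_r": np.asarray(r_unet),
        "peak_error_cm1": np.asarray(peak_err),
        "offpeak_unet": np.asarray(off_unet),
        "offpeak_classic": np.asarray(off_classic),
        "mse_unet": np.asarray(mse_unet),
        "mse_classic": np.asarray(mse_classic),
        "median_pearson_r": float(np.median(r_unet)),
        "median_peak_error_cm1": float(np.median(peak_err)),
    }


def train_default_purifier(n_pairs: int = 2000, epochs: int = 10,
                           seed: int = 0) -> purifier.TrainedPurifier:
    """Train the default purifier on freshly generated synthetic pairs."""
    config = purifier.PurifierConfig(epochs=epochs, seed=seed)
    pairs = purifier.make_training_pairs(n_pairs, seed=seed)
    return purifier.train_purifier(pairs, config)
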