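import numpy as np
import pytest

from serds import axes, core, synthetic
from serds.synthetic import (CLASS_NAMES, ClassTemplate, CohortConfig,
                             RamanPeak, build_class_library, generate_cohort,
                             render_raw_block, sample_clean_spectrum)

from conftest import single_line_template


class TestClassLibrary:
    def test_six_templates_with_valid_peaks(self, library):
        assert set(library) == set(CLASS_NAMES)
        for template in library.values():
            for p in template.peaks:
                assert 200.0 <= p.center_cm1 <= 2000.0
                assert p.fwhm_cm1 > 0 and p.mean_amplitude >= 0
            assert template.background.amplitude_ratio >= 1.0

    def test_bone_is_the_only_class_with_the_phosphate_marker(self, library):
        # 960 cm^-1 phosphate nu1 is diagnostic for mineralised tissue
        with_marker = [name for name, t in library.items()
                       if any(955 <= p.center_cm1 <= 965 for p in t.peaks)]
        assert with_marker == ["bone"]

    def test_neurofibroma_carries_the_phenylalanine_line(self, library):
        centers = {p.center_cm1 for p in library["neurofibroma"].peaks}
        assert 1004 in centers

    def test_lipid_classes_emphasise_lipid_bands(self, library):
        for name in ("fat", "nerve"):
            centers = {p.center_cm1 for p in library[name].peaks}
            assert any(1440 <= c <= 1470 for c in centers)
            assert 1073 in centers

    def test_unknown_override_class_rejected(self):
        with pytest.raises(ValueError, match="unknown class"):
            build_class_library({"cartilage": {}})

    def test_override_removing_peaks_gives_flat_spectrum(self, rng):
        lib = build_class_library({"fat": {"peaks": ()}})
        clean = sample_clean_spectrum(lib["fat"], synthetic.truth_shift_axis(), rng)
        assert np.all(clean == 0.0)


class TestCleanSpectrumSampling:
    def test_lorentzian_apex_and_half_maximum(self, rng):
        template = single_line_template(1004.0, 15.0, 1.0)
        axis = np.array([996.5, 1004.0, 1011.5])
        clean = sample_clean_spectrum(template, axis, rng)
        assert clean[1] == pytest.approx(1.0)
        assert clean[0] == pytest.approx(0.5)   # half maximum at +/- fwhm/2
        assert clean[2] == pytest.approx(0.5)

    def test_lognormal_amplitude_mean(self):
        # sample mean of 1000 lognormal draws within 3 standard errors of 1
        template = single_line_template(1004.0, 15.0, 1.0, cv=0.2)
        axis = np.array([990.0, 1004.0, 1020.0])
        rng = np.random.default_rng(123)
        draws = [sample_clean_spectrum(template, axis, rng)[1] for _ in range(1000)]
        se = 0.2 / np.sqrt(1000)
        assert np.mean(draws) == pytest.approx(1.0, abs=3 * se)

    def test_nonnegative_everywhere(self, library, rng):
        axis = synthetic.truth_shift_axis()
        for template in library.values():
            assert np.all(sample_clean_spectrum(template, axis, rng) >= 0)

    def test_decreasing_axis_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_clean_spectrum(single_line_template(), np.array([2.0, 1.0]), rng)


class TestRawBlockRendering:
    def test_noise_off_repeats_identical_to_mapped_clean(self, rng):
        template = single_line_template()
        config = CohortConfig(repeats=50)
        axis = synthetic.truth_shift_axis()
        clean = sample_clean_spectrum(template, axis, rng)
        block = render_raw_block(axis, clean, 784.0, template, config, rng,
                                 noise=False, include_background=False)
        expected = np.interp(
            axes.wavelength_to_shift(config.detector_grid(), 784.0),
            axis, clean, left=0, right=0) + template.noise_scale
        assert block.n_repeats == 50
        assert np.array_equal(block.intensities,
                              np.tile(expected, (50, 1)))

    def test_fluorescence_identical_for_both_excitations(self, rng):
        # difference of the two renders vanishes wherever no line contributes
        template = single_line_template()
        config = CohortConfig()
        axis = synthetic.truth_shift_axis()
        # truncated line: exactly zero outside +/- 3 fwhm
        clean = sample_clean_spectrum(template, axis, rng)
        clean[np.abs(axis - 1004.0) > 45.0] = 0.0
        bg = 20000.0 * template.background.profile(config.detector_grid())
        r784 = render_raw_block(axis, clean, 784.0, template, config, rng,
                                background=bg, noise=False)
        r785 = render_raw_block(axis, clean, 785.0, template, config, rng,
                                background=bg, noise=False)
        diff = r784.intensities[0] - r785.intensities[0]
        grid = config.detector_grid()
        line_784 = axes.shift_to_wavelength(1004.0, 784.0)
        line_785 = axes.shift_to_wavelength(1004.0, 785.0)
        away = ((np.abs(grid - line_784) > 6.0) & (np.abs(grid - line_785) > 6.0))
        assert np.all(diff[away] == 0.0)
        assert np.max(np.abs(diff)) > 0  # the line itself does move

    def test_raman_line_moves_by_one_excitation_step(self, rng):
        template = single_line_template(fwhm=8.0)
        config = CohortConfig()
        axis = synthetic.truth_shift_axis()
        clean = sample_clean_spectrum(template, axis, rng)
        ref = max(config.excitations_nm)
        apexes = {}
        for ex in config.excitations_nm:
            block = render_raw_block(axis, clean, ex, template, config, rng,
                                     noise=False, include_background=False)
            wl = block.wavelength_nm[np.argmax(block.intensities[0])]
            apexes[ex] = axes.wavelength_to_shift(wl, ref)
        step = apexes[784.0] - apexes[785.0]
        pixel_cm1 = 2.0  # ~0.137 nm pixel pitch in shift units
        assert step == pytest.approx(-axes.excitation_step_shift(),
                                     abs=pixel_cm1)

    def test_unknown_excitation_rejected(self, rng):
        template = single_line_template()
        config = CohortConfig()
        axis = synthetic.truth_shift_axis()
        with pytest.raises(ValueError, match="not in config"):
            render_raw_block(axis, np.zeros_like(axis), 700.0, template,
                             config, rng)

    def test_offgrid_lines_reported_as_clipped(self, rng):
        template = single_line_template(center=250.0, fwhm=10.0)
        config = CohortConfig()
        axis = synthetic.truth_shift_axis()
        clean = sample_clean_spectrum(template, axis, rng)
        block = render_raw_block(axis, clean, 785.0, template, config, rng,
                                 noise=False, include_background=False)
        assert block.clip_fraction > 0.05


class TestCohortGeneration:
    def test_default_cohort_composition(self, default_cohort):
        assert len(default_cohort) == 82
        counts = {}
        for p in default_cohort:
            counts[p.label] = counts.get(p.label, 0) + 1
        assert counts == synthetic.DEFAULT_LOCUS_COUNTS
        n_spectra = sum(p.block_a.n_repeats + p.block_b.n_repeats
                        for p in default_cohort)
        assert n_spectra == 8200

    def test_seed_determinism(self):
        config = CohortConfig(seed=7, locus_counts=(("bone", 2), ("fat", 2)))
        a = generate_cohort(config)
        b = generate_cohort(config)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.clean, pb.clean)
            assert np.array_equal(pa.block_a.intensities, pb.block_a.intensities)
            assert np.array_equal(pa.block_b.intensities, pb.block_b.intensities)

    def test_one_locus_per_class(self):
        config = CohortConfig(locus_counts=tuple((n, 1) for n in CLASS_NAMES))
        cohort = generate_cohort(config)
        assert len(cohort) == 6
        assert sum(p.block_a.n_repeats + p.block_b.n_repeats
                   for p in cohort) == 600

    def test_fluorescence_dominates_every_raw_spectrum(self, default_cohort):
        # mean raw intensity is far above the strongest possible Raman line
        for pair in default_cohort[::9]:
            for block in (pair.block_a, pair.block_b):
                raman_max = pair.clean.max()
                assert block.intensities.max() >= raman_max

    def test_background_dominance_by_construction(self, library, rng):
        config = CohortConfig()
        grid = config.detector_grid()
        axis = synthetic.truth_shift_axis()
        for template in library.values():
            clean = sample_clean_spectrum(template, axis, rng)
            amp = synthetic.locus_background_amplitude(
                template, float(clean.max()), rng)
            bg = amp * template.background.profile(grid)
            assert bg.max() >= clean.max()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(locus_counts=(("bone", 0),))
        with pytest.raises(ValueError):
            CohortConfig(excitations_nm=(785.0, 785.0))
        with pytest.raises(ValueError):
            CohortConfig(locus_counts=(("gristle", 3),))


class TestContrastBlending:
    def test_zero_contrast_removes_class_signal(self, library, rng):
        blended = synthetic.blend_library(library, 0.0)
        axis = synthetic.truth_shift_axis()
        spectra = []
        for t in blended.values():
            zero_cv = tuple(RamanPeak(p.center_cm1, p.fwhm_cm1,
                                      p.mean_amplitude, 0.0) for p in t.peaks)
            t0 = ClassTemplate(t.class_name, zero_cv)
            spectra.append(sample_clean_spectrum(t0, axis, rng))
        for s in spectra[1:]:
            assert np.allclose(s, spectra[0])

    def test_full_contrast_is_identity(self, library):
        blended = synthetic.blend_library(library, 1.0)
        for name in library:
            own = {(p.center_cm1): p.mean_amplitude for p in library[name].peaks}
            new = {(p.center_cm1): p.mean_amplitude for p in blended[name].peaks
                   if p.center_cm1 in own}
            assert all(np.isclose(new[c], own[c]) for c in own)
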