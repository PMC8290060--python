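"""Synthetic study generators: determinism, structure and ground-truth guarantees."""

import numpy as np
import pandas as pd
import pytest

from seasonfuse import synthetic
from seasonfuse.formulas import theoretical_mz
from seasonfuse.synthetic import (
    SEASONS,
    generate_climate,
    generate_design,
    generate_ms_features,
    generate_nmr_spectra,
    generate_reference_library,
)


class TestGenerateDesign:
    def test_row_counts(self):
        table = generate_design(3, 2, 42)
        assert len(table) == 24
        assert (table.season.value_counts() == 6).all()

    def test_minimal_design(self):
        table = generate_design(1, 1, 0)
        assert len(table) == 4
        assert set(table.season) == set(SEASONS)

    def test_deterministic(self):
        pd.testing.assert_frame_equal(generate_design(3, 2, 42),
                                      generate_design(3, 2, 42))

    def test_unique_sample_ids(self):
        table = generate_design(4, 3, 1)
        assert table.sample_id.is_unique

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_design(0, 1)
        with pytest.raises(ValueError):
            generate_design(1, 0)


class TestGenerateClimate:
    def test_seasonal_contrasts(self, design):
        climate = generate_climate(design, 7).merge(design, on="sample_id")
        means = climate.groupby("season").mean(numeric_only=True)
        assert means.loc["summer", "temperature"] > means.loc["winter", "temperature"]
        assert means.loc["winter", "rainfall"] < means.loc["spring", "rainfall"]

    def test_physical_bounds(self, design):
        climate = generate_climate(design, 8)
        assert climate.humidity.between(0, 100).all()
        assert (climate.rainfall >= 0).all()
        assert (climate.radiation >= 0).all()

    def test_deterministic(self, design):
        pd.testing.assert_frame_equal(generate_climate(design, 7),
                                      generate_climate(design, 7))


class TestGenerateMsFeatures:
    def test_shapes_and_ground_truth_counts(self, design, ms_study):
        matrix, truth = ms_study
        assert matrix.n_features == 200
        assert len(truth.planted_ms) == 10
        assert len(truth.blank_ms) == 10
        assert set(truth.planted_ms).isdisjoint(truth.blank_ms)

    def test_all_areas_positive(self, ms_study):
        matrix, _ = ms_study
        assert (matrix.areas() > 0).all().all()

    def test_acquisition_ranges(self, ms_study):
        matrix, _ = ms_study
        assert matrix.features.mz.between(150, 2000).all()
        assert matrix.features.rt_min.between(0, 45).all()

    def test_deterministic(self, design):
        a, _ = generate_ms_features(design, 50, 5, 5, 3.0, 11)
        b, _ = generate_ms_features(design, 50, 5, 5, 3.0, 11)
        pd.testing.assert_frame_equal(a.features, b.features)

    def test_blank_ratio_separation(self, ms_study):
        """Blank features: mean sample/blank ratio < 1; biological: > 10."""
        matrix, truth = ms_study
        feats = matrix.features.set_index("feature_id")
        ratio = feats[matrix.sample_ids].mean(axis=1) / feats["blank"]
        assert (ratio.loc[truth.blank_ms] < 1).all()
        biological = ratio.index.difference(truth.blank_ms)
        assert (ratio.loc[biological] > 10).all()

    def test_effect_size_zero_removes_group_structure(self, design):
        matrix, truth = generate_ms_features(design, 60, 6, 0, 0.0, 13)
        seasons = design.season.to_numpy()
        areas = matrix.areas()
        log_area = np.log(areas[list(truth.planted_ms)])
        gaps = []
        for fid, (season, d) in truth.planted_ms.items():
            assert d == 0.0
            col = log_area[fid].to_numpy()
            gaps.append(col[seasons == season].mean() - col.mean())
        # With no planted shift the seasonal deviation is pure noise.
        assert abs(np.mean(gaps)) < 0.2

    def test_planted_effect_monotone_in_effect_size(self, design):
        """Mean absolute standardized group difference of planted features
        strictly increases with effect size (averaged over seeds)."""
        def mean_gap(effect):
            gaps = []
            for seed in (0, 1, 2):
                matrix, truth = generate_ms_features(design, 60, 6, 0, effect, seed)
                seasons = design.season.to_numpy()
                areas = np.log(matrix.areas())
                for fid, (season, _) in truth.planted_ms.items():
                    col = areas[fid].to_numpy()
                    inside = col[seasons == season]
                    outside = col[seasons != season]
                    gaps.append(abs(inside.mean() - outside.mean()) / col.std(ddof=1))
            return np.mean(gaps)

        gaps = [mean_gap(e) for e in (0.0, 1.0, 3.0)]
        assert gaps[0] < gaps[1] < gaps[2]

    def test_inconsistent_counts_rejected(self, design):
        with pytest.raises(ValueError):
            generate_ms_features(design, 10, 8, 8, 3.0, 0)


class TestGenerateNmrSpectra:
    def test_common_axis_and_count(self, nmr_study):
        spectra, _ = nmr_study
        assert len(spectra) == 24
        for s in spectra[1:]:
            np.testing.assert_array_equal(s.ppm, spectra[0].ppm)

    def test_deterministic(self, design):
        a, _ = generate_nmr_spectra(design, n_peaks=10, n_planted=2, seed=5)
        b, _ = generate_nmr_spectra(design, n_peaks=10, n_planted=2, seed=5)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_noiseless_single_peak_max_at_center(self, design):
        spectra, _ = generate_nmr_spectra(
            design.head(1), n_peaks=1, n_planted=0, seed=3,
            baseline_amplitude=0.0, noise_sd=0.0)
        s = spectra[0]
        # peak 0 is the reference resonance; maximum sits at its center
        assert s.intensity.max() > 0.5
        peak_ppm = s.ppm[np.argmax(s.intensity)]
        top_region = s.ppm[s.intensity > 0.5 * s.intensity.max()]
        assert top_region.min() <= peak_ppm <= top_region.max()

    def test_planted_bins_inside_range(self, nmr_study):
        _, truth = nmr_study
        assert len(truth.planted_nmr_peaks) == 5
        labels = truth.planted_bin_labels()
        assert len(labels) == 5
        for center in truth.planted_nmr_peaks:
            assert 0.0 <= center <= 10.0

    def test_planted_peaks_resolved(self, nmr_study):
        _, truth = nmr_study
        centers = sorted(truth.planted_nmr_peaks)
        assert all(b - a >= 0.08 for a, b in zip(centers, centers[1:]))

    def test_invalid_range(self, design):
        with pytest.raises(ValueError):
            generate_nmr_spectra(design, ppm_range=(5.0, 2.0))
        with pytest.raises(ValueError):
            generate_nmr_spectra(design, ppm_range=(0.0, 20.0))


class TestReferenceLibrary:
    def test_size_and_uniqueness(self, library):
        assert len(library) >= 30
        assert library.name.is_unique

    def test_formulas_parse_with_carbon(self, library):
        from seasonfuse.formulas import parse_formula
        for formula in library.formula:
            counts = parse_formula(formula)
            assert counts.get("C", 0) >= 1

    @pytest.mark.parametrize("formula,adduct,printed_mz", [
        # Flavan-3-ol oligomer series [M+H]+
        ("C15H14O6", "[M+H]+", 291.0860),
        ("C30H26O12", "[M+H]+", 579.1500),
        ("C45H38O18", "[M+H]+", 867.2117),
        ("C60H50O24", "[M+H]+", 1155.2719),
        # Galloylquinic series [M+H]+
        ("C14H16O10", "[M+H]+", 345.0819),
        ("C21H20O14", "[M+H]+", 497.0930),
        ("C28H24O18", "[M+H]+", 649.1040),
        ("C35H28O22", "[M+H]+", 801.1151),
        # Triterpenes
        ("C30H50O", "[M+H]+", 427.3938),
        ("C30H48O3", "[M-H]-", 455.3546),
        ("C30H46O5", "[M+H]+", 487.3422),
        ("C30H48O5", "[M+H]+", 489.3579),
        # A-type pentamer
        ("C75H60O30", "[M+H]+", 1441.3228),
    ])
    def test_library_formulas_match_reference_ions(self, library, formula,
                                                   adduct, printed_mz):
        assert formula in set(library.formula)
        theo = theoretical_mz(formula, adduct)
        assert abs((printed_mz - theo) / theo) * 1e6 <= 5.0

    def test_required_classes_present(self, library):
        classes = set(library["class"])
        assert {"proanthocyanidin", "galloylquinic acid", "triterpene",
                "glycosylated flavonoid"} <= classes
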