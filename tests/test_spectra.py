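"""Spectrum I/O, calibration and the formatting chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from xrfmorph import (
    GRID_HI,
    GRID_LO,
    GRID_STEP,
    LANDMARK_GRID,
    N_LANDMARKS,
    Spectrum,
    calibrate_energy,
    extract_landmarks,
    landmark_vector,
    log_standardize,
    read_manifest,
    read_spectrum,
    reconstruct_continuous,
    subset_energy,
    write_spectrum,
)
from xrfmorph.spectra import validate_manifest


class TestReadSpectrum:
    def test_two_column_parse(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("2.0,10\n2.1,12\n")
        s = read_spectrum(p)
        assert np.allclose(s.energy, [2.0, 2.1])
        assert np.allclose(s.counts, [10, 12])

    def test_header_and_comments_ignored(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("# a comment\nenergy_keV,counts\n2.0,10\n2.1,12\n")
        s = read_spectrum(p)
        assert s.energy.size == 2

    def test_non_monotone_energy_names_row(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("3.0,1\n2.0,2\n")
        with pytest.raises(ValueError, match="non-monotone energy at row 1"):
            read_spectrum(p)

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("1.0,1\n2.0,-3\n")
        with pytest.raises(ValueError, match="negative counts"):
            read_spectrum(p)

    def test_single_row_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("1.0,1\n")
        with pytest.raises(ValueError):
            read_spectrum(p)

    def test_round_trip_identity(self, tmp_path, rng):
        energy = np.sort(rng.uniform(0.5, 20.0, size=100))
        counts = rng.uniform(0.0, 1e4, size=100)
        original = Spectrum("z", energy, counts)
        path = write_spectrum(original, tmp_path / "rt.csv")
        back = read_spectrum(path)
        assert np.array_equal(back.energy, original.energy)
        assert np.array_equal(back.counts, original.counts)

    def test_emsa_xy_mode(self, tmp_path):
        text = (
            "#FORMAT      : EMSA/MAS Spectral Data File\n"
            "#VERSION     : 1.0\n"
            "#DATATYPE    : XY\n"
            "#NPOINTS     : 3\n"
            "#SPECTRUM    : Spectral Data Starts Here\n"
            "1.0, 5\n1.5, 7\n2.0, 6\n"
            "#ENDOFDATA   :\n"
        )
        p = tmp_path / "s.msa"
        p.write_text(text)
        s = read_spectrum(p)  # format sniffed from the #FORMAT keyword
        assert np.allclose(s.energy, [1.0, 1.5, 2.0])
        assert np.allclose(s.counts, [5, 7, 6])


class TestManifest:
    def test_study_design_counts(self, dataset, tmp_path):
        path = tmp_path / "manifest.csv"
        dataset.manifest.to_csv(path, index=False)
        m = read_manifest(path)
        assert len(m) == 252

    def test_one_specimen_six_zones(self):
        rows = [
            {"zone_id": f"S1-{zt[:3]}{i}", "specimen_id": "S1", "site": "Paris Canyon",
             "clade": "arthropod", "zone_type": zt, "session": "DiffAbs-2018",
             "mineralogy": "phosphatic"}
            for zt in ("fossil", "sediment") for i in (1, 2, 3)
        ]
        m = validate_manifest(pd.DataFrame(rows))
        assert len(m) == 6
        assert (m["zone_type"] == "fossil").sum() == 3
        assert (m["zone_type"] == "sediment").sum() == 3

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_manifest(p)

    def test_missing_column_listed(self):
        df = pd.DataFrame({"zone_id": ["a"], "specimen_id": ["s"]})
        with pytest.raises(ValueError, match="site"):
            validate_manifest(df)

    def test_unknown_zone_type_rejected(self):
        df = pd.DataFrame([{"zone_id": "a", "specimen_id": "s", "site": "x", "clade": "c",
                            "zone_type": "bone", "session": "s1", "mineralogy": "m"}])
        with pytest.raises(ValueError, match="zone_type"):
            validate_manifest(df)

    def test_duplicate_zone_session_rejected(self):
        row = {"zone_id": "a", "specimen_id": "s", "site": "x", "clade": "c",
               "zone_type": "fossil", "session": "s1", "mineralogy": "m"}
        with pytest.raises(ValueError, match="duplicate"):
            validate_manifest(pd.DataFrame([row, row]))


class TestCalibration:
    def test_exact_affine_solution(self):
        cal = calibrate_energy([(369.2, 3.692), (640.5, 6.405), (1495.8, 14.958)])
        assert cal.gain == pytest.approx(0.01, abs=1e-12)
        assert cal.offset == pytest.approx(0.0, abs=1e-10)

    def test_identity_when_already_in_kev(self):
        cal = calibrate_energy([(3.692, 3.692), (6.405, 6.405)])
        assert cal.gain == pytest.approx(1.0)
        assert cal.offset == pytest.approx(0.0, abs=1e-12)

    def test_residuals_match_least_squares_oracle(self):
        pairs = [(100.0, 1.05), (200.0, 2.0), (300.0, 3.1)]  # non-collinear
        cal = calibrate_energy(pairs)
        ch = np.array([p[0] for p in pairs])
        en = np.array([p[1] for p in pairs])
        design = np.vstack([np.ones_like(ch), ch]).T
        coef, *_ = np.linalg.lstsq(design, en, rcond=None)
        oracle_resid = np.max(np.abs(design @ coef - en))
        assert cal.max_residual > 0
        assert cal.max_residual == pytest.approx(oracle_resid, rel=1e-9)

    def test_too_few_or_coincident_pairs(self):
        with pytest.raises(ValueError):
            calibrate_energy([(1.0, 1.0)])
        with pytest.raises(ValueError, match="coincident"):
            calibrate_energy([(1.0, 1.0), (1.0, 2.0)])


class TestReconstruction:
    def test_exact_at_points_linear_between(self, rng):
        energy = np.sort(rng.uniform(1.0, 19.0, 50))
        counts = rng.uniform(0, 100, 50)
        s = Spectrum("z", energy, counts)
        f = reconstruct_continuous(s)
        assert np.allclose(f(energy), counts)
        # brute-force per-interval check at interval midpoints
        mid = (energy[:-1] + energy[1:]) / 2
        expected = counts[:-1] + (counts[1:] - counts[:-1]) * 0.5
        assert np.allclose(f(mid), expected)

    def test_linear_midpoint(self):
        f = reconstruct_continuous(Spectrum("z", [2.0, 2.1], [10.0, 20.0]))
        assert f(2.05) == pytest.approx(15.0)

    def test_query_outside_support_errors(self):
        f = reconstruct_continuous(Spectrum("z", [2.0, 18.5], [1.0, 2.0]))
        with pytest.raises(ValueError, match="outside"):
            f(1.0)


class TestSubset:
    def test_support_becomes_exact_window(self, rng):
        energy = np.arange(0.2, 20.6, 0.017)
        s = Spectrum("z", energy, rng.uniform(1, 10, energy.size))
        sub = subset_energy(s)
        assert sub.support == (1.7, 18.3)
        assert np.all((sub.energy >= 1.7) & (sub.energy <= 18.3))

    def test_already_exact_unchanged(self):
        s = Spectrum("z", np.linspace(1.7, 18.3, 50), np.arange(50, dtype=float))
        sub = subset_energy(s)
        assert np.array_equal(sub.energy, s.energy)
        assert np.array_equal(sub.counts, s.counts)

    def test_retained_count_matches_range_oracle(self):
        energy = np.round(np.arange(0.2, 20.6 + 1e-9, 0.01), 10)
        s = Spectrum("z", energy, np.ones(energy.size))
        sub = subset_energy(s)
        inside = int(np.sum((energy >= 1.7) & (energy <= 18.3)))
        synthesized = int(1.7 not in energy) + int(18.3 not in energy)
        assert sub.energy.size == inside + synthesized

    def test_narrow_support_rejected(self):
        s = Spectrum("z", [2.0, 18.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="does not cover"):
            subset_energy(s)

    def test_idempotent(self, rng):
        energy = np.linspace(0.2, 20.6, 500)
        s = Spectrum("z", energy, rng.uniform(0, 5, 500))
        once = subset_energy(s)
        twice = subset_energy(once)
        assert np.array_equal(once.energy, twice.energy)
        assert np.array_equal(once.counts, twice.counts)


class TestLogStandardize:
    def test_known_values(self):
        s = Spectrum("z", [1.0, 2.0, 3.0], [9.0, 99.0, 999.0])
        out = log_standardize(s)
        expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)  # (1,2,3) z-scored
        assert np.allclose(out.counts, expected)
        assert expected[2] == pytest.approx(1.2247448, abs=1e-6)

    def test_constant_spectrum_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            log_standardize(Spectrum("z", [1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_always_mean0_sd1(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 400))
        s = Spectrum("z", np.sort(r.uniform(0.2, 20.6, n)), r.uniform(0, 1e4, n))
        out = log_standardize(s)
        assert abs(out.counts.mean()) < 1e-12
        assert abs(np.std(out.counts) - 1.0) < 1e-12


class TestLandmarks:
    def test_grid_arithmetic(self):
        assert int(round((GRID_HI - GRID_LO) / GRID_STEP)) + 1 == N_LANDMARKS == 831
        assert LANDMARK_GRID[0] == 1.7
        assert LANDMARK_GRID[-1] == 18.3
        assert np.allclose(np.diff(LANDMARK_GRID), 0.02)

    def test_linear_spectrum_sampled_exactly(self):
        s = Spectrum("z", [0.2, 20.6], [0.2 * 3 + 1, 20.6 * 3 + 1])  # the line 3E + 1
        lm = extract_landmarks(s)
        assert lm.shape == (831,)
        assert np.allclose(lm, 3 * LANDMARK_GRID + 1)

    def test_insufficient_support_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            extract_landmarks(Spectrum("z", [2.0, 18.0], [1.0, 2.0]))

    def test_formatting_chain_deterministic(self, tmp_path, rng):
        energy = np.sort(rng.uniform(0.2, 20.6, 300))
        energy[0], energy[-1] = 0.2, 20.6
        s = Spectrum("z", energy, rng.uniform(0, 1e3, 300))
        path = write_spectrum(s, tmp_path / "d.csv")
        v1 = landmark_vector(read_spectrum(path))
        v2 = landmark_vector(read_spectrum(path))
        assert np.array_equal(v1, v2)
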