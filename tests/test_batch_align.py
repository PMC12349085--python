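"""Session realignment via homologous control spectra and replicate averaging."""

import numpy as np
import pandas as pd
import pytest

from xrfmorph import (
    BatchDelta,
    LandmarkMatrix,
    N_LANDMARKS,
    apply_realignment,
    average_pseudoreplicates,
    compute_mean_delta,
    fit_pca,
    pair_homologous,
    realign_sessions,
)


def _meta(rows):
    base = {"site": "Paris Canyon", "clade": "arthropod", "zone_type": "fossil",
            "mineralogy": "phosphatic"}
    return pd.DataFrame([{**base, **r} for r in rows])


def _matrix(values, rows, aligned=False):
    return LandmarkMatrix(np.asarray(values, dtype=float), _meta(rows), aligned=aligned)


def _row(zone, session, specimen=None):
    return {"zone_id": zone, "session": session, "specimen_id": specimen or zone.split("-")[0]}


class TestPairing:
    def test_study_design_yields_12_pairs(self, landmark_matrix):
        pairs = pair_homologous(landmark_matrix, "PUMA-2021", "DiffAbs-2018")
        assert len(pairs) == 12  # 2 control specimens x 6 zones

    def test_same_session_pairs_identical_rows(self, landmark_matrix):
        pairs = pair_homologous(landmark_matrix, "DiffAbs-2018", "DiffAbs-2018")
        assert all(i == j for i, j in pairs)

    def test_missing_partner_excluded(self):
        values = np.zeros((5, N_LANDMARKS))
        m = _matrix(values, [
            _row("A-f1", "s1"), _row("A-f2", "s1"), _row("A-f1", "s2"),
            _row("A-f2", "s2"), _row("A-f3", "s2"),  # f3 unmatched in s1
        ])
        pairs = pair_homologous(m, "s2", "s1")
        assert len(pairs) == 2

    def test_no_pairs_is_an_error(self):
        m = _matrix(np.zeros((2, N_LANDMARKS)), [_row("A-f1", "s1"), _row("B-f1", "s2")])
        with pytest.raises(ValueError, match="no homologous"):
            pair_homologous(m, "s2", "s1")


class TestMeanDelta:
    def test_identical_spectra_zero_delta(self):
        v = np.tile(np.arange(N_LANDMARKS, dtype=float), (2, 1))
        m = _matrix(v, [_row("A-f1", "s1"), _row("A-f1", "s2")])
        d = compute_mean_delta(m, [(1, 0)], "s2", "s1")
        assert np.array_equal(d.delta, np.zeros(N_LANDMARKS))

    def test_mean_of_constant_offsets(self):
        base = np.zeros(N_LANDMARKS)
        v = np.vstack([base, base, base + 1.0, base + 3.0])
        m = _matrix(v, [_row("A-f1", "s1"), _row("A-f2", "s1"),
                        _row("A-f1", "s2"), _row("A-f2", "s2")])
        d = compute_mean_delta(m, [(2, 0), (3, 1)], "s2", "s1")
        assert np.allclose(d.delta, 2.0)
        assert d.n_pairs == 2

    def test_single_pair_is_its_difference(self, rng):
        v = rng.normal(size=(2, N_LANDMARKS))
        m = _matrix(v, [_row("A-f1", "s1"), _row("A-f1", "s2")])
        d = compute_mean_delta(m, [(1, 0)], "s2", "s1")
        assert np.allclose(d.delta, v[1] - v[0])


class TestRealignment:
    def test_zero_delta_is_identity(self, rng):
        v = rng.normal(size=(3, N_LANDMARKS))
        m = _matrix(v, [_row("A-f1", "s1"), _row("A-f1", "s2"), _row("A-f2", "s2")])
        out = apply_realignment(m, BatchDelta("s2", "s1", np.zeros(N_LANDMARKS), 1))
        assert np.array_equal(out.values, v)
        assert out.aligned

    def test_reference_session_rows_untouched(self, rng):
        v = rng.normal(size=(2, N_LANDMARKS))
        m = _matrix(v, [_row("A-f1", "s1"), _row("A-f1", "s2")])
        out = apply_realignment(m, BatchDelta("s2", "s1", np.full(N_LANDMARKS, 5.0), 1))
        assert np.array_equal(out.values[0], v[0])
        assert np.allclose(out.values[1], v[1] - 5.0)

    def test_mean_homologous_residual_zero_for_arbitrary_offsets(self, rng):
        ref = rng.normal(size=(4, N_LANDMARKS))
        offsets = rng.normal(size=(4, N_LANDMARKS))  # each pair shifted differently
        rows = [_row(f"A-f{i}", "s1") for i in range(4)] + [_row(f"A-f{i}", "s2") for i in range(4)]
        m = _matrix(np.vstack([ref, ref + offsets]), rows)
        pairs = pair_homologous(m, "s2", "s1")
        delta = compute_mean_delta(m, pairs, "s2", "s1")
        out = apply_realignment(m, delta)
        residuals = np.stack([out.values[i] - out.values[j] for i, j in pairs])
        assert np.max(np.abs(residuals.mean(axis=0))) < 1e-12

    def test_constant_session_offset_cancels_exactly(self, rng):
        ref = rng.normal(size=(3, N_LANDMARKS))
        offset = rng.normal(size=N_LANDMARKS)  # same curve for every zone
        rows = [_row(f"A-f{i}", "s1") for i in range(3)] + [_row(f"A-f{i}", "s2") for i in range(3)]
        m = _matrix(np.vstack([ref, ref + offset]), rows)
        out, _ = realign_sessions(m, "s1")
        pairs = pair_homologous(out, "s2", "s1")
        for i, j in pairs:
            assert np.allclose(out.values[i], out.values[j], atol=1e-12)

    def test_within_session_differences_preserved(self, rng):
        v = rng.normal(size=(4, N_LANDMARKS))
        rows = [_row("A-f1", "s1"), _row("A-f1", "s2"), _row("A-f2", "s2"), _row("A-f3", "s2")]
        m = _matrix(v, rows)
        out = apply_realignment(m, BatchDelta("s2", "s1", rng.normal(size=N_LANDMARKS), 1))
        assert np.allclose(out.values[2] - out.values[1], v[2] - v[1])
        assert np.allclose(out.values[3] - out.values[2], v[3] - v[2])

    def test_session_separation_vanishes_on_pc1(self, rng):
        # three sessions differing only by additive offset curves
        n_per, grid = 30, N_LANDMARKS
        base = rng.normal(size=(n_per, grid))
        offsets = {"s1": np.zeros(grid), "s2": 3 * np.sin(np.linspace(0, 6, grid)),
                   "s3": np.linspace(-2, 2, grid)}
        rows, values = [], []
        for ses, off in offsets.items():
            for i in range(n_per):
                rows.append(_row(f"A-f{i}", ses))
                values.append(base[i] + off)
        m = _matrix(np.vstack(values), rows)
        out, _ = realign_sessions(m, "s1")
        pc1 = fit_pca(out).scores[:, 0]
        ses = m.meta["session"].to_numpy()
        for other in ("s2", "s3"):
            a, b = pc1[ses == "s1"], pc1[ses == other]
            pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
            assert abs(a.mean() - b.mean()) / pooled < 0.1


class TestAveraging:
    def test_study_design_252_to_228(self, landmark_matrix):
        aligned, _ = realign_sessions(landmark_matrix, "DiffAbs-2018")
        merged = average_pseudoreplicates(aligned)
        assert landmark_matrix.n_rows == 252
        assert merged.n_rows == 228

    def test_mean_of_two_sessions(self):
        v = np.vstack([np.zeros(N_LANDMARKS), np.full(N_LANDMARKS, 2.0)])
        m = _matrix(v, [_row("A-f1", "s1"), _row("A-f1", "s2")], aligned=True)
        merged = average_pseudoreplicates(m)
        assert merged.n_rows == 1
        assert np.allclose(merged.values[0], 1.0)
        assert merged.meta.at[0, "session"] == "merged"

    def test_single_session_rows_pass_through(self, rng):
        v = rng.normal(size=(2, N_LANDMARKS))
        m = _matrix(v, [_row("A-f1", "s1"), _row("A-f2", "s1")])
        merged = average_pseudoreplicates(m)
        assert np.array_equal(merged.values, v)
        assert list(merged.meta["session"]) == ["s1", "s1"]

    def test_idempotent(self, landmark_matrix):
        aligned, _ = realign_sessions(landmark_matrix, "DiffAbs-2018")
        once = average_pseudoreplicates(aligned)
        twice = average_pseudoreplicates(once)
        assert np.array_equal(once.values, twice.values)

    def test_unaligned_multisession_rejected(self, rng):
        v = rng.normal(size=(2, N_LANDMARKS))
        m = _matrix(v, [_row("A-f1", "s1"), _row("A-f1", "s2")])
        with pytest.raises(ValueError, match="realigned"):
            average_pseudoreplicates(m)
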