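"""Spine resampling, tangent correlations, the worm-like-chain decay fit
and the WLC simulator."""

import math

import numpy as np
import pytest

from wirebundle.analysis import (CorrelationPair, Trace,
                                 estimate_persistence_length, fit_persistence,
                                 generate_wlc, read_traces_csv,
                                 resample_spine, tangent_correlation,
                                 vertex_distance_stats)
from wirebundle.errors import AnalysisError, FitRangeError


def straight_trace(length=110.0, n=23):
    x = np.linspace(0, length, n)
    return Trace(points=np.stack([x, np.zeros_like(x)], axis=1))


class TestResample:
    def test_straight_segment_point_count(self):
        sp = resample_spine(straight_trace(110.0), spacing=11.0)
        assert len(sp.points) == 11
        assert np.allclose(np.diff(sp.points[:, 0]), 11.0)
        assert np.allclose(sp.points[0], [0, 0])

    def test_semicircle_equal_arc_spacing(self):
        """Arc-length parameterization oracle: on a finely sampled
        semicircle, resampled points are equally spaced in arc length
        (angle increments equal)."""
        r = 50.0
        t = np.linspace(0, np.pi, 2001)
        tr = Trace(points=np.stack([r * np.cos(t), r * np.sin(t)], axis=1))
        arc = tr.arc_length
        sp = resample_spine(tr, spacing=arc / 10)
        assert len(sp.points) == 11
        ang = np.arctan2(sp.points[:, 1], sp.points[:, 0])
        ang[ang < 0] += 2 * np.pi
        dang = np.abs(np.diff(ang))
        assert np.allclose(dang, dang[0], rtol=1e-3)

    def test_too_short_trace_rejected(self):
        tr = Trace(points=np.array([[0, 0], [2.5, 0], [5.0, 0]]))
        with pytest.raises(AnalysisError, match="shorter"):
            resample_spine(tr, spacing=11.0)

    def test_trace_validation(self):
        with pytest.raises(AnalysisError):
            Trace(points=np.array([[0, 0], [1, 1]]))  # too few
        with pytest.raises(AnalysisError, match="repeated"):
            Trace(points=np.array([[0, 0], [0, 0], [1, 1]]))


class TestTangentCorrelation:
    def test_straight_lines_give_unit_cosine(self):
        spines = [resample_spine(straight_trace(), 11.0) for _ in range(3)]
        for c in tangent_correlation(spines):
            assert c.mean_cosine == pytest.approx(1.0)

    def test_rotation_and_translation_invariance(self):
        chains = generate_wlc(500, 11, 30, 5, seed=7)
        base = tangent_correlation(chains)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = [Trace(points=t.points @ R.T + np.array([13.0, -4.0]))
                 for t in chains]
        got = tangent_correlation(moved)
        for a, b in zip(base, got):
            assert b.mean_cosine == pytest.approx(a.mean_cosine, abs=1e-12)
            assert b.n_pairs == a.n_pairs

    def test_wlc_ensemble_decays(self):
        chains = generate_wlc(300, 11, 50, 200, seed=3)
        corr = tangent_correlation(chains)
        c5 = [c.mean_cosine for c in corr[:5]]
        assert all(b < a for a, b in zip(c5, c5[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(AnalysisError):
            tangent_correlation([])


class TestFitPersistence:
    @staticmethod
    def exact_pairs(p, s, spacing=11.0, n=15):
        return [CorrelationPair(k * spacing,
                                math.exp(-k * spacing / (s * p)), 100)
                for k in range(1, n + 1)]

    def test_exact_inversion_machine_precision(self):
        fit = fit_persistence(self.exact_pairs(500.0, 2.0), s=2.0)
        assert abs(fit.p_nm - 500.0) / 500.0 < 1e-9

    def test_s_and_p_enter_as_product(self):
        """Fitting data generated at s=2, p=500 with s=1 must return
        p=1000: only s*p is identifiable."""
        fit = fit_persistence(self.exact_pairs(500.0, 2.0), s=1.0)
        assert fit.p_nm == pytest.approx(1000.0, rel=1e-9)

    def test_non_decaying_reports_infinity(self):
        pairs = [CorrelationPair(k * 11.0, 0.9 + 0.005 * k, 50)
                 for k in range(1, 8)]
        fit = fit_persistence(pairs)
        assert math.isinf(fit.p_nm)
        assert "non-decaying" in fit.diagnostics["reason"]

    def test_all_below_cutoff_fit_range_error(self):
        pairs = [CorrelationPair(k * 11.0, 0.1, 50) for k in range(1, 6)]
        with pytest.raises(FitRangeError):
            fit_persistence(pairs)

    def test_too_few_separations_rejected(self):
        pairs = [CorrelationPair(11.0, 0.9, 100),
                 CorrelationPair(22.0, 0.8, 100)]
        with pytest.raises(AnalysisError, match=">= 3"):
            fit_persistence(pairs)

    @pytest.mark.parametrize("p_true", [200.0, 461.0, 1000.0, 1730.0])
    def test_parameter_recovery_within_15_percent(self, p_true):
        """100 chains x 50 points at 11 nm recover the generating
        persistence length, mirroring the TEM analysis at both measured
        stiffness scales."""
        chains = generate_wlc(p_true, 11.0, 50, 100, seed=2026)
        fit = estimate_persistence_length(chains, spacing=11.0,
                                          resample=False)
        assert abs(fit.p_nm - p_true) / p_true < 0.15


class TestGenerateWlc:
    def test_stiff_limit_nearly_straight(self):
        chains = generate_wlc(1e9, 11, 50, 20, seed=0)
        corr = tangent_correlation(chains)
        assert corr[0].mean_cosine > 0.9999

    def test_one_step_cosine_matches_closed_form(self):
        """p = spacing: E[cos] at one step is exp(-1/2)."""
        chains = generate_wlc(11.0, 11.0, 200, 300, seed=9)
        corr = tangent_correlation(chains)
        assert corr[0].mean_cosine == pytest.approx(math.exp(-0.5),
                                                    abs=0.01)

    def test_deterministic_per_seed(self):
        a = generate_wlc(500, 11, 20, 3, seed=4)
        b = generate_wlc(500, 11, 20, 3, seed=4)
        for t1, t2 in zip(a, b):
            assert np.array_equal(t1.points, t2.points)

    def test_invalid_parameters(self):
        with pytest.raises(AnalysisError):
            generate_wlc(-1, 11, 50, 10)


class TestVertexDistanceStats:
    def test_simple_groups(self):
        df = vertex_distance_stats({"a": [10, 10, 10], "b": [20, 20]},
                                   order=["a", "b"])
        assert df["mean_nm"].tolist() == [10.0, 20.0]
        assert df["n"].tolist() == [3, 2]
        assert df.attrs["monotone_increasing"]

    def test_single_group_vacuously_monotone(self):
        df = vertex_distance_stats({"only": [5.0]})
        assert df.attrs["monotone_increasing"]

    def test_synthetic_designed_lengths_recovered(self):
        """Groups simulated around the five designed pentagon edge
        lengths (27..78 nm) recover the means and the increasing trend."""
        rng = np.random.default_rng(11)
        designed = [27.2, 41.1, 54.1, 68.0, 78.2]
        groups = {f"d{i}": (d + rng.normal(0, 2.0, size=100)).tolist()
                  for i, d in enumerate(designed)}
        df = vertex_distance_stats(groups, order=sorted(groups))
        assert df.attrs["monotone_increasing"]
        for mean, d in zip(df["mean_nm"], designed):
            assert abs(mean - d) < 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            vertex_distance_stats({"x": []})


def test_traces_csv_roundtrip(tmp_path):
    import pandas as pd
    chains = generate_wlc(800, 11, 20, 3, seed=1)
    rows = [{"trace_id": t.source, "x_nm": x, "y_nm": y}
            for t in chains for x, y in t.points]
    path = tmp_path / "traces.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    back = read_traces_csv(path)
    assert len(back) == 3
    assert all(len(t.points) == 20 for t in back)
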