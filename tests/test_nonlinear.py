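"""Entropy/RQA contracts, checked against independent brute-force oracles.

The oracles re-derive ApEn, SampEn and the recurrence measures from their
definitions with explicit loops over template/point pairs — no shared code
with the implementation under test.
"""

import math

import numpy as np
import pytest

from gaitfall.nonlinear import (
    EntropySpec,
    RqaSpec,
    apen,
    coarse_grain,
    mse,
    rqa,
    sampen,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def apen_oracle(x, m=2, r=0.25):
    x = np.asarray(x, float)
    n = len(x)
    tol = r * x.std()

    def phi(mm):
        templates = [x[i : i + mm] for i in range(n - mm + 1)]
        total = 0.0
        for a in templates:
            count = 0
            for b in templates:
                if max(abs(a - b)) <= tol:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def sampen_oracle(x, m=2, r=0.25, tol=None):
    x = np.asarray(x, float)
    n = len(x)
    if tol is None:
        tol = r * x.std()
    B = A = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i : i + m] - x[j : j + m])) <= tol:
                B += 1
            if max(abs(x[i : i + m + 1] - x[j : j + m + 1])) <= tol:
                A += 1
    if A == 0 or B == 0:
        return np.nan
    return -math.log(A / B)


def rqa_oracle(x, dim=5, delay=10, radius=0.40, lmin=2, theiler=None):
    x = np.asarray(x, float)
    z = (x - x.mean()) / x.std()
    n_e = len(z) - (dim - 1) * delay
    pts = [z[i : i + (dim - 1) * delay + 1 : delay] for i in range(n_e)]
    if theiler is None:
        theiler = delay
    dmax = 0.0
    for i in range(n_e):
        for j in range(n_e):
            d = math.dist(pts[i], pts[j])
            dmax = max(dmax, d)
    thr = radius * dmax
    rec = [[math.dist(pts[i], pts[j]) <= thr for j in range(n_e)] for i in range(n_e)]
    allowed = rec_count = 0
    for i in range(n_e):
        for j in range(n_e):
            if abs(i - j) > theiler:
                allowed += 1
                if rec[i][j]:
                    rec_count += 1
    rr = rec_count / allowed
    lengths = []
    for k in range(theiler + 1, n_e):
        run = 0
        for i in range(n_e - k):
            if rec[i][i + k]:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    long_l = [l for l in lengths if l >= lmin]
    det = 2 * sum(long_l) / rec_count if rec_count else 0.0
    if long_l:
        vals, counts = np.unique(long_l, return_counts=True)
        p = counts / counts.sum()
        ent = float(-(p * np.log(p)).sum())
        maxline = max(long_l)
    else:
        ent, maxline = 0.0, 0
    return rr, det, ent, maxline


# ---------------------------------------------------------------------------


class TestApEn:
    def test_constant_series_is_zero(self):
        assert apen(np.ones(100)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self, rng):
        for _ in range(3):
            x = rng.standard_normal(120)
            assert apen(x) == pytest.approx(apen_oracle(x), abs=1e-12)

    def test_sine_more_regular_than_noise(self, rng):
        t = np.linspace(0, 20, 1000)
        wins = 0
        for _ in range(20):
            sine = np.sin(2 * np.pi * t + rng.uniform(0, 2 * np.pi))
            noise = rng.standard_normal(1000)
            noise *= sine.std() / noise.std()
            wins += apen(sine) < apen(noise)
        assert wins >= 19

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            apen(np.arange(10))


class TestSampEn:
    def test_defaults_are_m2_r025(self):
        spec = EntropySpec()
        assert spec.m == 2 and spec.r == 0.25

    def test_constant_series_is_zero(self):
        assert sampen(np.ones(80)) == pytest.approx(0.0)

    def test_matches_brute_force(self, rng):
        for _ in range(3):
            x = rng.standard_normal(150)
            assert sampen(x) == pytest.approx(sampen_oracle(x), abs=1e-12)

    def test_no_match_flagged(self, rng):
        # continuous random values never repeat within a vanishing tolerance
        x = rng.standard_normal(60)
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(sampen(x, EntropySpec(r=1e-12)))

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(200)
        assert sampen(x) == pytest.approx(sampen(5.0 * x), abs=1e-12)


class TestCoarseGrain:
    def test_identity_at_scale_one(self, rng):
        x = rng.standard_normal(30)
        np.testing.assert_array_equal(coarse_grain(x, 1), x)

    def test_hand_case(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4], 2), [1.5, 3.5])

    def test_variance_shrinks_like_clt(self, rng):
        vars_ = [np.var(coarse_grain(rng.standard_normal(20000), 4)) for _ in range(10)]
        assert np.mean(vars_) == pytest.approx(0.25, rel=0.1)

    def test_tau_too_large_rejected(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(5), 6)


class TestMse:
    def test_white_noise_entropy_decreases_with_scale(self, rng):
        hits = 0
        for _ in range(10):
            scales, vals, _, slope = mse(rng.standard_normal(2000))
            hits += slope < 0 and vals[0] > vals[-1]
        assert hits >= 9

    def test_pink_exceeds_white_in_area(self, rng):
        from gaitfall.synthetic import pink_noise

        spec = EntropySpec.for_length(2000)
        wins = 0
        for _ in range(10):
            _, _, area_w, _ = mse(rng.standard_normal(2000), spec)
            _, _, area_p, _ = mse(pink_noise(2000, rng), spec)
            wins += area_p > area_w
        assert wins >= 9

    def test_scale_range_rule(self):
        assert EntropySpec.for_length(1000).mse_scales == tuple(range(1, 7))
        assert EntropySpec.for_length(2000).mse_scales == tuple(range(1, 14))

    def test_constant_series_gives_zero_area_and_slope(self):
        _, _, area, slope = mse(np.ones(500))
        assert area == 0.0 and slope == 0.0

    def test_truncation_flagged_for_short_series(self):
        with pytest.warns(UserWarning, match="truncated"):
            scales, vals, _, _ = mse(np.random.default_rng(0).standard_normal(120))
        assert len(scales) < 6


class TestRqa:
    def test_defaults_match_study_parameters(self):
        spec = RqaSpec()
        assert spec.embedding_dim == 5 and spec.delay == 10
        assert spec.radius_fraction == 0.40

    def test_matches_brute_force(self, rng):
        for n in (200, 300):
            x = rng.standard_normal(n)
            r = rqa(x)
            rr, det, ent, maxline = rqa_oracle(x)
            assert r.recurrence_rate == pytest.approx(rr, abs=1e-12)
            assert r.determinism == pytest.approx(det, abs=1e-12)
            assert r.entropy == pytest.approx(ent, abs=1e-12)
            assert r.maxline == maxline

    def test_sine_is_highly_deterministic(self):
        t = np.arange(500)
        x = np.sin(2 * np.pi * t / 25)
        r = rqa(x)
        assert r.determinism >= 0.95
        assert r.maxline >= 100

    def test_noise_less_deterministic_than_sine(self, rng):
        t = np.arange(500)
        det_sine = rqa(np.sin(2 * np.pi * t / 25)).determinism
        wins = sum(rqa(rng.standard_normal(500)).determinism < det_sine for _ in range(10))
        assert wins == 10

    def test_bounds(self, rng):
        x = rng.standard_normal(400)
        r = rqa(x)
        assert 0 <= r.recurrence_rate <= 1
        assert 0 <= r.determinism <= 1
        n_embedded = 400 - 4 * 10
        assert r.maxline <= n_embedded - 1

    def test_amplitude_invariance(self, rng):
        x = rng.standard_normal(300)
        a, b = rqa(x), rqa(100.0 * x)
        assert a.recurrence_rate == pytest.approx(b.recurrence_rate, abs=1e-12)
        assert a.determinism == pytest.approx(b.determinism, abs=1e-12)
        assert a.maxline == b.maxline

    def test_degenerate_embedding_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            r = rqa(np.ones(100))
        assert r.recurrence_rate == 1.0 and r.determinism == 1.0 and r.degenerate

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            rqa(np.arange(30))
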