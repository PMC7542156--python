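"""Nonlinear battery vs independent brute-force oracles.

Sample entropy is checked against a double-loop template-counting oracle,
RQA line statistics against exhaustive run enumeration on small binary
matrices, and DFA against the known scaling exponents of white noise and
its integral and against fractional Gaussian noise of varying Hurst index.
"""

import numpy as np
import pytest
from scipy import stats

from sibdetect.nonlinear import (
    EmbeddingParams,
    RecurrencePlot,
    cross_sample_entropy,
    dfa_exponent,
    nonlinear_features,
    NONLINEAR_FEATURE_NAMES,
    reconstruct_phase_space,
    rqa_metrics,
    rqa_threshold,
    sample_entropy,
    select_embedding_dimension,
    select_time_delay,
)
from tests.conftest import make_window


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def sampen_bruteforce(x, m, r_coeff=0.2):
    """Double-loop template counting straight from the defining steps."""
    x = np.asarray(x, dtype=float)
    r = r_coeff * x.std()

    def phi(mm):
        nt = len(x) - mm + 1
        tpl = [x[t : t + mm] for t in range(nt)]
        total = 0.0
        for t in range(nt):
            cnt = 0
            for i in range(nt):
                if i == t:
                    continue
                if np.max(np.abs(tpl[t] - tpl[i])) <= r:
                    cnt += 1
            total += cnt / (nt - 1)
        return total / nt

    pm, pm1 = phi(m), phi(m + 1)
    if pm == 0 or pm1 == 0:
        return np.inf
    return -np.log(pm1 / pm)


def rqa_bruteforce(matrix, w=1, lmin=2, vmin=2):
    """Exhaustive cell-by-cell enumeration of diagonal and vertical lines."""
    k = matrix.shape[0]
    offband = [
        (i, j) for i in range(k) for j in range(k)
        if abs(i - j) > w and matrix[i, j]
    ]
    n_rec = len(offband)
    n_cells = sum(1 for i in range(k) for j in range(k) if abs(i - j) > w)

    diag_runs = []
    for d in list(range(-(k - 1), -w)) + list(range(w + 1, k)):
        cells = [(i, i + d) for i in range(k) if 0 <= i + d < k]
        run = 0
        for i, j in cells:
            if matrix[i, j]:
                run += 1
            else:
                if run:
                    diag_runs.append(run)
                run = 0
        if run:
            diag_runs.append(run)

    vert_runs = []
    for j in range(k):
        run = 0
        for i in range(k):
            if matrix[i, j] and abs(i - j) > w:
                run += 1
            else:
                if run:
                    vert_runs.append(run)
                run = 0
        if run:
            vert_runs.append(run)

    det = 100.0 * sum(r for r in diag_runs if r >= lmin) / n_rec if n_rec else 0.0
    lam = 100.0 * sum(r for r in vert_runs if r >= vmin) / n_rec if n_rec else 0.0
    long_v = [r for r in vert_runs if r >= vmin]
    return {
        "recurrence": 100.0 * n_rec / n_cells,
        "determinism": det,
        "laminarity": lam,
        "max_diag": max(diag_runs) if diag_runs else 0,
        "trapping_time": float(np.mean(long_v)) if long_v else 0.0,
    }


def fractional_gaussian_noise(h, n, rng):
    """Davies-Harte circulant-embedding sampler of fGn with Hurst index h."""
    k = np.arange(n + 1)
    gamma = 0.5 * ((k + 1) ** (2 * h) - 2 * k ** (2 * h) + np.abs(k - 1) ** (2 * h))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eigs = np.fft.fft(row).real
    eigs[eigs < 0] = 0.0  # clip tiny negative round-off
    m = len(row)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    f = np.fft.fft(z * np.sqrt(eigs / (2 * m)))
    return f.real[:n]


# ---------------------------------------------------------------------------
# embedding parameters
# ---------------------------------------------------------------------------

class TestDelaySelection:
    def test_white_noise_acf_delay_one(self, rng):
        x = rng.standard_normal(2000)
        sel = select_time_delay(x)
        assert sel.tau_acf == 1

    def test_sine_ami_near_quarter_period(self):
        # light noise breaks the histogram-estimator plateaus of a pure tone,
        # which otherwise create spurious early minima in the binned AMI
        p = 40
        t = np.arange(1200)
        r = np.random.default_rng(0)
        x = np.sin(2 * np.pi * t / p) + 0.05 * r.standard_normal(len(t))
        sel = select_time_delay(x)
        assert abs(sel.tau_ami - p / 4) <= 1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            select_time_delay(np.arange(10.0))


class TestEmbeddingDimension:
    def test_noiseless_sine_low_dimension(self):
        t = np.arange(1000)
        x = np.sin(2 * np.pi * t / 25)
        m, flagged = select_embedding_dimension(x, tau=6)
        assert m <= 3 and not flagged

    def test_white_noise_flagged_at_max(self, rng):
        x = rng.standard_normal(400)
        m, flagged = select_embedding_dimension(x, tau=1, m_max=8)
        assert flagged and m == 8

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            select_embedding_dimension(np.arange(20.0), tau=5, m_max=10)


class TestPhaseSpace:
    def test_exact_construction(self):
        ps = reconstruct_phase_space(np.arange(1.0, 11.0), EmbeddingParams(tau=2, m=3))
        assert ps.vectors.shape == (6, 3)
        np.testing.assert_array_equal(ps.vectors[0], [1, 3, 5])
        np.testing.assert_array_equal(ps.vectors[-1], [6, 8, 10])

    def test_m1_identity(self, rng):
        x = rng.standard_normal(30)
        ps = reconstruct_phase_space(x, EmbeddingParams(tau=3, m=1))
        np.testing.assert_array_equal(ps.vectors.ravel(), x)

    def test_degenerate_length_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_phase_space(np.arange(8.0), EmbeddingParams(tau=4, m=3))

    @pytest.mark.parametrize("n,tau,m", [(50, 1, 2), (50, 5, 4), (200, 7, 6), (16, 3, 5)])
    def test_row_count_formula(self, n, tau, m, rng):
        ps = reconstruct_phase_space(rng.standard_normal(n), EmbeddingParams(tau, m))
        assert ps.vectors.shape[0] == n - (m - 1) * tau


# ---------------------------------------------------------------------------
# entropies
# ---------------------------------------------------------------------------

class TestSampleEntropy:
    def test_constant_series_zero(self):
        assert sample_entropy(np.full(50, 2.0), m=2) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.standard_normal(50)
        assert sample_entropy(x, m=2) == pytest.approx(
            sampen_bruteforce(x, 2), abs=1e-12
        )

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_oracle_equivalence_sweep(self, m, rng):
        for n in (20, 35, 60):
            x = rng.standard_normal(n)
            ours = sample_entropy(x, m=m)
            theirs = sampen_bruteforce(x, m)
            if np.isfinite(theirs):
                assert ours == pytest.approx(theirs, abs=1e-12)
            else:
                assert not np.isfinite(ours)

    def test_periodic_below_noise(self, rng):
        t = np.arange(200)
        periodic = np.sin(2 * np.pi * t / 20)
        noise = rng.standard_normal(200) * periodic.std()
        assert sample_entropy(periodic, m=2) < sample_entropy(noise, m=2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(4.0), m=4)


class TestCrossSampleEntropy:
    def test_self_cross_entropy_zero(self, rng):
        x = rng.standard_normal(80)
        assert cross_sample_entropy(x, x, m=2) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        x, y = rng.standard_normal(60), rng.standard_normal(60)
        assert cross_sample_entropy(x, y, m=2) == pytest.approx(
            cross_sample_entropy(y, x, m=2), abs=1e-12
        )

    def test_synchronous_below_independent(self, rng):
        # identical-shape streams register lower asynchrony than independent
        # noise pairs, averaged over seeds
        vals_same, vals_indep = [], []
        for s in range(5):
            r = np.random.default_rng(s)
            x = np.sin(2 * np.pi * np.arange(100) / 25) + 0.1 * r.standard_normal(100)
            y = x * 2.0 + 0.3  # same shape, different scale
            vals_same.append(cross_sample_entropy(x, y, m=2))
            a, b = r.standard_normal(100), r.standard_normal(100)
            vals_indep.append(cross_sample_entropy(a, b, m=2))
        assert np.mean(vals_same) < np.mean(vals_indep)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_sample_entropy(np.zeros(30), np.zeros(31), m=2)


# ---------------------------------------------------------------------------
# RQA
# ---------------------------------------------------------------------------

class TestRQAThreshold:
    def test_band_on_seeded_noise(self, rng):
        ps = reconstruct_phase_space(rng.standard_normal(120), EmbeddingParams(5, 4))
        rp = rqa_threshold(ps)
        assert 0.1 <= rp.recurrence_pct <= 2.0

    def test_monotone_in_radius(self, rng):
        ps = reconstruct_phase_space(rng.standard_normal(120), EmbeddingParams(5, 4))
        rp = rqa_threshold(ps)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(ps.vectors))
        mask = np.abs(np.subtract.outer(range(len(d)), range(len(d)))) > 1
        pct_small = 100 * ((d < rp.radius) & mask).sum() / mask.sum()
        pct_large = 100 * ((d < 2 * rp.radius) & mask).sum() / mask.sum()
        assert pct_large >= pct_small

    def test_identical_points_rejected(self):
        ps = reconstruct_phase_space(np.zeros(60), EmbeddingParams(5, 4))
        with pytest.raises(ValueError):
            rqa_threshold(ps)


class TestRQAMetrics:
    def test_hand_built_single_diagonal(self):
        # 6x6 with one length-3 diagonal (offset 2) and its symmetric image
        m = np.zeros((6, 6), dtype=np.int8)
        for i in range(3):
            m[i, i + 2] = m[i + 2, i] = 1
        rp = RecurrencePlot(matrix=m, radius=1.0, recurrence_pct=0.0, theiler_w=1)
        rq = rqa_metrics(rp)
        assert rq.determinism == pytest.approx(100.0)
        assert rq.max_diag_len == 3
        assert rq.divergence == pytest.approx(1.0 / 3.0)

    def test_empty_matrix(self):
        rp = RecurrencePlot(np.zeros((8, 8), dtype=np.int8), 1.0, 0.0, 1)
        rq = rqa_metrics(rp)
        assert rq.recurrence == 0.0 and rq.determinism == 0.0 and rq.flagged

    def test_periodic_sine_highly_deterministic(self):
        # non-integer period: an integer period makes >2% of distances exactly
        # zero, which pushes every attainable radius outside the target band
        t = np.arange(120)
        x = np.sin(2 * np.pi * t / 19.7)
        ps = reconstruct_phase_space(x, EmbeddingParams(5, 4))
        rq = rqa_metrics(rqa_threshold(ps))
        assert rq.determinism >= 95.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        r = np.random.default_rng(seed)
        k = int(r.integers(8, 21))
        m = (r.uniform(size=(k, k)) < 0.2).astype(np.int8)
        m = np.triu(m) + np.triu(m, 1).T  # symmetrize
        rp = RecurrencePlot(matrix=m, radius=1.0, recurrence_pct=0.0, theiler_w=1)
        rq = rqa_metrics(rp)
        oracle = rqa_bruteforce(m)
        assert rq.recurrence == pytest.approx(oracle["recurrence"])
        assert rq.determinism == pytest.approx(oracle["determinism"])
        assert rq.laminarity == pytest.approx(oracle["laminarity"])
        assert rq.max_diag_len == oracle["max_diag"]
        assert rq.trapping_time == pytest.approx(oracle["trapping_time"])

    def test_divergence_inverse_of_max_diag(self, rng):
        ps = reconstruct_phase_space(rng.standard_normal(150), EmbeddingParams(5, 4))
        rq = rqa_metrics(rqa_threshold(ps))
        if rq.max_diag_len >= 1:
            assert rq.divergence * rq.max_diag_len == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------

class TestDFA:
    def test_white_noise_exponent(self):
        x = np.random.default_rng(42).standard_normal(4096)
        res = dfa_exponent(x)
        assert res.alpha == pytest.approx(0.5, abs=0.05)

    def test_integrated_noise_exponent(self):
        x = np.cumsum(np.random.default_rng(43).standard_normal(4096))
        res = dfa_exponent(x)
        assert res.alpha == pytest.approx(1.5, abs=0.1)

    def test_constant_series_flagged(self):
        res = dfa_exponent(np.full(256, 0.3))
        assert res.flagged

    def test_linear_ramp_exponent_two(self):
        # a ramp's profile is quadratic; DFA-1 saturates at alpha ~ 2
        res = dfa_exponent(np.linspace(0, 1, 1024))
        assert res.alpha == pytest.approx(2.0, abs=0.15)

    def test_alpha_monotone_in_hurst(self, rng):
        hs = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        alphas = [
            dfa_exponent(fractional_gaussian_noise(h, 4096, rng)).alpha for h in hs
        ]
        rho, _ = stats.spearmanr(hs, alphas)
        assert rho > 0.9

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dfa_exponent(np.arange(10.0))


# ---------------------------------------------------------------------------
# per-window battery
# ---------------------------------------------------------------------------

class TestNonlinearFeatures:
    def test_emits_27_named_values(self, rng):
        f = nonlinear_features(make_window(rng.standard_normal((120, 3))))
        assert set(f.keys()) == set(NONLINEAR_FEATURE_NAMES)
        assert len(f) == 27
        assert all(np.isfinite(v) for v in f.values())

    def test_constant_window_sentinels(self):
        f = nonlinear_features(make_window(np.full((120, 3), 1.0)))
        for c in "xyz":
            assert f[f"sampen_{c}"] == 0.0
            assert f[f"dfa_alpha_{c}"] == 0.5   # flagged DFA maps to neutral
            assert f[f"rqa_recurrence_{c}"] == 0.0  # degenerate RQA path

    def test_dynamics_differ_in_determinism(self, rng):
        t = np.arange(120) / 60.0
        periodic = make_window(
            np.column_stack([np.sin(2 * np.pi * 4 * t + p) for p in (0, 1, 2)])
        )
        noisy = make_window(rng.standard_normal((120, 3)))
        fp = nonlinear_features(periodic)
        fn = nonlinear_features(noisy)
        assert fp["rqa_determinism_x"] > fn["rqa_determinism_x"]
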