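"""Evaluation metrics against hand arithmetic and naive-loop oracles."""

import math

import numpy as np
import pytest

from kpfuse import (
    ImageBuffer,
    MetricReport,
    coefficient_of_variation,
    cosine_similarity,
    evaluate_sequences,
    joint_accuracy,
    mse,
    percentage_difference,
    psnr,
    r_squared,
    ssim,
)
from kpfuse.synthetic import make_test_image
from conftest import build_sequence


# ---------------------------------------------------------------------------
# Naive-loop oracles, written independently of the vectorised implementations
# ---------------------------------------------------------------------------

def oracle_mse(F, D):
    total = 0.0
    for f, d in zip(F, D):
        for a, b in zip(np.atleast_1d(f), np.atleast_1d(d)):
            total += (a - b) ** 2
    return total / len(F)


def oracle_cosine(F, D):
    f = [x for row in np.atleast_2d(F) for x in row]
    d = [x for row in np.atleast_2d(D) for x in row]
    num = sum(a * b for a, b in zip(f, d))
    return num / (math.sqrt(sum(a * a for a in f)) * math.sqrt(sum(b * b for b in d)))


def oracle_r2(F, D):
    f = [x for row in np.atleast_2d(F) for x in row]
    d = [x for row in np.atleast_2d(D) for x in row]
    m = sum(d) / len(d)
    ss_res = sum((a - b) ** 2 for a, b in zip(f, d))
    ss_tot = sum((b - m) ** 2 for b in d)
    return 1.0 - ss_res / ss_tot


def oracle_percentage(F, D):
    f = [abs(x) for row in np.atleast_2d(F) for x in row]
    d = [abs(x) for row in np.atleast_2d(D) for x in row]
    terms = [abs(a - b) / ((a + b) / 2) for a, b in zip(f, d)]
    return 100.0 * sum(terms) / len(terms)


def oracle_accuracy(F, D, thr):
    hits = 0
    for f, d in zip(F, D):
        if math.dist(f, d) <= thr:
            hits += 1
    return hits / len(F)


def oracle_cv(vals):
    m = sum(vals) / len(vals)
    var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
    return math.sqrt(var) / m * 100.0


def oracle_ssim(p, q, L=1.0):
    gp = [0.2126 * a + 0.7152 * b + 0.0722 * c for a, b, c in p.reshape(-1, 3)]
    gq = [0.2126 * a + 0.7152 * b + 0.0722 * c for a, b, c in q.reshape(-1, 3)]
    mp, mq = sum(gp) / len(gp), sum(gq) / len(gq)
    vp = sum((a - mp) ** 2 for a in gp) / len(gp)
    vq = sum((a - mq) ** 2 for a in gq) / len(gq)
    cov = sum((a - mp) * (b - mq) for a, b in zip(gp, gq)) / len(gp)
    c1, c2 = (0.01 * L) ** 2, (0.03 * L) ** 2
    return ((2 * mp * mq + c1) * (2 * cov + c2)) / ((mp**2 + mq**2 + c1) * (vp + vq + c2))


def oracle_psnr(p, q, L=1.0):
    err = sum((a - b) ** 2 for a, b in zip(p.reshape(-1), q.reshape(-1))) / p.size
    return 10.0 * math.log10(L * L / err)


class TestHandExamples:
    def test_mse(self):
        assert mse([1.0, 2.0], [0.0, 0.0]) == pytest.approx(2.5)
        assert mse([1.0, 1.0], [1.0, 1.0]) == 0.0
        assert mse([3.0, 4.0], [1.0, 2.0]) == pytest.approx(4.0)  # constant shift c^2

    def test_cosine(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(1 / math.sqrt(2))
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_r_squared(self):
        assert r_squared([0.0, 1.0, 2.0], [0.0, 2.0, 4.0]) == pytest.approx(0.375)
        assert r_squared([1.0, 2.0], [1.0, 2.0]) == 1.0
        d = [1.0, 2.0, 3.0]
        assert r_squared([2.0, 2.0, 2.0], d) == pytest.approx(0.0)  # predict mean(D)
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [3.0, 3.0])

    def test_percentage_difference(self):
        assert percentage_difference([3.0], [1.0]) == pytest.approx(100.0)
        assert percentage_difference([2.0, 2.0], [2.0, 2.0]) == 0.0
        with pytest.raises(ValueError):
            percentage_difference([0.0], [0.0])  # zero mean-pair denominator
        # distance variant on 3-vectors
        F = np.array([[3.0, 0.0, 0.0]])
        D = np.array([[1.0, 0.0, 0.0]])
        assert percentage_difference(F, D, mode="distance") == pytest.approx(100.0)

    def test_joint_accuracy_counting(self):
        D = np.zeros((12, 2))
        F = np.zeros((12, 2))
        F[:9, 0] = 5.0  # nine at distance 5
        F[9:, 0] = 20.0  # three at distance 20
        assert joint_accuracy(F, D, 8.0) == pytest.approx(0.75)
        assert joint_accuracy(F, F, 6.0) == 1.0

    def test_cv(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0]) == 0.0
        # [1, 3]: sample sd = sqrt(2), mean 2
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(math.sqrt(2) / 2 * 100)
        a = coefficient_of_variation([1.0, 2.0, 3.0])
        assert coefficient_of_variation([10.0, 20.0, 30.0]) == pytest.approx(a)
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])

    def test_ssim_constant_images(self):
        a, b = 0.25, 0.75
        p = ImageBuffer(np.full((4, 4, 3), a))
        q = ImageBuffer(np.full((4, 4, 3), b))
        c1 = 0.01**2
        expected = (2 * a * b + c1) / (a * a + b * b + c1)  # variance terms -> c2/c2
        assert ssim(p, q) == pytest.approx(expected)
        assert ssim(p, p) == pytest.approx(1.0)

    def test_psnr_identities(self):
        img = make_test_image("checker", 8)
        assert psnr(img, img) == math.inf
        # per-pixel MSE = 6.5025 on the 8-bit scale: 255^2 / 6.5025 = 1e4 -> 40 dB
        p = np.zeros((10, 10))
        q = p + math.sqrt(6.5025)  # uniform offset 2.55
        assert psnr(p, q, max_value=255.0) == pytest.approx(40.0, abs=1e-9)
        # MSE = MAX^2 -> 0 dB
        z = np.zeros((4, 4))
        o = np.ones((4, 4))
        assert psnr(z, o) == pytest.approx(0.0)


@pytest.fixture(scope="module")
def instances():
    rng = np.random.default_rng(314)
    out = []
    for _ in range(100):
        n = rng.integers(3, 30)
        F = rng.normal(1.0, 2.0, size=(int(n), 3))
        D = rng.normal(1.0, 2.0, size=(int(n), 3))
        out.append((F, D))
    return out


class TestOracleEquivalence:

    def test_trajectory_metrics_match_loops(self, instances):
        for F, D in instances:
            assert mse(F, D) == pytest.approx(oracle_mse(F, D), abs=1e-10)
            assert cosine_similarity(F, D) == pytest.approx(oracle_cosine(F, D), abs=1e-10)
            assert r_squared(F, D) == pytest.approx(oracle_r2(F, D), abs=1e-10)
            assert percentage_difference(np.abs(F) + 0.1, np.abs(D) + 0.1) == pytest.approx(
                oracle_percentage(np.abs(F) + 0.1, np.abs(D) + 0.1), abs=1e-10
            )
            thr = 2.5
            assert joint_accuracy(F[:, :2], D[:, :2], thr) == pytest.approx(
                oracle_accuracy(F[:, :2], D[:, :2], thr), abs=1e-10
            )
            assert coefficient_of_variation(np.abs(F[:, 0]) + 1) == pytest.approx(
                oracle_cv(list(np.abs(F[:, 0]) + 1)), abs=1e-10
            )

    def test_image_metrics_match_loops(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            p = rng.random((6, 5, 3))
            q = np.clip(p + rng.normal(0, 0.1, size=p.shape), 0, 1)
            bp, bq = ImageBuffer(p.copy()), ImageBuffer(q.copy())
            assert ssim(bp, bq) == pytest.approx(oracle_ssim(bp.pixels, bq.pixels), abs=1e-6)
            assert psnr(bp, bq) == pytest.approx(oracle_psnr(bp.pixels, bq.pixels), abs=1e-6)

    def test_psnr_matches_skimage(self):
        from skimage.metrics import peak_signal_noise_ratio

        rng = np.random.default_rng(7)
        p = rng.random((8, 8, 3))
        q = np.clip(p + rng.normal(0, 0.05, size=p.shape), 0, 1)
        assert psnr(ImageBuffer(p.copy()), ImageBuffer(q.copy())) == pytest.approx(
            peak_signal_noise_ratio(p, q, data_range=1.0), abs=1e-9
        )


class TestStructuralProperties:
    def test_accuracy_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        F = rng.normal(size=(200, 2)) * 5
        D = rng.normal(size=(200, 2)) * 5
        assert joint_accuracy(F, D, 8.0) >= joint_accuracy(F, D, 6.0)

    def test_symmetry(self):
        rng = np.random.default_rng(22)
        F = rng.random((30, 3)) + 0.5
        D = rng.random((30, 3)) + 0.5
        assert mse(F, D) == pytest.approx(mse(D, F))
        assert percentage_difference(F, D) == pytest.approx(percentage_difference(D, F))
        ip = ImageBuffer(np.clip(F[:9].reshape(3, 3, 3), 0, 1))
        iq = ImageBuffer(np.clip(D[:9].reshape(3, 3, 3), 0, 1))
        assert ssim(ip, iq) == pytest.approx(ssim(iq, ip))

    def test_r_squared_asymmetric(self):
        F = np.array([0.0, 1.0, 2.0])
        D = np.array([0.0, 2.0, 4.0])
        assert r_squared(F, D) != pytest.approx(r_squared(D, F))

    def test_psnr_decreases_with_noise(self):
        rng = np.random.default_rng(23)
        img = make_test_image("gradient", 32)
        vals = []
        for sigma in (0.01, 0.05, 0.1, 0.2):
            noisy = ImageBuffer(
                np.clip(img.pixels + rng.normal(0, sigma, img.pixels.shape), 0, 1)
            )
            vals.append(psnr(img, noisy))
        assert np.all(np.diff(vals) < 0)


class TestSequenceReport:
    def test_report_excludes_invalid_samples(self):
        rng = np.random.default_rng(31)
        coords = rng.normal(size=(40, 12, 3)) + 5.0
        ref = build_sequence(coords)
        pred_coords = coords + 0.01 * rng.normal(size=coords.shape)
        # corrupt some frames but mark them invalid: they must not count
        valid = np.ones((40, 12), bool)
        valid[0, 0] = False
        pred_coords2 = pred_coords.copy()
        pred_coords2[0, 0] = np.nan
        pred = build_sequence(pred_coords2, valid=valid)
        rep = evaluate_sequences(pred, ref, thresholds=(6.0, 8.0))
        assert rep.n == 40 * 12 - 1
        assert rep.joint_accuracy[8.0] >= rep.joint_accuracy[6.0]
        assert 0.0 <= rep.joint_accuracy[6.0] <= 1.0
        assert rep.r_squared <= 1.0

    def test_monotonicity_enforced_in_report(self):
        with pytest.raises(ValueError, match="monotone"):
            MetricReport(
                mse=0.0, r_squared=1.0, cosine=1.0, diff_percent=0.0,
                joint_accuracy={6.0: 0.9, 8.0: 0.5},
            )
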