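import math

import numpy as np
import pytest

from hrvstress import (
    DegenerateSeriesError,
    EstimationError,
    ValidationError,
    approximate_entropy,
    chon_threshold,
    correlation_dimension,
    detrended_fluctuation,
    extract_all_features,
    max_entropy_threshold,
    poincare_descriptors,
    recurrence_measures,
)
from hrvstress.features import (
    _euclidean_distances,
    correlation_sum,
    entropy_profile,
    sdds,
    sdnn,
)
from hrvstress.rr_io import RRSeries, to_nn

from conftest import make_rr_like


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def apen_oracle(x, m, r):
    """Exhaustive pairwise evaluation with explicit loops."""
    x = np.asarray(x, dtype=float)

    def phi(mm):
        n = len(x) - mm + 1
        templates = [x[i:i + mm] for i in range(n)]
        logs = np.empty(n)
        for i in range(n):
            count = 0
            for j in range(n):
                if np.max(np.abs(templates[i] - templates[j])) <= r:
                    count += 1
            logs[i] = np.log(count / n)
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


def rqa_oracle(matrix):
    """Walk every diagonal of the boolean matrix, both triangles,
    accumulating the run-length histogram (runs >= 2, main diagonal
    excluded); then the five measures."""
    k = matrix.shape[0]
    rec = sum(int(matrix[i, j]) for i in range(k) for j in range(k)) / k**2
    hist = {}
    for offset in range(1, k):
        for rows, cols in (
            (range(k - offset), range(offset, k)),        # upper triangle
            (range(offset, k), range(k - offset)),        # lower triangle
        ):
            run = 0
            for i, j in zip(rows, cols):
                if matrix[i, j]:
                    run += 1
                else:
                    if run >= 2:
                        hist[run] = hist.get(run, 0) + 1
                    run = 0
            if run >= 2:
                hist[run] = hist.get(run, 0) + 1
    if not hist:
        return rec, 0.0, 0.0, 0.0, 0
    lengths = np.array(sorted(hist))
    counts = np.array([hist[l] for l in lengths], dtype=float)
    points = float(np.sum(lengths * counts))
    det = points / float(np.count_nonzero(matrix))
    l_mean = points / counts.sum()
    l_max = int(lengths.max())
    fractions = counts / counts.sum()
    shen = float(-np.sum(fractions * np.log(fractions)))
    return rec, det, shen, l_mean, l_max


# ---------------------------------------------------------------------------
# Poincaré
# ---------------------------------------------------------------------------

class TestPoincare:
    def test_constant_series(self):
        sd1, sd2 = poincare_descriptors(np.full(100, 0.8))
        assert sd1 == 0.0
        assert sd2 == pytest.approx(0.0, abs=1e-12)  # 1-ulp mean rounding

    def test_alternating_series(self):
        # odd length: the 100 successive differences split 50/50 in sign,
        # so their population SD is exactly |a-b|/sqrt(2)
        a, b = 0.7, 0.9
        x = np.resize([a, b], 101)
        sd1, sd2 = poincare_descriptors(x)
        assert sd1 == pytest.approx(abs(a - b) / math.sqrt(2), rel=1e-12)
        assert sd2 == pytest.approx(0.0, abs=1e-12)

    def test_sd1_identity_oracle(self):
        # SD1^2 == Var(successive differences) / 2 (population), closed form
        rng = np.random.default_rng(5)
        x = make_rr_like(rng, 300)
        sd1, _ = poincare_descriptors(x)
        var_diff = np.mean((np.diff(x) - np.diff(x).mean()) ** 2)
        assert sd1**2 == pytest.approx(var_diff / 2, rel=1e-12)

    def test_total_variance_rotation_invariant(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = make_rr_like(rng, rng.integers(10, 200))
            sd1, sd2 = poincare_descriptors(x)
            a, b = x[:-1], x[1:]
            total = np.var(a) + np.var(b)
            assert sd1**2 + sd2**2 == pytest.approx(total, rel=1e-10)

    def test_too_short(self):
        with pytest.raises(DegenerateSeriesError):
            poincare_descriptors(np.array([0.8, 0.9]))


# ---------------------------------------------------------------------------
# Approximate entropy
# ---------------------------------------------------------------------------

class TestApEn:
    def test_constant_series_zero(self):
        assert approximate_entropy(np.full(60, 0.8), m=2, r=0.1) == 0.0

    def test_small_periodic_matches_oracle(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2], dtype=float)
        got = approximate_entropy(x, m=2, r=0.5)
        assert got == apen_oracle(x, 2, 0.5)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_brute_force_equivalence(self, m):
        rng = np.random.default_rng(100 + m)
        for _ in range(5):
            n = int(rng.integers(30, 120))
            x = make_rr_like(rng, n)
            r = 0.2 * sdnn(x)
            assert approximate_entropy(x, m=m, r=r) == apen_oracle(x, m, r)

    def test_periodic_apen_shrinks_with_length(self):
        # strictly periodic, r below half the amplitude: ApEn -> 0 with N
        # (finite-N values are edge effects of magnitude ~1/N)
        period = np.array([0.7, 0.8, 0.9, 0.8])
        values = [abs(approximate_entropy(np.resize(period, n), m=2, r=0.05))
                  for n in (50, 100, 200)]
        assert values[0] > values[2]
        assert values[2] < 1e-3

    def test_invalid_r(self):
        with pytest.raises(ValidationError):
            approximate_entropy(np.full(30, 0.8), m=2, r=0.0)

    def test_too_short(self):
        with pytest.raises(DegenerateSeriesError):
            approximate_entropy(np.array([0.8, 0.9, 0.7]), m=2, r=0.1)


class TestChonThreshold:
    def test_direct_substitution_unit_ratio(self):
        # SDDS/SDNN = 1 at N = 1000 -> -0.036 + 0.26 = 0.224
        # engineered: alternating +/- pattern has SDDS = 2*SDNN; instead
        # verify via the formula on synthetic stats using a stub series is
        # impossible, so check the algebra through a crafted series below
        # and the exact two-point cases through the closed form.
        rng = np.random.default_rng(0)
        x = make_rr_like(rng, 1000)
        expected = (-0.036 + 0.26 * math.sqrt(sdds(x) / sdnn(x)))
        expected /= (len(x) / 1000.0) ** 0.25
        assert chon_threshold(x) == pytest.approx(expected, rel=1e-12)

    def test_formula_values(self):
        # closed-form spot checks of the algebra used by chon_threshold
        assert -0.036 + 0.26 * math.sqrt(1.0) == pytest.approx(0.224)
        assert -0.036 + 0.26 * math.sqrt(4.0) == pytest.approx(0.484)

    def test_two_pass_oracle_ar1(self):
        rng = np.random.default_rng(42)
        x = np.empty(300)
        x[0] = 0.8
        for i in range(1, 300):
            x[i] = 0.8 + 0.5 * (x[i - 1] - 0.8) + 0.02 * rng.standard_normal()
        n = len(x)
        mean = sum(x) / n
        sd_nn = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
        d = [x[i + 1] - x[i] for i in range(n - 1)]
        dmean = sum(d) / len(d)
        sd_ds = math.sqrt(sum((v - dmean) ** 2 for v in d) / len(d))
        expected = (-0.036 + 0.26 * math.sqrt(sd_ds / sd_nn)) / (n / 1000) ** 0.25
        assert chon_threshold(x) == pytest.approx(expected, rel=1e-12)

    def test_constant_series_raises(self):
        with pytest.raises(DegenerateSeriesError):
            chon_threshold(np.full(100, 0.8))


class TestMaxEntropyThreshold:
    def test_dominates_grid_member(self):
        rng = np.random.default_rng(7)
        x = make_rr_like(rng, 200)
        r_max, en_rmax = max_entropy_threshold(x)
        sd = sdnn(x)
        assert 0.1 * sd <= r_max <= 0.9 * sd
        en_02 = approximate_entropy(x, m=2, r=0.2 * sd)
        assert en_rmax >= en_02  # 0.2*SDNN is on the 81-point grid

    def test_refined_grid_argmax_within_one_step(self):
        rng = np.random.default_rng(8)
        x = make_rr_like(rng, 250)
        sd = sdnn(x)
        r_max, _ = max_entropy_threshold(x)
        fine = sd * np.linspace(0.1, 0.9, 801)
        _, fine_values = entropy_profile(x, m=2, radii=fine)
        fine_argmax = fine[int(np.argmax(fine_values))]
        coarse_step = 0.01 * sd
        assert abs(r_max - fine_argmax) <= coarse_step + 1e-15

    def test_constant_series_raises(self):
        with pytest.raises(DegenerateSeriesError):
            max_entropy_threshold(np.full(50, 0.8))

    def test_profile_matches_pointwise_apen(self):
        rng = np.random.default_rng(9)
        x = make_rr_like(rng, 150)
        radii, values = entropy_profile(x, m=2)
        for k in (0, 10, 40, 80):
            assert values[k] == approximate_entropy(x, m=2, r=radii[k])

    def test_apen_decays_past_its_maximum(self):
        # monotone decrease in r is not a theorem (the profile peaks inside
        # the grid); what holds is decay after the argmax, up to small bumps
        rng = np.random.default_rng(12)
        for _ in range(5):
            x = make_rr_like(rng, 200)
            _, values = entropy_profile(x, m=2)
            k = int(np.argmax(values))
            assert np.all(np.diff(values[k:]) <= 0.02)
            assert values[-1] < 0.8 * values[k]


# ---------------------------------------------------------------------------
# Correlation dimension
# ---------------------------------------------------------------------------

class TestCorrelationDimension:
    def test_identical_vectors_zero(self):
        assert correlation_dimension(np.full(60, 0.8), m=10) == 0.0

    def test_line_segment_dimension_one(self):
        rng = np.random.default_rng(21)
        estimates = []
        for _ in range(5):
            # points uniform on a 1-D curve through embedding space
            x = np.cumsum(np.full(600, 0.001)) + 0.7
            x = x + 1e-6 * rng.standard_normal(600)  # break exact ties
            estimates.append(correlation_dimension(x, m=10))
        assert 0.8 <= np.mean(estimates) <= 1.2

    def test_correlation_sum_brute_force(self):
        rng = np.random.default_rng(22)
        x = make_rr_like(rng, 120)
        m = 10
        d = _euclidean_distances(x, m)
        k = d.shape[0]
        radii = np.geomspace(d[d > 0].min(), d.max(), 20)
        got = correlation_sum(d, radii)
        # O(N^2) explicit pair count
        emb = np.array([x[i:i + m] for i in range(k)])
        for idx, r in enumerate(radii):
            count = 0
            for i in range(k):
                for j in range(k):
                    dist = math.sqrt(sum((emb[i][t] - emb[j][t]) ** 2
                                         for t in range(m)))
                    if dist <= r:
                        count += 1
            assert got[idx] == count / (k * k)

    def test_nonnegative_clip(self):
        rng = np.random.default_rng(23)
        x = make_rr_like(rng, 150)
        assert correlation_dimension(x, m=10) >= 0.0

    def test_fit_metadata(self):
        rng = np.random.default_rng(24)
        x = make_rr_like(rng, 150)
        d2, info = correlation_dimension(x, m=10, return_fit=True)
        assert info["fit_range"][0] < info["fit_range"][1]
        assert len(info["radii"]) >= 3


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------

class TestDFA:
    def test_constant_series_raises(self):
        with pytest.raises(EstimationError):
            detrended_fluctuation(np.full(200, 0.8))

    def test_white_noise_alpha_half(self):
        rng = np.random.default_rng(30)
        alphas = [detrended_fluctuation(rng.standard_normal(4000)).alpha1
                  for _ in range(10)]
        assert abs(np.mean(alphas) - 0.5) < 0.1

    def test_integrated_noise_alpha_three_halves(self):
        rng = np.random.default_rng(31)
        alphas = [detrended_fluctuation(
            np.cumsum(rng.standard_normal(4000))).alpha1 for _ in range(10)]
        assert abs(np.mean(alphas) - 1.5) < 0.1

    def test_fluctuations_match_per_segment_polyfit(self):
        rng = np.random.default_rng(32)
        x = make_rr_like(rng, 500)
        profile = detrended_fluctuation(x)
        y = np.cumsum(x - x.mean())
        for n, f in zip(profile.box_sizes[:6], profile.fluctuations[:6]):
            k = len(x) // n
            sq = 0.0
            for seg in range(k):
                ys = y[seg * n:(seg + 1) * n]
                t = np.arange(n, dtype=float)
                coef = np.polyfit(t, ys, 1)
                sq += float(np.sum((ys - np.polyval(coef, t)) ** 2))
            assert f == pytest.approx(math.sqrt(sq / (k * n)), rel=1e-10)

    def test_box_sizes_cover_4_to_64(self):
        rng = np.random.default_rng(33)
        profile = detrended_fluctuation(make_rr_like(rng, 300))
        assert profile.box_sizes[0] == 4
        assert profile.box_sizes[-1] == 64
        assert np.all(np.diff(profile.box_sizes) > 0)
        assert np.all(profile.fluctuations > 0)


# ---------------------------------------------------------------------------
# Recurrence plot
# ---------------------------------------------------------------------------

class TestRecurrence:
    def test_constant_series_fully_recurrent(self):
        x = np.full(80, 0.8)
        structure, measures = recurrence_measures(x, m=10, tau=1, r=0.05)
        k = structure.matrix.shape[0]
        assert structure.matrix.all()
        assert measures.rec == 1.0
        assert measures.l_max == k - 1  # longest off-main-diagonal line
        # under off-diagonal line counting with the full-matrix denominator
        assert measures.det == pytest.approx((k * k - k - 2) / k**2)

    def test_only_self_recurrence(self):
        # strictly increasing with huge steps: all off-diagonal distances > r
        x = np.linspace(1.0, 100.0, 40)
        structure, measures = recurrence_measures(x, m=10, tau=1, r=1e-6)
        k = structure.matrix.shape[0]
        assert measures.rec == pytest.approx(k / k**2)
        assert measures.det == 0.0
        assert measures.no_lines

    def test_matrix_walk_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(5):
            x = make_rr_like(rng, 80)
            structure, measures = recurrence_measures(x, m=10, tau=1)
            rec, det, shen, l_mean, l_max = rqa_oracle(structure.matrix)
            assert measures.rec == rec
            assert measures.det == det
            assert measures.shen == shen
            assert measures.l_mean == l_mean
            assert measures.l_max == l_max

    def test_matrix_properties(self):
        rng = np.random.default_rng(56)
        x = make_rr_like(rng, 60)
        structure, measures = recurrence_measures(x, m=10, tau=1)
        mat = structure.matrix
        assert mat.shape[0] == 60 - 9
        assert np.array_equal(mat, mat.T)
        assert np.all(np.diagonal(mat))
        assert measures.rec >= 1.0 / mat.shape[0]
        if not measures.no_lines:
            assert measures.l_max >= measures.l_mean >= 2

    def test_equality_maps_to_zero(self):
        # d == r must be non-recurrent (strict less-than)
        x = np.tile([0.0, 1.0], 20)
        d = _euclidean_distances(x, 2)
        r = float(np.unique(d)[1])  # an attained positive distance
        structure, _ = recurrence_measures(x, m=2, tau=1, r=r)
        assert not structure.matrix[d == r].any()

    def test_radius_modes(self):
        rng = np.random.default_rng(57)
        x = make_rr_like(rng, 100)
        _, lit = recurrence_measures(x, m=10, tau=1, radius_mode="literal")
        _, sq = recurrence_measures(x, m=10, tau=1, radius_mode="sqrt_m")
        assert lit.rec >= sq.rec
        # the literal m*SDNN radius saturates the plot
        assert lit.rec > 0.99

    def test_derived_radius_on_constant_series_raises(self):
        with pytest.raises(DegenerateSeriesError):
            recurrence_measures(np.full(60, 0.8), m=10, tau=1)


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def rest_nn():
    from hrvstress import SyntheticParams, generate_session
    return to_nn(generate_session(SyntheticParams(seed=1), 0, "rest"))


class TestExtractAll:
    def test_all_fields_finite(self, rest_nn):
        vector = extract_all_features(rest_nn)
        values = vector.as_dict()
        assert len(values) == 13
        assert all(np.isfinite(v) for v in values.values())
        assert 0 <= values["REC"] <= 1
        assert 0 <= values["DET"] <= 1
        assert values["SD1"] >= 0 and values["SD2"] >= 0

    def test_deterministic(self, rest_nn):
        v1 = extract_all_features(rest_nn)
        v2 = extract_all_features(rest_nn)
        assert v1.as_dict() == v2.as_dict()

    def test_error_carries_feature_name(self):
        with pytest.raises(DegenerateSeriesError, match="SDNN"):
            extract_all_features(np.full(100, 0.8))

    def test_nn_filtering_commutes(self, rest_nn):
        # appending then removing a non-normal beat leaves features unchanged
        base = extract_all_features(rest_nn)
        intervals = np.append(rest_nn.intervals, 1.3)
        labels = np.array(["N"] * len(rest_nn) + ["V"], dtype=object)
        rr = RRSeries(intervals, labels, subject_id=rest_nn.subject_id,
                      session=rest_nn.session)
        again = extract_all_features(to_nn(rr))
        assert base.as_dict() == again.as_dict()

    def test_metadata_records_tolerances(self, rest_nn):
        vector = extract_all_features(rest_nn)
        assert vector.meta["rp_radius_mode"] == "sqrt_m"
        assert vector.meta["r_chon_abs"] == pytest.approx(
            vector.meta["r_chon"] * sdnn(rest_nn.intervals))
        assert vector.meta["d2_fit_range"][0] > 0
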