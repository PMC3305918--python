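"""The 13 nonlinear HRV measures computed from an NN-interval series.

Measures (canonical output names in parentheses):

* Poincaré plot descriptors SD1, SD2 (``SD1``, ``SD2``)
* Approximate entropy at three tolerances: ``En02`` (r = 0.2·SDNN),
  ``EnRmax`` (entropy-maximising r on a grid over (0.1·SDNN, 0.9·SDNN)) and
  ``EnRchon`` (Chon's data-driven tolerance)
* Correlation dimension ``D2`` (embedding dimension 10)
* Detrended fluctuation analysis slopes ``alpha1`` (n in 4–16) and
  ``alpha2`` (n in 16–64)
* Recurrence-plot measures ``REC``, ``DET``, ``ShEn``, ``lmean``, ``lmax``
  (embedding dimension 10, lag 1)

Conventions applied throughout: standard deviations are population
(divide-by-N) so the closed-form Poincaré identities hold exactly; REC and
DET are fractions in [0, 1]; ShEn uses natural logarithm of line-length
fractions, negated to be non-negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateSeriesError, EstimationError, ValidationError
from .rr_io import NNSeries

FEATURE_NAMES = [
    "SD1", "SD2", "En02", "EnRmax", "EnRchon", "D2",
    "alpha1", "alpha2", "lmean", "lmax", "REC", "DET", "ShEn",
]

#: number of tolerance grid points for the entropy-maximising search
RMAX_GRID_POINTS = 81

RadiusMode = Literal["sqrt_m", "literal"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, NNSeries):
        return np.asarray(x.intervals, dtype=float)
    return np.asarray(x, dtype=float)


def sdnn(x) -> float:
    """Population standard deviation of the series."""
    return float(np.std(_as_array(x)))


def sdds(x) -> float:
    """Population standard deviation of the first-difference sequence."""
    return float(np.std(np.diff(_as_array(x))))


def _sdnn_positive(x: np.ndarray) -> float:
    """SDNN, raising on a (numerically) constant series.

    np.std of a constant array can return ~1e-16 from mean rounding, so the
    degeneracy test is relative to the series magnitude.
    """
    sd = float(np.std(x))
    if sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        raise DegenerateSeriesError("SDNN ~ 0: series has no variability")
    return sd


# ---------------------------------------------------------------------------
# Poincaré plot
# ---------------------------------------------------------------------------

def poincare_descriptors(nn) -> tuple[float, float]:
    """SD1 and SD2 of the lag-1 Poincaré cloud (rotated-coordinate form).

    SD1 is the population standard deviation of (RR_{j+1} - RR_j)/sqrt(2)
    (spread perpendicular to the line of identity); SD2 of
    (RR_{j+1} + RR_j)/sqrt(2) about its mean (spread along it).  This is
    the closed form equivalent to fitting an identity-oriented ellipse.
    """
    x = _as_array(nn)
    if len(x) < 3:
        raise DegenerateSeriesError("Poincaré descriptors need length >= 3")
    a, b = x[:-1], x[1:]
    sd1 = float(np.std((b - a) / math.sqrt(2.0)))
    sd2 = float(np.std((b + a) / math.sqrt(2.0)))
    return sd1, sd2


# ---------------------------------------------------------------------------
# Approximate entropy
# ---------------------------------------------------------------------------

def _chebyshev_distances(x: np.ndarray, m: int) -> np.ndarray:
    """(N-m+1) x (N-m+1) max-absolute-component template distances."""
    emb = sliding_window_view(x, m)
    return np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)


def _phi_from_distances(d: np.ndarray, r: float) -> float:
    """Mean log of per-template match fractions; self-matches included."""
    n = d.shape[0]
    counts = np.count_nonzero(d <= r, axis=1)
    if np.any(counts == 0):  # impossible with self-matches
        raise EstimationError("internal: zero template-match count")
    return float(np.mean(np.log(counts / n)))


def approximate_entropy(nn, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r, N) = Phi^m(r) - Phi^{m+1}(r).

    Template distances are max-absolute-component; the match condition is
    d <= r and self-matches are included, so every count is positive.
    """
    x = _as_array(nn)
    if r is None:
        raise ValidationError("r must be provided")
    if r <= 0:
        raise ValidationError(f"tolerance r must be > 0, got {r}")
    if len(x) < m + 2:
        raise DegenerateSeriesError(f"ApEn(m={m}) needs N >= {m + 2}")
    phi_m = _phi_from_distances(_chebyshev_distances(x, m), r)
    phi_m1 = _phi_from_distances(_chebyshev_distances(x, m + 1), r)
    return phi_m - phi_m1


def chon_threshold(nn) -> float:
    """Chon's automatic ApEn tolerance coefficient.

    r_chon = (-0.036 + 0.26 * sqrt(SDDS / SDNN)) / (N / 1000) ** 0.25

    where SDDS is the standard deviation of the first-difference sequence
    and SDNN that of the series itself (both population).  Like the fixed
    0.2 coefficient, the value is a multiplier of SDNN: the entropy is
    evaluated at tolerance ``r_chon * SDNN`` (an absolute tolerance of
    ~0.2 s would exceed the variability of any RR series and force the
    entropy to 0).
    """
    x = _as_array(nn)
    if len(x) < 2:
        raise DegenerateSeriesError("Chon threshold needs N >= 2")
    sd_nn = _sdnn_positive(x)
    sd_ds = sdds(x)
    n = len(x)
    return (-0.036 + 0.26 * math.sqrt(sd_ds / sd_nn)) / (n / 1000.0) ** 0.25


def entropy_profile(nn, m: int = 2,
                    radii: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """ApEn evaluated over a grid of tolerances, sharing distance matrices.

    Returns ``(radii, apen_values)``.  When ``radii`` is None the default
    81-point grid over [0.1*SDNN, 0.9*SDNN] (step 0.01*SDNN) is used.
    Values are bit-identical to calling :func:`approximate_entropy` per r.
    """
    x = _as_array(nn)
    if len(x) < m + 2:
        raise DegenerateSeriesError(f"ApEn(m={m}) needs N >= {m + 2}")
    if radii is None:
        sd = _sdnn_positive(x)
        radii = sd * np.linspace(0.1, 0.9, RMAX_GRID_POINTS)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValidationError("all grid tolerances must be > 0")
    d_m = _chebyshev_distances(x, m)
    d_m1 = _chebyshev_distances(x, m + 1)
    values = np.empty(len(radii))
    for k, r in enumerate(radii):
        values[k] = _phi_from_distances(d_m, r) - _phi_from_distances(d_m1, r)
    return radii, values


def max_entropy_threshold(nn, m: int = 2) -> tuple[float, float]:
    """Tolerance maximising ApEn over the default grid, and the maximum.

    The grid spans [0.1*SDNN, 0.9*SDNN] in steps of 0.01*SDNN (81 points);
    ties are broken toward the smaller tolerance.
    """
    radii, values = entropy_profile(nn, m=m)
    k = int(np.argmax(values))  # argmax returns the first (smallest-r) maximum
    return float(radii[k]), float(values[k])


# ---------------------------------------------------------------------------
# Correlation dimension
# ---------------------------------------------------------------------------

def _euclidean_distances(x: np.ndarray, m: int, tau: int = 1) -> np.ndarray:
    emb = sliding_window_view(x, (m - 1) * tau + 1)[:, ::tau]
    diff = emb[:, None, :] - emb[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def correlation_sum(d: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """C^m(r): mean over templates of the fraction of templates within r.

    Self-matches are included (d(i,i) = 0 <= r), matching the averaged
    per-template count definition.
    """
    n = d.shape[0]
    out = np.empty(len(radii))
    for k, r in enumerate(radii):
        out[k] = np.count_nonzero(d <= r) / (n * n)
    return out


def correlation_dimension(nn, m: int = 10, n_radii: int = 50,
                          return_fit: bool = False):
    """Correlation dimension D2: slope of log C^m(r) versus log r.

    The radius grid is 50 log-spaced values between the 1st and 99th
    percentiles of the pairwise template distances; the regression is
    restricted to the widest contiguous run of radii with
    C^m(r) in (1/K^2, 0.95).  The slope is clipped at 0.
    """
    x = _as_array(nn)
    if len(x) < m + 10:
        raise DegenerateSeriesError(f"D2(m={m}) needs N >= {m + 10}")
    d = _euclidean_distances(x, m)
    k_templates = d.shape[0]
    iu = np.triu_indices(k_templates, k=1)
    pairwise = d[iu]
    if pairwise.max() == 0.0:
        # all embedded vectors identical: C(r) = 1 for every r, slope 0
        return (0.0, {"radii": None, "fit_range": None}) if return_fit else 0.0
    lo, hi = np.percentile(pairwise, [1.0, 99.0])
    smallest_positive = pairwise[pairwise > 0].min()
    lo = max(lo, smallest_positive)
    radii = np.geomspace(lo, hi, n_radii)
    c = correlation_sum(d, radii)
    usable = (c > 1.0 / k_templates**2) & (c < 0.95)
    start, length = _widest_true_run(usable)
    if length < 3:
        raise EstimationError(
            "correlation dimension: fewer than 3 usable (log r, log C) points"
        )
    sel = slice(start, start + length)
    slope = float(np.polyfit(np.log(radii[sel]), np.log(c[sel]), 1)[0])
    d2 = max(slope, 0.0)
    if return_fit:
        return d2, {
            "radii": radii[sel],
            "correlation_sums": c[sel],
            "fit_range": (float(radii[sel][0]), float(radii[sel][-1])),
        }
    return d2


def _widest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest contiguous run of True."""
    best_start = best_len = 0
    start = None
    for i, flag in enumerate(list(mask) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
    return best_start, best_len


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DFAProfile:
    """Fluctuation function F(n) with the two scaling slopes."""

    box_sizes: np.ndarray
    fluctuations: np.ndarray
    alpha1: float  # slope of log F vs log n for n in [4, 16]
    alpha2: float  # slope of log F vs log n for n in [16, 64]


def detrended_fluctuation(nn, n_min: int = 4, n_max: int = 64,
                          alpha1_range: tuple[int, int] = (4, 16),
                          alpha2_range: tuple[int, int] = (16, 64)) -> DFAProfile:
    """Detrended fluctuation analysis of the series.

    The mean-subtracted series is integrated; for each box size n the
    integrated profile is split into floor(N/n) non-overlapping boxes
    (trailing remainder dropped), a least-squares line is removed per box
    and F(n) is the RMS of the residuals over the covered samples.  alpha1
    and alpha2 are log-log regression slopes over the stated n ranges
    (n = 16 belongs to both).
    """
    x = _as_array(nn)
    n_samples = len(x)
    if n_samples < 2 * n_min:
        raise DegenerateSeriesError(f"DFA needs N >= {2 * n_min}")
    y = np.cumsum(x - x.mean())
    box_sizes = np.array([n for n in range(n_min, n_max + 1) if n_samples // n >= 1])
    fluctuations = np.empty(len(box_sizes), dtype=float)
    for idx, n in enumerate(box_sizes):
        n_boxes = n_samples // n
        segments = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n, dtype=float)
        design = np.vstack([t, np.ones(n)]).T
        # one shared pseudoinverse: identical design in every box
        coef, *_ = np.linalg.lstsq(design, segments.T, rcond=None)
        residuals = segments.T - design @ coef
        f = math.sqrt(float(np.mean(residuals * residuals)))
        if f == 0.0:
            raise EstimationError(f"DFA: F(n) = 0 at box size n = {n}")
        fluctuations[idx] = f

    def _slope(lo: int, hi: int) -> float:
        sel = (box_sizes >= lo) & (box_sizes <= hi)
        if sel.sum() < 2:
            raise EstimationError(f"DFA: fewer than 2 box sizes in [{lo}, {hi}]")
        return float(np.polyfit(np.log(box_sizes[sel]),
                                np.log(fluctuations[sel]), 1)[0])

    alpha1 = _slope(*alpha1_range)
    alpha2 = _slope(*alpha2_range)
    return DFAProfile(box_sizes, fluctuations, alpha1, alpha2)


# ---------------------------------------------------------------------------
# Recurrence plot
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecurrenceStructure:
    """Binary recurrence matrix with its diagonal-line-length histogram."""

    embedding_dim: int
    lag: int
    radius: float
    matrix: np.ndarray  # K x K boolean, symmetric, True on the main diagonal
    line_histogram: dict[int, int]  # length -> count, off-diagonal, l >= 2


def recurrence_radius(x, m: int = 10,
                      radius_mode: RadiusMode = "sqrt_m") -> float:
    """Default RP threshold: sqrt(m)*SDNN (``sqrt_m``) or m*SDNN (``literal``).

    ``literal`` follows the printed parameter choice verbatim; with m = 10
    it makes essentially every template pair recurrent (REC ~ 1), so the
    conventional ``sqrt_m`` scaling is the default.  The mode used is
    recorded in the run log by the pipeline.
    """
    sd = _sdnn_positive(x)
    if radius_mode == "sqrt_m":
        return math.sqrt(m) * sd
    if radius_mode == "literal":
        return m * sd
    raise ValidationError(f"unknown radius_mode {radius_mode!r}")


@dataclass(frozen=True)
class RecurrenceMeasures:
    rec: float     # recurrence rate, fraction of the full K x K matrix
    det: float     # determinism, fraction of recurrent points on lines
    shen: float    # Shannon entropy of the line-length distribution (nats)
    l_mean: float  # mean diagonal line length (beats)
    l_max: int     # maximum diagonal line length (beats)
    no_lines: bool = False  # True when no off-diagonal line of length >= 2


def recurrence_measures(
    nn, m: int = 10, tau: int = 1, r: float | None = None,
    radius_mode: RadiusMode = "sqrt_m", l_min: int = 2,
) -> tuple[RecurrenceStructure, RecurrenceMeasures]:
    """Recurrence-plot quantification of the embedded series.

    The K x K matrix (K = N - (m-1)*tau) thresholds Euclidean template
    distances strictly below ``r`` (d = r maps to 0).  REC averages the full
    matrix, main diagonal included.  Diagonal lines are maximal runs of
    recurrent points off the main diagonal with length >= ``l_min``; DET is
    their point count over the full-matrix sum, ShEn the negated natural
    entropy of the line-length fractions.
    """
    x = _as_array(nn)
    if tau < 1 or m < 1:
        raise ValidationError("m and tau must be >= 1")
    if len(x) < (m - 1) * tau + 10:
        raise DegenerateSeriesError(
            f"recurrence analysis needs N >= {(m - 1) * tau + 10}"
        )
    if r is None:
        r = recurrence_radius(x, m=m, radius_mode=radius_mode)
    if r <= 0:
        raise ValidationError("recurrence radius must be > 0")
    d = _euclidean_distances(x, m, tau)
    matrix = d < r
    k = matrix.shape[0]
    rec = float(np.count_nonzero(matrix)) / (k * k)

    histogram: dict[int, int] = {}
    for offset in range(1, k):
        for run in _run_lengths(np.diagonal(matrix, offset)):
            if run >= l_min:
                # symmetric matrix: the mirrored diagonal holds the same line
                histogram[run] = histogram.get(run, 0) + 2

    structure = RecurrenceStructure(m, tau, float(r), matrix, histogram)
    if not histogram:
        warnings.warn("recurrence plot has no diagonal line of length "
                      f">= {l_min}; DET/ShEn/l statistics reported as 0",
                      stacklevel=2)
        return structure, RecurrenceMeasures(rec, 0.0, 0.0, 0.0, 0, True)

    lengths = np.array(sorted(histogram))
    counts = np.array([histogram[l] for l in lengths], dtype=float)
    points_on_lines = float(np.sum(lengths * counts))
    det = points_on_lines / float(np.count_nonzero(matrix))
    l_mean = points_on_lines / counts.sum()
    l_max = int(lengths.max())
    fractions = counts / counts.sum()
    shen = float(-np.sum(fractions * np.log(fractions)))
    return structure, RecurrenceMeasures(rec, det, shen, l_mean, l_max)


def _run_lengths(flags: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    padded = np.concatenate([[0], flags.astype(np.int8), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return (ends - starts).tolist()


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureVector:
    """The 13 nonlinear measures for one record."""

    sd1: float
    sd2: float
    en_02: float
    en_rmax: float
    en_rchon: float
    d2: float
    alpha1: float
    alpha2: float
    l_mean: float
    l_max: float
    rec: float
    det: float
    shen: float
    subject_id: str = ""
    session: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def as_dict(self) -> dict[str, float]:
        """Feature values keyed by the canonical output names."""
        return {
            "SD1": self.sd1, "SD2": self.sd2, "En02": self.en_02,
            "EnRmax": self.en_rmax, "EnRchon": self.en_rchon, "D2": self.d2,
            "alpha1": self.alpha1, "alpha2": self.alpha2,
            "lmean": self.l_mean, "lmax": self.l_max,
            "REC": self.rec, "DET": self.det, "ShEn": self.shen,
        }


def extract_all_features(
    nn, entropy_m: int = 2, d2_m: int = 10, rp_m: int = 10, rp_tau: int = 1,
    rp_radius_mode: RadiusMode = "sqrt_m",
) -> FeatureVector:
    """Compute all 13 measures with the study's default parameters.

    Deterministic for a fixed input; any component failure is re-raised
    with the feature name attached.
    """
    x = _as_array(nn)
    subject_id = getattr(nn, "subject_id", "")
    session = getattr(nn, "session", "")
    meta: dict = {"rp_radius_mode": rp_radius_mode}

    def _step(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise type(exc)(f"{name}: {exc}") from exc

    sd1, sd2 = _step("SD1/SD2", lambda: poincare_descriptors(x))
    sd = _sdnn_positive(x)
    en_02 = _step("En02",
                  lambda: approximate_entropy(x, m=entropy_m, r=0.2 * sd))
    r_max, en_rmax = _step("EnRmax",
                           lambda: max_entropy_threshold(x, m=entropy_m))
    r_chon = _step("EnRchon", lambda: chon_threshold(x))
    if r_chon <= 0:
        raise ValidationError(
            f"EnRchon: Chon tolerance coefficient {r_chon:.4g} is not positive"
        )
    en_rchon = _step("EnRchon",
                     lambda: approximate_entropy(x, m=entropy_m, r=r_chon * sd))
    d2_value, d2_fit = _step("D2",
                             lambda: correlation_dimension(x, m=d2_m,
                                                           return_fit=True))
    profile = _step("alpha1/alpha2", lambda: detrended_fluctuation(x))
    _, rqa = _step("RP", lambda: recurrence_measures(
        x, m=rp_m, tau=rp_tau, radius_mode=rp_radius_mode))
    meta.update({
        "r_02": 0.2 * sd, "r_max": r_max, "r_chon": r_chon,
        "r_chon_abs": r_chon * sd,
        "d2_fit_range": d2_fit["fit_range"],
        "rp_no_lines": rqa.no_lines,
    })
    return FeatureVector(
        sd1=sd1, sd2=sd2, en_02=en_02, en_rmax=en_rmax, en_rchon=en_rchon,
        d2=d2_value, alpha1=profile.alpha1, alpha2=profile.alpha2,
        l_mean=rqa.l_mean, l_max=float(rqa.l_max), rec=rqa.rec, det=rqa.det,
        shen=rqa.shen, subject_id=subject_id, session=session, meta=meta,
    )
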