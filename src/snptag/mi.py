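"""B-spline mutual-information estimation between variant vectors.

Genotype vectors are tri-level (0/1/2) and the metaSNP consensus profile is
continuous, so mutual information is estimated with B-spline soft binning:
each observation is distributed over ``num_bins`` bins according to the
B-spline basis functions of order ``spline_order`` evaluated at its min-max
rescaled value.  With ``spline_order = 1`` this reduces to ordinary histogram
(indicator) binning; with order 2 every observation is shared by at most two
adjacent bins, which smooths the estimate for continuous arguments.

The similarity metric used by the attractor iteration is ``J = I**alpha``
where ``I`` is the normalized mutual information and ``alpha`` a nonnegative
exponent that sharpens the metric by pushing weak associations toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.special import xlogy

from .errors import InvalidInputError

__all__ = [
    "SimilarityConfig",
    "bin_weight_profile",
    "effective_entropy",
    "entropy",
    "mutual_information",
    "normalized_mi",
    "similarity",
]


@dataclass(frozen=True)
class SimilarityConfig:
    """Parameters of the B-spline MI estimator and the similarity exponent.

    Parameters
    ----------
    alpha
        Nonnegative exponent applied to the normalized MI; larger values
        sharpen the similarity metric (default 5, the main-scan setting).
    num_bins
        Number of soft bins (default 4, enough to resolve tri-level data).
    spline_order
        B-spline order; order 2 spreads each value over at most two bins.
    log_base
        Base of the logarithm; 2 gives entropies and MI in bits.
    normalization
        ``"min"`` divides raw MI by ``min(H(x), H(y))`` (guarantees
        ``I(x, x) = 1``); ``"sqrt"`` divides by ``sqrt(H(x) * H(y))``.
    """

    alpha: float = 5.0
    num_bins: int = 4
    spline_order: int = 2
    log_base: float = 2.0
    normalization: str = "min"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise InvalidInputError("alpha must be nonnegative")
        if self.num_bins < 1 or self.spline_order < 1:
            raise InvalidInputError("num_bins and spline_order must be positive")
        if self.num_bins < self.spline_order:
            raise InvalidInputError("num_bins must be >= spline_order")
        if self.log_base <= 1:
            raise InvalidInputError("log_base must exceed 1")
        if self.normalization not in ("min", "sqrt"):
            raise InvalidInputError("normalization must be 'min' or 'sqrt'")

    @property
    def domain_max(self) -> float:
        """Right edge of the spline support: bins minus degree."""
        return float(self.num_bins - self.spline_order + 1)

    def knots(self) -> np.ndarray:
        degree = self.spline_order - 1
        interior = np.arange(0.0, self.num_bins - self.spline_order + 2)
        return np.concatenate(
            [np.zeros(degree), interior, np.full(degree, self.domain_max)]
        )


DEFAULT_CONFIG = SimilarityConfig()


def _rescale(x: np.ndarray, cfg: SimilarityConfig) -> np.ndarray:
    """Min-max rescale onto the spline support; constants map to its midpoint."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full(x.shape, cfg.domain_max / 2.0)
    # clip guards round-off just past the support edge
    return np.clip((x - lo) * (cfg.domain_max / (hi - lo)), 0.0, cfg.domain_max)


def bin_weight_profile(x: np.ndarray, cfg: SimilarityConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Soft bin-membership weights of each sample.

    Returns a ``(P, num_bins)`` matrix whose row ``p`` holds the B-spline
    basis functions evaluated at the rescaled value of sample ``p``.  Rows
    sum to 1 (partition of unity on the spline support).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.size == 0:
        raise InvalidInputError("cannot bin an empty vector")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("bin_weight_profile requires finite values")
    scaled = _rescale(x, cfg)
    return BSpline.design_matrix(scaled, cfg.knots(), cfg.spline_order - 1).toarray()


def entropy_from_pmf(pmf: np.ndarray, log_base: float) -> float:
    """Shannon entropy of a (possibly multidimensional) probability array."""
    return float(-xlogy(pmf, pmf).sum() / np.log(log_base))


def entropy(profile: np.ndarray, cfg: SimilarityConfig = DEFAULT_CONFIG) -> float:
    """Entropy of the bin distribution implied by a bin-weight profile.

    The bin probability is the column mean of the profile; the result lies
    in ``[0, log(num_bins)]`` in units of ``log_base``.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 2 or profile.shape[0] == 0:
        raise InvalidInputError("profile must be a nonempty (P, num_bins) matrix")
    return max(0.0, entropy_from_pmf(profile.mean(axis=0), cfg.log_base))


def effective_entropy(profile: np.ndarray, log_base: float) -> float:
    """Self-consistent entropy ``2 H(x) - H(x, x)`` of a bin-weight profile.

    Soft binning (order >= 2) inflates the column-mean entropy because a
    single observation spreads over adjacent bins; the raw MI of a vector
    with itself equals this *effective* entropy, not the column-mean one.
    Normalizing by it makes self-similarity exactly 1.  For tri-level
    genotype data at 4 bins / order 2 it coincides with the plug-in entropy
    of the genotype frequencies (distinct genotypes occupy disjoint bin
    supports), and at order 1 with the histogram entropy for any data.
    """
    n = profile.shape[0]
    h_marg = entropy_from_pmf(profile.mean(axis=0), log_base)
    h_self = entropy_from_pmf(profile.T @ profile / n, log_base)
    return max(0.0, 2.0 * h_marg - h_self)


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size != y.size:
        raise InvalidInputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size == 0:
        raise InvalidInputError("empty input vectors")
    keep = ~(np.isnan(x) | np.isnan(y))
    if not keep.any():
        raise InvalidInputError("no pairwise-complete samples")
    return x[keep], y[keep]


def mutual_information(
    x: np.ndarray, y: np.ndarray, cfg: SimilarityConfig = DEFAULT_CONFIG
) -> float:
    """Unnormalized mutual information ``H(x) + H(y) - H(x, y)``.

    The joint bin distribution is the sample mean of the outer products of
    the two per-sample bin-weight rows.  Missing entries (NaN) restrict the
    computation to the pairwise-complete sample subset.  Small negative
    round-off is clamped to 0.
    """
    x, y = _pairwise_complete(x, y)
    px = bin_weight_profile(x, cfg)
    py = bin_weight_profile(y, cfg)
    joint = px.T @ py / x.size
    h_x = entropy_from_pmf(px.mean(axis=0), cfg.log_base)
    h_y = entropy_from_pmf(py.mean(axis=0), cfg.log_base)
    h_xy = entropy_from_pmf(joint, cfg.log_base)
    return max(0.0, h_x + h_y - h_xy)


def normalize_mi(i_raw: float, h_x: float, h_y: float, normalization: str) -> float:
    """Map raw MI and effective marginal entropies to the score in [0, 1].

    Zero-entropy arguments (monomorphic SNPs, constant metaSNPs) carry no
    diversity and are assigned similarity 0 by convention.
    """
    if h_x <= 0.0 or h_y <= 0.0:
        return 0.0
    denom = min(h_x, h_y) if normalization == "min" else float(np.sqrt(h_x * h_y))
    return float(np.clip(i_raw / denom, 0.0, 1.0))


def normalized_mi(
    x: np.ndarray, y: np.ndarray, cfg: SimilarityConfig = DEFAULT_CONFIG
) -> float:
    """Normalized mutual information in ``[0, 1]``; 1 for ``y = x`` (non-constant).

    The raw MI is divided by the minimum (or geometric mean) of the two
    *effective* entropies — see :func:`effective_entropy` — so that the
    self-similarity identity holds at every spline order.
    """
    x, y = _pairwise_complete(x, y)
    px = bin_weight_profile(x, cfg)
    py = bin_weight_profile(y, cfg)
    h_x = entropy_from_pmf(px.mean(axis=0), cfg.log_base)
    h_y = entropy_from_pmf(py.mean(axis=0), cfg.log_base)
    h_xy = entropy_from_pmf(px.T @ py / x.size, cfg.log_base)
    i_raw = max(0.0, h_x + h_y - h_xy)
    return normalize_mi(
        i_raw,
        effective_entropy(px, cfg.log_base),
        effective_entropy(py, cfg.log_base),
        cfg.normalization,
    )


def similarity(
    x: np.ndarray, y: np.ndarray, cfg: SimilarityConfig = DEFAULT_CONFIG
) -> float:
    """Similarity metric ``J = I**alpha`` with ``I`` the normalized MI."""
    return float(normalized_mi(x, y, cfg) ** cfg.alpha)


def profile_matrix(values: np.ndarray, cfg: SimilarityConfig) -> np.ndarray:
    """Per-variant bin-weight profiles for an ``(N, P)`` matrix with NaN missing.

    Rescaling is per variant over its non-missing entries; profile rows of
    missing samples are NaN.  Used by the attractor engine to amortize the
    basis evaluation across iterations.
    """
    n_var, n_samp = values.shape
    profiles = np.full((n_var, n_samp, cfg.num_bins), np.nan)
    knots = cfg.knots()
    degree = cfg.spline_order - 1
    for i in range(n_var):
        row = values[i]
        ok = ~np.isnan(row)
        if not ok.any():
            continue
        profiles[i, ok, :] = BSpline.design_matrix(
            _rescale(row[ok], cfg), knots, degree
        ).toarray()
    return profiles
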