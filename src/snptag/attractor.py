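"""Iterative attractor estimation for a single seed SNP.

Starting from a seed variant ``k``, the weight of every SNP in the window is
its similarity ``J`` to the seed; the metaSNP is the per-sample weighted
average of the windowed SNP vectors; weights are then recomputed against the
metaSNP and the two steps alternate until the squared Euclidean distance
between consecutive weight vectors drops below ``epsilon``.  On high-LD data
the iteration converges to a fixed point (the attractor) whose large weights
mark the members of the underlying haplotype block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .errors import DegenerateAttractorError, DegenerateSeedError, InvalidInputError
from .matrix import GenotypeMatrix
from .mi import (
    SimilarityConfig,
    bin_weight_profile,
    effective_entropy,
    entropy_from_pmf,
    normalize_mi,
)

__all__ = ["AttractorConfig", "AttractorResult", "compute_metasnp", "run_attractor"]


@dataclass(frozen=True)
class AttractorConfig:
    """Tuning parameters of the attractor scan.

    Defaults follow the published settings: sharp exponent ``alpha_main = 5``
    for full attractors, permissive ``alpha_prescreen = 2`` for the short
    prescreen, convergence threshold ``epsilon = 1e-7``, a 10,001-SNP main
    window and a 101-SNP short window, attractee criterion "5th-largest
    short-attractor weight >= 0.5", and strength rank ``n = 10``.
    """

    alpha_main: float = 5.0
    alpha_prescreen: float = 2.0
    epsilon: float = 1e-7
    max_iter: int = 100
    window_main: int = 10001
    window_short: int = 101
    attractee_rank: int = 5
    attractee_threshold: float = 0.5
    strength_rank: int = 10
    coalesce_seeds: bool = False
    mi: SimilarityConfig = field(default_factory=SimilarityConfig)

    def __post_init__(self) -> None:
        for w in (self.window_main, self.window_short):
            if w < 3 or w % 2 == 0:
                raise InvalidInputError("windows must be odd and >= 3")
        if not (0 < self.attractee_threshold <= 1):
            raise InvalidInputError("attractee_threshold must be in (0, 1]")
        if self.attractee_rank > self.window_short:
            raise InvalidInputError("attractee_rank cannot exceed window_short")
        if self.epsilon <= 0 or self.max_iter < 1:
            raise InvalidInputError("epsilon must be > 0 and max_iter >= 1")


@dataclass
class AttractorResult:
    """Converged attractor for one seed.

    ``weights`` aligns with ``range(*window_range)`` into the source matrix;
    ``metasnp`` is the continuous consensus vector over samples.
    """

    seed_index: int
    weights: np.ndarray
    metasnp: np.ndarray
    iterations: int
    converged: bool
    window_range: tuple[int, int]

    @property
    def window_indices(self) -> np.ndarray:
        return np.arange(self.window_range[0], self.window_range[1])


def window_bounds(center: int, width: int, n: int) -> tuple[int, int]:
    """Index interval of the ``width``-SNP window centered at ``center``,
    truncated (never wrapped) at the chromosome ends."""
    half = width // 2
    return max(0, center - half), min(n, center + half + 1)


def compute_metasnp(
    g: GenotypeMatrix, weights: np.ndarray, window: tuple[int, int]
) -> np.ndarray:
    """Weighted average of the windowed SNP vectors, per sample.

    Each sample's value is renormalized by the total weight of the SNPs
    genotyped in that sample, so missing calls neither contribute nor bias
    the scale.  A sample missing at every positively-weighted SNP has no
    defined consensus value and is an error.
    """
    weights = np.asarray(weights, dtype=np.float64)
    lo, hi = window
    if weights.shape[0] != hi - lo:
        raise InvalidInputError("weight vector does not align with the window")
    if not np.any(weights > 0):
        raise DegenerateAttractorError("all-zero weight vector")
    sub = g.values[lo:hi]
    valid = ~np.isnan(sub)
    numer = weights @ np.where(valid, sub, 0.0)
    denom = weights @ valid
    if np.any(denom <= 0):
        raise DegenerateAttractorError(
            "a sample is missing at every SNP with positive weight"
        )
    return numer / denom


def _metasnp_profile(
    meta: np.ndarray, cfg: SimilarityConfig
) -> tuple[np.ndarray, float, float]:
    prof = bin_weight_profile(meta, cfg)
    h_marg = max(0.0, entropy_from_pmf(prof.mean(axis=0), cfg.log_base))
    return prof, h_marg, effective_entropy(prof, cfg.log_base)


def _weights_against_meta(
    g: GenotypeMatrix,
    window: tuple[int, int],
    meta: np.ndarray,
    alpha: float,
    cfg: SimilarityConfig,
) -> np.ndarray:
    """Similarity of every windowed SNP to the metaSNP, vectorized.

    Complete (no-missing) variants share one batched matrix product; variants
    with missing calls are handled individually on their pairwise-complete
    sample subsets.  Normalization uses the effective (self-MI) entropies.
    """
    lo, hi = window
    cache = g.profiles(cfg)
    mprof, h_meta, h_meta_eff = _metasnp_profile(meta, cfg)
    n_samp = g.num_samples
    n_bins = cfg.num_bins
    log_b = np.log(cfg.log_base)

    w = np.zeros(hi - lo)
    row_missing = cache.row_has_missing[lo:hi]
    complete = ~row_missing
    if complete.any():
        flat = cache.profiles_flat[lo * n_bins : hi * n_bins]
        joint = (flat @ mprof).reshape(hi - lo, n_bins * n_bins) / n_samp
        with np.errstate(invalid="ignore"):
            h_joint = -xlogy(joint, joint).sum(axis=1) / log_b
        h_joint = h_joint[complete]
        h_x = cache.marginal_entropy[lo:hi][complete]
        i_raw = np.maximum(0.0, h_x + h_meta - h_joint)
        hx_eff = cache.effective_entropy[lo:hi][complete]
        if cfg.normalization == "min":
            denom = np.minimum(hx_eff, h_meta_eff)
        else:
            denom = np.sqrt(hx_eff * h_meta_eff)
        nmi = np.zeros_like(i_raw)
        ok = (hx_eff > 0) & (h_meta_eff > 0)
        nmi[ok] = np.clip(i_raw[ok] / denom[ok], 0.0, 1.0)
        w[complete] = nmi**alpha
    prof = cache.profiles
    for local_i in np.nonzero(row_missing)[0]:
        i = lo + local_i
        keep = ~np.isnan(g.values[i])
        if not keep.any():
            continue
        px = prof[i][keep]
        py = mprof[keep]
        n = keep.sum()
        h_x = max(0.0, entropy_from_pmf(px.mean(axis=0), cfg.log_base))
        h_y = max(0.0, entropy_from_pmf(py.mean(axis=0), cfg.log_base))
        h_xy = entropy_from_pmf(px.T @ py / n, cfg.log_base)
        i_raw = max(0.0, h_x + h_y - h_xy)
        w[local_i] = (
            normalize_mi(
                i_raw,
                effective_entropy(px, cfg.log_base),
                effective_entropy(py, cfg.log_base),
                cfg.normalization,
            )
            ** alpha
        )
    return w


def run_attractor(
    g: GenotypeMatrix,
    seed: int,
    window: tuple[int, int],
    cfg: AttractorConfig,
    alpha: float | None = None,
) -> AttractorResult:
    """Iterate seed -> metaSNP -> weights to convergence within a window.

    ``alpha`` overrides the similarity exponent (the scan uses
    ``alpha_prescreen`` for short windows and ``alpha_main`` for full ones).
    The iteration is fully deterministic.  Raises :class:`DegenerateSeedError`
    for a monomorphic seed.
    """
    lo, hi = window
    if not (0 <= lo <= seed < hi <= g.num_variants):
        raise InvalidInputError("seed must lie inside the window, window inside matrix")
    if alpha is None:
        alpha = cfg.alpha_main
    mi_cfg = cfg.mi

    seed_vec = g.values[seed]
    w = _weights_against_meta(g, window, _seed_meta(seed_vec), alpha, mi_cfg)
    if not np.any(w > 0):
        raise DegenerateSeedError(f"seed {seed} is monomorphic; all weights are zero")

    meta = compute_metasnp(g, w, window)
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        w_new = _weights_against_meta(g, window, meta, alpha, mi_cfg)
        if not np.any(w_new > 0):
            raise DegenerateAttractorError("weights collapsed to zero mid-iteration")
        delta = float(np.sum((w_new - w) ** 2))
        w = w_new
        meta = compute_metasnp(g, w, window)
        if delta < cfg.epsilon:
            converged = True
            break
    return AttractorResult(
        seed_index=seed,
        weights=w,
        metasnp=meta,
        iterations=iterations,
        converged=converged,
        window_range=(lo, hi),
    )


def _seed_meta(seed_vec: np.ndarray) -> np.ndarray:
    """Initial metaSNP equals the seed vector; missing calls are imputed with
    the seed's non-missing mean purely to define the continuous consensus (the
    pairwise-complete MI never reads the imputed entries of the seed itself
    beyond the binning geometry)."""
    if np.isnan(seed_vec).all():
        raise DegenerateSeedError("seed has no genotyped samples")
    if np.isnan(seed_vec).any():
        seed_vec = np.where(
            np.isnan(seed_vec), np.nanmean(seed_vec), seed_vec
        )
    return seed_vec.astype(np.float64)
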