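"""Genotype/haplotype matrix container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .mi import SimilarityConfig, effective_entropy, entropy_from_pmf, profile_matrix

GENOTYPE_ALPHABET = (0.0, 1.0, 2.0)
HAPLOTYPE_ALPHABET = (0.0, 1.0)


@dataclass(eq=False)
class GenotypeMatrix:
    """N variants by P samples, tri-level genotypes or bi-level haplotypes.

    ``values`` is a float matrix with entries in {0, 1, 2} (``ploidy_mode ==
    "genotype"``: 0 = reference homozygote, 1 = heterozygote, 2 = alternate
    homozygote) or {0, 1} (``"haplotype"``: one column per phased chromosome
    copy).  Missing calls are NaN.  One chromosome per matrix; positions are
    1-based and non-decreasing.
    """

    values: np.ndarray
    ids: np.ndarray
    positions: np.ndarray
    chromosome: str = "1"
    ploidy_mode: str = "genotype"
    sample_names: np.ndarray | None = None
    _profile_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.values.ndim != 2:
            raise InvalidInputError("values must be a 2-D (variants x samples) matrix")
        n = self.values.shape[0]
        if len(self.ids) != n or len(self.positions) != n:
            raise InvalidInputError("ids/positions must match the number of variants")
        if np.any(np.diff(self.positions) < 0):
            raise InvalidInputError(
                "positions must be sorted non-decreasing; sort the input by position"
            )
        if self.ploidy_mode not in ("genotype", "haplotype"):
            raise InvalidInputError("ploidy_mode must be 'genotype' or 'haplotype'")
        alphabet = (
            GENOTYPE_ALPHABET if self.ploidy_mode == "genotype" else HAPLOTYPE_ALPHABET
        )
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.isin(observed, alphabet).all():
            bad = observed[~np.isin(observed, alphabet)][0]
            raise InvalidInputError(
                f"value {bad} outside the {self.ploidy_mode} alphabet {alphabet}"
            )
        if self.sample_names is None:
            self.sample_names = np.array(
                [f"sample{j + 1}" for j in range(self.values.shape[1])], dtype=object
            )

    @property
    def num_variants(self) -> int:
        return self.values.shape[0]

    @property
    def num_samples(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def profiles(self, cfg: SimilarityConfig) -> "ProfileCache":
        """Cached per-variant bin profiles and entropies (see ProfileCache)."""
        key = (cfg.num_bins, cfg.spline_order, cfg.log_base)
        if key not in self._profile_cache:
            prof = profile_matrix(self.values, cfg)
            n = self.num_variants
            h = np.zeros(n)
            h_eff = np.zeros(n)
            for i in range(n):
                rows = prof[i][~np.isnan(prof[i, :, 0])]
                if rows.shape[0]:
                    h[i] = max(0.0, entropy_from_pmf(rows.mean(axis=0), cfg.log_base))
                    h_eff[i] = effective_entropy(rows, cfg.log_base)
            prof_t = np.ascontiguousarray(prof.swapaxes(1, 2))
            self._profile_cache[key] = ProfileCache(
                profiles=prof,
                profiles_flat=prof_t.reshape(n * cfg.num_bins, self.num_samples),
                marginal_entropy=h,
                effective_entropy=h_eff,
                row_has_missing=np.isnan(self.values).any(axis=1),
            )
        return self._profile_cache[key]


@dataclass
class ProfileCache:
    """Per-variant bin-weight profiles precomputed for the attractor engine.

    ``profiles`` is (N, P, B) with NaN rows for missing calls;
    ``profiles_flat`` is the (N*B, P) transposed layout used for one-GEMM
    joint-distribution computation; entropies are per variant over its
    non-missing samples.
    """

    profiles: np.ndarray
    profiles_flat: np.ndarray
    marginal_entropy: np.ndarray
    effective_entropy: np.ndarray
    row_has_missing: np.ndarray
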