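"""Tag-SNP selection, attractor strength, and ranking.

The tag of an attractor is its maximum-weight SNP; co-top SNPs (weights tied
within 1e-9) are resolved to the one closest to the median of the tied
genomic positions.  The strength S of an attractor is the unnormalized
mutual information, in bits, between its n-th top-weighted SNP and the
metaSNP — a deep-association score: it is large only when at least n SNPs
are strongly mutually linked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attractor import AttractorConfig, AttractorResult
from .errors import DegenerateAttractorError
from .matrix import GenotypeMatrix
from .mi import mutual_information

__all__ = ["TagSNP", "select_tag", "strength", "rank_tags", "tag_attractor"]

WEIGHT_TIE_TOL = 1e-9


@dataclass
class TagSNP:
    """A selected representative variant."""

    snp_index: int
    id: str
    position: int
    strength: float
    source: AttractorResult
    rank: int = 0


def select_tag(a: AttractorResult, g: GenotypeMatrix) -> int:
    """Index (into ``g``) of the attractor's tag SNP.

    The max-weight SNP wins; among co-top SNPs (within ``WEIGHT_TIE_TOL``)
    the one nearest the median of their genomic positions is chosen.  An
    even number of tied candidates uses the mean of the two central
    positions as the median; equal distances break toward the smaller
    position.
    """
    w = np.asarray(a.weights)
    if not np.any(w > 0):
        raise DegenerateAttractorError("attractor has no positive weight")
    top = w.max()
    tied_local = np.nonzero(w >= top - WEIGHT_TIE_TOL)[0]
    candidates = a.window_range[0] + tied_local
    if candidates.size == 1:
        return int(candidates[0])
    pos = g.positions[candidates].astype(np.float64)
    median = float(np.median(pos))
    dist = np.abs(pos - median)
    best = candidates[dist == dist.min()]
    return int(best[np.argmin(g.positions[best])])


def strength(a: AttractorResult, g: GenotypeMatrix, cfg: AttractorConfig) -> float:
    """Attractor strength S in bits.

    Unnormalized MI between the SNP with the ``strength_rank``-th largest
    weight and the metaSNP; if fewer SNPs carry positive weight, the
    smallest positive-weight SNP stands in.
    """
    w = np.asarray(a.weights)
    positive_local = np.nonzero(w > 0)[0]
    if positive_local.size == 0:
        raise DegenerateAttractorError("attractor has no positive weight")
    order = positive_local[np.argsort(-w[positive_local], kind="stable")]
    nth_local = order[min(cfg.strength_rank, order.size) - 1]
    snp = a.window_range[0] + int(nth_local)
    return mutual_information(g.values[snp], a.metasnp, cfg.mi)


def tag_attractor(a: AttractorResult, g: GenotypeMatrix, cfg: AttractorConfig) -> TagSNP:
    """Bundle an attractor with its selected tag and strength."""
    idx = select_tag(a, g)
    return TagSNP(
        snp_index=idx,
        id=str(g.ids[idx]),
        position=int(g.positions[idx]),
        strength=strength(a, g, cfg),
        source=a,
    )


def rank_tags(tags: list[TagSNP]) -> list[TagSNP]:
    """Order tags by descending strength (position ascending on ties) and
    assign ranks 1..T.  Permutation-invariant and deterministic."""
    ranked = sorted(tags, key=lambda t: (-t.strength, t.position, t.snp_index))
    for r, t in enumerate(ranked, start=1):
        t.rank = r
    return ranked
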