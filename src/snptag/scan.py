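"""Sliding-window genome scan: prescreen, full attractors, deduplication.

An exhaustive scan would run the attractor iteration from all N seeds; the
two-layer heuristic instead (1) screens every SNP with a cheap short-window
("short-attractor") run and keeps only *attractee seeds* — seeds whose
converged short-attractor has at least ``attractee_rank`` weights at or above
``attractee_threshold`` — then (2) runs the full-window attractor from each
surviving seed and collapses attractors that select the same tag SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .attractor import (
    AttractorConfig,
    AttractorResult,
    run_attractor,
    window_bounds,
)
from .errors import DegenerateAttractorError, DegenerateSeedError
from .matrix import GenotypeMatrix
from .tagging import TagSNP, rank_tags, tag_attractor

logger = logging.getLogger(__name__)

__all__ = ["ScanReport", "prescreen", "scan_all", "deduplicate", "is_degenerate_attractor"]


@dataclass
class ScanReport:
    """Outcome of a full scan over one chromosome."""

    attractee_seeds: list[int]
    attractors: list[AttractorResult]
    tags: list[TagSNP]
    discarded_count: int
    prescreen_stats: dict[int, float] = field(default_factory=dict)
    skipped_seeds: list[int] = field(default_factory=list)
    degenerate_seeds: list[int] = field(default_factory=list)


def is_degenerate_attractor(a: AttractorResult, cfg: AttractorConfig, alpha: float) -> bool:
    """True for trivial single-SNP self-attractors.

    Any seed is a fixed point of the iteration with weight 1 on itself and
    near-zero weights elsewhere; such an "attractor" expresses no multi-locus
    association and tags only itself.  A genuine attractor must mutually
    associate at least two SNPs at the attractee bar: the prescreen demands
    normalized MI >= attractee_threshold ** (1/alpha_prescreen), which at the
    exponent ``alpha`` of the full run is the weight bar
    ``attractee_threshold ** (alpha / alpha_prescreen)``.  An attractor whose
    second-largest weight falls below that bar is discarded.
    """
    w = a.weights
    if w.size < 2:
        return True
    bar = cfg.attractee_threshold ** (alpha / cfg.alpha_prescreen)
    return float(np.sort(w)[-2]) < bar


def _prescreen_statistic(weights: np.ndarray, rank: int) -> float:
    """The ``rank``-th largest converged weight (capped at the window size)."""
    k = min(rank, weights.size)
    return float(np.sort(weights)[-k])


def prescreen(g: GenotypeMatrix, cfg: AttractorConfig) -> tuple[list[int], dict[int, float]]:
    """Identify attractee seeds via short-window attractors.

    Every SNP is run through the attractor iteration on the
    ``window_short``-SNP window centered at it (truncated at chromosome
    ends) with the permissive exponent ``alpha_prescreen``; it survives iff
    the ``attractee_rank``-th largest converged weight reaches
    ``attractee_threshold``.  Returns the surviving seed indices and the
    per-seed statistic.
    """
    seeds: list[int] = []
    stats: dict[int, float] = {}
    n = g.num_variants
    for k in range(n):
        if k and k % 1000 == 0:
            logger.info("prescreen: %d/%d seeds processed", k, n)
        window = window_bounds(k, cfg.window_short, n)
        try:
            res = run_attractor(g, k, window, cfg, alpha=cfg.alpha_prescreen)
        except (DegenerateSeedError, DegenerateAttractorError):
            continue
        stat = _prescreen_statistic(res.weights, cfg.attractee_rank)
        stats[k] = stat
        if stat >= cfg.attractee_threshold:
            seeds.append(k)
    return seeds, stats


def deduplicate(tags: list[TagSNP]) -> list[TagSNP]:
    """Collapse attractors that selected the same tag SNP.

    Equivalent attractee seeds converge to the same attractor; the observable
    equivalence is tag identity.  Among duplicates the attractor with the
    largest strength survives (ties: the earliest seed).  Output is ordered
    by the tag's genomic position.
    """
    best: dict[int, TagSNP] = {}
    for t in tags:
        cur = best.get(t.snp_index)
        if cur is None or t.strength > cur.strength:
            best[t.snp_index] = t
    return sorted(best.values(), key=lambda t: (t.position, t.snp_index))


def scan_all(g: GenotypeMatrix, cfg: AttractorConfig | None = None) -> ScanReport:
    """Run the full two-layer scan and return ranked tag SNPs.

    With ``cfg.coalesce_seeds`` enabled, attractee seeds already inside a
    previously found attractor's top-weight set are skipped before the full
    run (a workload optimization; results on block-structured data are
    unchanged because such seeds are attractees of the same attractor).
    """
    if cfg is None:
        cfg = AttractorConfig()
    seeds, stats = prescreen(g, cfg)
    n = g.num_variants
    tagged: list[TagSNP] = []
    skipped: list[int] = []
    degenerate: list[int] = []
    covered: set[int] = set()
    for j, k in enumerate(seeds):
        if j and j % 1000 == 0:
            logger.info("scan: %d/%d attractee seeds processed", j, len(seeds))
        if cfg.coalesce_seeds and k in covered:
            continue
        window = window_bounds(k, cfg.window_main, n)
        try:
            res = run_attractor(g, k, window, cfg, alpha=cfg.alpha_main)
            if is_degenerate_attractor(res, cfg, cfg.alpha_main):
                degenerate.append(k)
                continue
            tag = tag_attractor(res, g, cfg)
        except (DegenerateSeedError, DegenerateAttractorError) as exc:
            logger.warning("seed %d skipped: %s", k, exc)
            skipped.append(k)
            continue
        tagged.append(tag)
        if cfg.coalesce_seeds:
            top = res.window_indices[res.weights >= cfg.attractee_threshold]
            covered.update(int(i) for i in top)
    unique = deduplicate(tagged)
    ranked = rank_tags(unique)
    return ScanReport(
        attractee_seeds=seeds,
        attractors=[t.source for t in ranked],
        tags=ranked,
        discarded_count=g.num_variants - len(seeds),
        prescreen_stats=stats,
        skipped_seeds=skipped,
        degenerate_seeds=degenerate,
    )
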