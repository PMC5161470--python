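"""Coverage rate R of a tag set: the haplotype-diversity metric.

Samples are grouped by their genotype pattern restricted to the tag loci;
within each of the t pattern groups, G_i is the largest number of samples
sharing one identical full-length genotype sequence, and

    R = (G_1 + ... + G_t) / P.

R = 1 means every sample's complete sequence is the majority sequence of its
tag-pattern group, i.e. the tags resolve all common diversity.  With missing
calls, both the pattern grouping and full-sequence identity treat a missing
entry as compatible with anything (per-comparison exclusion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .matrix import GenotypeMatrix

__all__ = [
    "CoverageResult",
    "coverage_rate",
    "coverage_rate_missing",
    "coverage_curve",
]


@dataclass
class CoverageResult:
    """Coverage rate with its pattern decomposition."""

    R: float
    t: int
    pattern_coverages: list[int]
    P: int
    cost: int
    tag_indices: tuple[int, ...]


def _check_tags(g: GenotypeMatrix, tags) -> np.ndarray:
    idx = np.asarray(list(tags), dtype=np.int64)
    if idx.size == 0:
        raise InvalidInputError("tag set must be non-empty")
    if idx.min() < 0 or idx.max() >= g.num_variants:
        raise InvalidInputError("tag index out of range")
    return idx


def coverage_rate(g: GenotypeMatrix, tags) -> CoverageResult:
    """Coverage rate of a tag set on complete data.

    Dispatches to :func:`coverage_rate_missing` when the matrix contains
    missing calls.
    """
    idx = _check_tags(g, tags)
    if g.missing_mask.any():
        return coverage_rate_missing(g, tags)
    tag_block = g.values[idx]  # (c, P)
    full = g.values
    n_samp = g.num_samples
    groups: dict[bytes, list[int]] = {}
    for p in range(n_samp):
        groups.setdefault(tag_block[:, p].tobytes(), []).append(p)
    coverages = []
    for members in groups.values():
        seqs: dict[bytes, int] = {}
        for p in members:
            key = full[:, p].tobytes()
            seqs[key] = seqs.get(key, 0) + 1
        coverages.append(max(seqs.values()))
    return CoverageResult(
        R=sum(coverages) / n_samp,
        t=len(coverages),
        pattern_coverages=coverages,
        P=n_samp,
        cost=idx.size,
        tag_indices=tuple(int(i) for i in idx),
    )


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    """Wildcard equality: agree wherever both are observed."""
    both = ~(np.isnan(a) | np.isnan(b))
    return bool(np.all(a[both] == b[both]))


def coverage_rate_missing(g: GenotypeMatrix, tags) -> CoverageResult:
    """Coverage rate with per-comparison exclusion of missing loci.

    Grouping: samples fully observed at the tag loci form exact pattern
    groups first; each remaining sample joins the largest compatible
    existing group (missing entries match anything; a sample missing at all
    tag loci therefore joins the largest group), or founds a new group under
    its partial pattern.  Within a group, G_i is the maximum, over member
    full sequences used as templates, of the number of members compatible
    with that template.  Reduces exactly to :func:`coverage_rate` on
    complete data.
    """
    idx = _check_tags(g, tags)
    tag_block = g.values[idx]
    full = g.values
    n_samp = g.num_samples

    group_keys: list[np.ndarray] = []
    group_members: list[list[int]] = []
    exact: dict[bytes, int] = {}
    deferred: list[int] = []
    for p in range(n_samp):
        pat = tag_block[:, p]
        if np.isnan(pat).any():
            deferred.append(p)
            continue
        key = pat.tobytes()
        if key not in exact:
            exact[key] = len(group_keys)
            group_keys.append(pat.copy())
            group_members.append([])
        group_members[exact[key]].append(p)
    for p in deferred:
        pat = tag_block[:, p]
        compat = [gi for gi, key in enumerate(group_keys) if _compatible(pat, key)]
        if compat:
            gi = max(compat, key=lambda i: (len(group_members[i]), -i))
            group_members[gi].append(p)
        else:
            group_keys.append(pat.copy())
            group_members.append([p])

    coverages = []
    for members in group_members:
        best = 0
        for t_p in members:
            template = full[:, t_p]
            count = sum(1 for p in members if _compatible(full[:, p], template))
            best = max(best, count)
        coverages.append(best)
    return CoverageResult(
        R=sum(coverages) / n_samp,
        t=len(coverages),
        pattern_coverages=coverages,
        P=n_samp,
        cost=idx.size,
        tag_indices=tuple(int(i) for i in idx),
    )


def coverage_curve(g: GenotypeMatrix, ranked_tags, costs) -> list[CoverageResult]:
    """Coverage of the top-c tags for each cost c; non-decreasing in c."""
    ranked = list(ranked_tags)
    results = []
    for c in costs:
        if not (1 <= c <= len(ranked)):
            raise InvalidInputError(f"cost {c} outside 1..{len(ranked)}")
        results.append(coverage_rate(g, ranked[:c]))
    return results
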