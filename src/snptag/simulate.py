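"""Synthetic genotype/haplotype matrices with planted LD blocks.

The generator uses a founder-copying model: each block has one founder
biallelic variant per chromosome copy per sample; every SNP inside the block
copies the founder allele with probability ``copy_prob`` and flips it
otherwise, emulating the decay of linkage by recombination/mutation.
Background SNPs are i.i.d. draws at their own allele frequency.  Diploid
genotypes are the sum of two independent haplotypes.  Block membership is
known exactly, which is what algorithm validation needs — population-genetic
realism (coalescent genealogies, recombination maps) is deliberately not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .matrix import GenotypeMatrix

__all__ = ["BlockSpec", "SimulationSpec", "SyntheticTruth", "simulate", "worked_example"]


@dataclass(frozen=True)
class BlockSpec:
    """One planted LD block: contiguous SNPs sharing a founder variant."""

    start: int
    size: int
    maf: float = 0.3
    copy_prob: float = 0.95

    def __post_init__(self) -> None:
        if self.size < 1 or self.start < 0:
            raise InvalidInputError("block start/size must be nonnegative/positive")
        if not (0 < self.maf <= 0.5):
            raise InvalidInputError("founder MAF must be in (0, 0.5]")
        if not (0 <= self.copy_prob <= 1):
            raise InvalidInputError("copy_prob must be in [0, 1]")

    @property
    def stop(self) -> int:
        return self.start + self.size


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic data set."""

    num_snps: int
    num_samples: int
    blocks: tuple[BlockSpec, ...] = ()
    background_maf: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    ploidy_mode: str = "genotype"
    seed: int = 0
    position_spacing: int = 250

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if self.num_snps < 1 or self.num_samples < 1:
            raise InvalidInputError("num_snps and num_samples must be positive")
        if not (0 <= self.missing_rate < 1):
            raise InvalidInputError("missing_rate must be in [0, 1)")
        lo, hi = self.background_maf
        if not (0 < lo <= hi <= 0.5):
            raise InvalidInputError("background MAF range must satisfy 0 < lo <= hi <= 0.5")
        spans = sorted((b.start, b.stop) for b in self.blocks)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise InvalidInputError("blocks must not overlap")
        if spans and spans[-1][1] > self.num_snps:
            raise InvalidInputError("block extends past num_snps")


@dataclass
class SyntheticTruth:
    """Planted structure: per-SNP block label (-1 = background) and the
    founder haplotypes (block x chromosome-copy x sample)."""

    block_labels: np.ndarray
    founders: list[np.ndarray] = field(default_factory=list)
    spec: SimulationSpec | None = None


def simulate(spec: SimulationSpec) -> tuple[GenotypeMatrix, SyntheticTruth]:
    """Generate a matrix and its planted truth, reproducibly from the seed."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.num_snps, spec.num_samples
    n_hap = 2 if spec.ploidy_mode == "genotype" else 1
    haps = np.empty((n, n_hap, p), dtype=np.float64)

    labels = np.full(n, -1, dtype=np.int64)
    for bi, b in enumerate(spec.blocks):
        labels[b.start : b.stop] = bi

    bg_maf = rng.uniform(*spec.background_maf, size=n)
    founders: list[np.ndarray] = []
    for bi, b in enumerate(spec.blocks):
        founder = (rng.random((n_hap, p)) < b.maf).astype(np.float64)
        founders.append(founder)
        copies = rng.random((b.size, n_hap, p)) < b.copy_prob
        haps[b.start : b.stop] = np.where(copies, founder, 1.0 - founder)
    background = labels < 0
    haps[background] = (
        rng.random((int(background.sum()), n_hap, p))
        < bg_maf[background, None, None]
    ).astype(np.float64)

    values = haps.sum(axis=1)
    if spec.missing_rate > 0:
        mask = rng.random((n, p)) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    g = GenotypeMatrix(
        values=values,
        ids=np.array([f"snp{i + 1:06d}" for i in range(n)], dtype=object),
        positions=(np.arange(n, dtype=np.int64) + 1) * spec.position_spacing,
        chromosome="1",
        ploidy_mode=spec.ploidy_mode,
    )
    return g, SyntheticTruth(block_labels=labels, founders=founders, spec=spec)


def random_blocks(
    num_snps: int,
    num_blocks: int,
    seed: int,
    size_range: tuple[int, int] = (8, 50),
    maf_range: tuple[float, float] = (0.1, 0.5),
    copy_prob: float = 0.95,
    gap: int = 10,
) -> tuple[BlockSpec, ...]:
    """Draw non-overlapping blocks with random sizes, placements and MAFs.

    Block founder MAFs default to uniform(0.1, 0.5) — the common-variant
    range tag-SNP panels target.  Blocks are separated by at least ``gap``
    background SNPs.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.integers(size_range[0], size_range[1] + 1, num_blocks)
    free = num_snps - int(sizes.sum()) - gap * num_blocks
    if free <= num_blocks:
        raise InvalidInputError("num_snps too small for the requested blocks")
    cuts = np.sort(rng.choice(free, num_blocks, replace=False))
    return tuple(
        BlockSpec(
            start=int(cuts[i] + gap * (i + 1) + sizes[:i].sum()),
            size=int(sizes[i]),
            maf=float(rng.uniform(*maf_range)),
            copy_prob=copy_prob,
        )
        for i in range(num_blocks)
    )


def worked_example() -> GenotypeMatrix:
    """The canonical 5-sample, 4-SNP genotype matrix used to illustrate the
    coverage rate: sample sequences "2111", "2200", "2201", "2110", "2200"
    (one character per locus), samples I-V."""
    seqs = ["2111", "2200", "2201", "2110", "2200"]
    values = np.array([[int(s[i]) for s in seqs] for i in range(4)], dtype=np.float64)
    return GenotypeMatrix(
        values=values,
        ids=np.array([f"locus{i + 1}" for i in range(4)], dtype=object),
        positions=np.array([100, 200, 300, 400], dtype=np.int64),
        chromosome="1",
        ploidy_mode="genotype",
        sample_names=np.array(["I", "II", "III", "IV", "V"], dtype=object),
    )
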