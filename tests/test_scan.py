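import numpy as np
import pytest

import snptag as st
from snptag.attractor import AttractorResult
from snptag.scan import deduplicate, is_degenerate_attractor
from snptag.simulate import random_blocks
from snptag.tagging import TagSNP


class TestPrescreen:
    def test_independent_snps_yield_no_attractee_seeds(self):
        g, _ = st.simulate(
            st.SimulationSpec(num_snps=150, num_samples=200, seed=21)
        )
        seeds, stats = st.prescreen(g, st.AttractorConfig())
        assert seeds == []
        assert max(stats.values()) < 0.5

    def test_perfect_block_members_all_pass_with_stat_one(self):
        blocks = (st.BlockSpec(start=55, size=10, maf=0.3, copy_prob=1.0),)
        g, _ = st.simulate(
            st.SimulationSpec(num_snps=120, num_samples=100, blocks=blocks, seed=8)
        )
        seeds, stats = st.prescreen(g, st.AttractorConfig())
        assert set(range(55, 65)).issubset(seeds)
        for k in range(55, 65):
            assert stats[k] == pytest.approx(1.0)

    def test_block_smaller_than_attractee_rank_is_invisible(self):
        blocks = (st.BlockSpec(start=60, size=3, maf=0.3, copy_prob=1.0),)
        g, _ = st.simulate(
            st.SimulationSpec(num_snps=130, num_samples=150, blocks=blocks, seed=9)
        )
        seeds, stats = st.prescreen(g, st.AttractorConfig())
        for k in range(60, 63):
            assert stats[k] < 0.5
        assert seeds == []


class TestScanAll:
    def test_five_planted_blocks_give_exactly_five_tags(self, five_block_data, five_block_report):
        g, truth = five_block_data
        report = five_block_report
        assert len(report.tags) == 5
        tagged_blocks = sorted(truth.block_labels[t.snp_index] for t in report.tags)
        assert tagged_blocks == [0, 1, 2, 3, 4]
        # workload bound: full runs only for surviving seeds, never all N
        assert len(report.attractee_seeds) < g.num_variants

    def test_equivalent_seeds_collapse_to_one_attractor(self, five_block_report):
        report = five_block_report
        # many attractee seeds per block, one surviving tag each
        assert len(report.attractee_seeds) > len(report.tags)
        assert len({t.snp_index for t in report.tags}) == len(report.tags)

    def test_empty_attractee_list_gives_empty_report(self):
        g, _ = st.simulate(
            st.SimulationSpec(num_snps=150, num_samples=200, seed=21)
        )
        report = st.scan_all(g, st.AttractorConfig())
        assert report.tags == [] and report.attractors == []
        assert report.discarded_count == g.num_variants

    def test_coalesce_seeds_preserves_tags(self, five_block_data, five_block_report):
        g, _ = five_block_data
        base = five_block_report
        fast = st.scan_all(g, st.AttractorConfig(coalesce_seeds=True))
        assert [t.snp_index for t in base.tags] == [t.snp_index for t in fast.tags]

    def test_tags_ordered_and_ranked(self, five_block_report):
        tags = five_block_report.tags
        assert [t.rank for t in tags] == list(range(1, len(tags) + 1))
        strengths = [t.strength for t in tags]
        assert strengths == sorted(strengths, reverse=True)


def _fake_tag(idx: int, position: int, strength: float, seed: int = 0) -> TagSNP:
    a = AttractorResult(
        seed_index=seed,
        weights=np.array([1.0]),
        metasnp=np.zeros(2),
        iterations=1,
        converged=True,
        window_range=(idx, idx + 1),
    )
    return TagSNP(snp_index=idx, id=f"v{idx}", position=position, strength=strength, source=a)


class TestDeduplicate:
    def test_identical_tag_indices_keep_strongest(self):
        tags = [_fake_tag(4, 400, 1.0, seed=1), _fake_tag(4, 400, 2.5, seed=2)]
        out = deduplicate(tags)
        assert len(out) == 1 and out[0].strength == 2.5

    def test_disjoint_tags_unchanged(self):
        tags = [_fake_tag(1, 100, 1.0), _fake_tag(5, 500, 0.5)]
        assert [t.snp_index for t in deduplicate(tags)] == [1, 5]

    def test_survivors_match_exhaustive_pairwise_comparison(self):
        rng = np.random.default_rng(17)
        tags = [
            _fake_tag(int(idx), int(idx) * 10, float(s), seed=i)
            for i, (idx, s) in enumerate(
                zip(rng.integers(0, 3, 5), rng.uniform(0.1, 3.0, 5))
            )
        ]
        # oracle: for every tag index, scan all candidates for the max strength
        expected = {}
        for t in tags:
            if t.snp_index not in expected or t.strength > expected[t.snp_index].strength:
                expected[t.snp_index] = t
        out = deduplicate(tags)
        assert {t.snp_index: t.strength for t in out} == {
            i: t.strength for i, t in expected.items()
        }
        positions = [t.position for t in out]
        assert positions == sorted(positions)


def test_degenerate_attractor_screen_uses_rescaled_bar():
    cfg = st.AttractorConfig()
    bar = cfg.attractee_threshold ** (cfg.alpha_main / cfg.alpha_prescreen)
    a = AttractorResult(
        seed_index=0,
        weights=np.array([1.0, bar + 0.01, 0.001]),
        metasnp=np.zeros(2),
        iterations=1,
        converged=True,
        window_range=(0, 3),
    )
    assert not is_degenerate_attractor(a, cfg, cfg.alpha_main)
    a.weights = np.array([1.0, bar - 0.01, 0.001])
    assert is_degenerate_attractor(a, cfg, cfg.alpha_main)
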