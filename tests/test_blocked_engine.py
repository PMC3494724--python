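"""Blocked selection and incremental block-sum updates vs linear-scan oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blockssa import (
    BlockPartition,
    BlockedEngine,
    hierarchical_select,
    init_block_sums,
)
from blockssa.blocked_engine import (
    BlockSums,
    SelectionError,
    first_index_ge,
    select_block,
    select_chunk,
    select_within_chunk,
)
from blockssa.ssa_core import RngStream


def linear_scan_select(propensities, target):
    """Sequential accumulate-and-compare — the Direct Method's search."""
    running = 0.0
    for i, a in enumerate(propensities):
        running += a
        if running >= target:
            return i
    return -1


def random_propensity_vector(rng, size):
    """Non-negative vector with zero runs interleaved."""
    a = rng.exponential(1.0, size=size)
    zero = rng.random(size) < 0.35
    a[zero] = 0.0
    if a.sum() == 0.0:
        a[rng.integers(size)] = 1.0
    return a


class TestPartition:
    def test_default_geometry(self):
        p = BlockPartition.for_reactions(256)
        assert (p.num_blocks, p.block_size) == (2, 128)
        p = BlockPartition.for_reactions(50_000)
        assert p.block_size % 128 == 0 and p.num_blocks <= 25
        assert p.num_blocks * p.block_size >= 50_000

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            BlockPartition(2, 100)  # not a chunk multiple
        with pytest.raises(ValueError):
            BlockPartition(2, 128, chunk_size=48)  # not a lane multiple


class TestBlockSums:
    def test_uniform_vector(self):
        sums = init_block_sums(np.ones(256), BlockPartition(2, 128))
        assert sums.cumulative.tolist() == [128.0, 256.0]
        assert sums.total == 256.0

    def test_single_reaction(self):
        sums = init_block_sums(np.array([3.5]), BlockPartition(1, 128))
        assert sums.cumulative.tolist() == [3.5]

    def test_total_matches_full_summation(self):
        rng = np.random.default_rng(0)
        a = random_propensity_vector(rng, 1000)
        sums = init_block_sums(a, BlockPartition.for_reactions(1000))
        assert abs(sums.total - a.sum()) <= 1e-12 * a.sum()

    def test_empty_vector_invalid(self):
        with pytest.raises(ValueError):
            init_block_sums(np.empty(0), BlockPartition(1, 128))


class TestSelectBlock:
    def test_first_cumulative_reaching_target(self):
        sums = BlockSums(np.array([10.0, 20.0, 30.0, 40.0]))
        assert select_block(sums, 25.0) == 2

    def test_boundary_tie_goes_low(self):
        sums = BlockSums(np.array([10.0, 20.0]))
        assert select_block(sums, 10.0) == 0

    def test_target_above_total_rejected(self):
        with pytest.raises(SelectionError):
            select_block(BlockSums(np.array([10.0])), 11.0)

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(1)
        cum = np.cumsum(rng.exponential(1.0, 32))
        sums = BlockSums(cum)
        for target in rng.uniform(1e-9, cum[-1], 10_000):
            expected = int(np.searchsorted(cum, target, side="left"))
            assert select_block(sums, target) == expected


class TestSelectChunkAndWithin:
    PART = BlockPartition(num_blocks=2, block_size=64, chunk_size=32, lane_width=32)

    def test_chunk_sums_decide(self):
        a = np.full(128, 5.0 / 32.0)  # two chunks of sum 5 per block
        chunk, base = select_chunk(a, self.PART, 0, 6.0)
        assert chunk == 1 and base == 5.0
        chunk, base = select_chunk(a, self.PART, 0, 4.0)
        assert chunk == 0 and base == 0.0

    def test_within_chunk_prefix(self):
        a = np.ones(128)
        assert select_within_chunk(a, self.PART, 0, 0, 2.5) == 2
        # single positive propensity catches any residual in (0, a]
        b = np.zeros(128)
        b[40] = 3.0
        for resid in (0.01, 1.5, 3.0):
            assert select_within_chunk(b, self.PART, 0, 1, resid) == 40

    def test_random_chunk_matches_scan(self):
        rng = np.random.default_rng(2)
        a = random_propensity_vector(rng, 128)
        block_sum = a[:64].sum()
        for resid in rng.uniform(1e-9, block_sum, 1000):
            chunk, base = select_chunk(a, self.PART, 0, resid)
            expected = linear_scan_select(a[:64], resid)
            assert expected // 32 == chunk
            f = select_within_chunk(a, self.PART, 0, chunk, resid - base)
            # composing local residuals reproduces the scan up to rounding at
            # chunk boundaries; the engine's continued-frame path is exact
            assert abs(f - expected) <= (1 if resid - base < 1e-9 else 0)


class TestHierarchicalSelect:
    def test_uniform_vector_target(self):
        a = np.ones(256)
        part = BlockPartition(2, 128)
        assert hierarchical_select(a, part, 130.5 / 256.0) == 130

    def test_single_nonzero(self):
        a = np.zeros(300)
        a[137] = 2.5
        part = BlockPartition.for_reactions(300)
        for z1 in (1e-12, 0.3, 1.0):
            assert hierarchical_select(a, part, z1) == 137

    def test_zero_total_signals_no_reaction(self):
        assert hierarchical_select(np.zeros(10), BlockPartition(1, 128), 0.5) == -1

    def test_invalid_z1(self):
        with pytest.raises(SelectionError):
            hierarchical_select(np.ones(10), BlockPartition(1, 128), 0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_linear_scan_property(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(1, 700))
        a = random_propensity_vector(rng, size)
        part = BlockPartition.for_reactions(
            size, num_blocks=int(rng.integers(1, 8)), chunk_size=32
        )
        sums = init_block_sums(a, part)
        for z1 in rng.uniform(1e-12, 1.0, 40):
            f = hierarchical_select(a, part, z1, sums)
            assert f == linear_scan_select(a, z1 * sums.total)

    def test_boundary_exact_targets(self):
        """Targets equal to prefix sums (incl. across zero runs) tie low."""
        rng = np.random.default_rng(3)
        a = random_propensity_vector(rng, 257)
        part = BlockPartition.for_reactions(257, num_blocks=4, chunk_size=32)
        sums = init_block_sums(a, part)
        cum = np.cumsum(a)
        for j in range(257):
            target = cum[j]
            if not 0.0 < target <= sums.total:
                continue
            z1 = target / sums.total
            if z1 * sums.total != target:  # rounding moved the target off
                continue
            f = hierarchical_select(a, part, z1, sums)
            assert f == linear_scan_select(a, target)


class TestIncrementalUpdates:
    def test_prefixed_deltas_update_cumulative_sums(self, random64):
        part = BlockPartition(8, 8, chunk_size=8, lane_width=8)
        engine = BlockedEngine(random64, partition=part, refresh_interval=None, rel_tol=None)
        rng = RngStream(4)
        for _ in range(200):
            z1, _ = rng.pair()
            before = engine.propensities.copy()
            cum_before = engine._cum.copy()
            f = engine.select(z1)
            engine.fire(f)
            deltas = engine.propensities - before
            per_block = np.add.reduceat(deltas, np.arange(0, 64, 8))
            np.testing.assert_allclose(
                engine._cum, cum_before + np.cumsum(per_block), rtol=1e-12, atol=1e-12
            )
            assert np.all(np.diff(engine._cum) >= -1e-12 * engine._cum[-1])

    def test_no_dependent_change_leaves_sums_unchanged(self, chain5):
        engine = BlockedEngine(chain5, refresh_interval=None, rel_tol=None)
        cum = engine._cum.copy()
        engine.update_after_firing(0)  # state untouched: all deltas zero
        np.testing.assert_array_equal(engine._cum, cum)

    def test_drift_after_many_updates(self, random256):
        engine = BlockedEngine(random256, refresh_interval=None, rel_tol=None)
        rng = RngStream(5)
        fires = 0
        while fires < 10_000:
            if engine.total_propensity <= 0:
                engine.reset()
                continue
            z1, _ = rng.pair()
            engine.fire(engine.select(z1))
            fires += 1
        assert engine.refresh_count == 0
        fresh = init_block_sums(engine.propensities, engine.partition)
        drift = np.abs(engine._cum - fresh.cumulative).max()
        assert drift <= 1e-8 * fresh.total

    def test_sparse_and_dense_paths_bitwise_identical(self, random64):
        part = BlockPartition.for_reactions(64, num_blocks=4, chunk_size=16, lane_width=16)
        sparse = BlockedEngine(random64, partition=part, dense_update_threshold=1e18)
        dense = BlockedEngine(random64, partition=part, dense_update_threshold=-1.0)
        assert not sparse.dense_updates and dense.dense_updates
        rng_a, rng_b = RngStream(6), RngStream(6)
        for _ in range(500):
            za, _ = rng_a.pair()
            zb, _ = rng_b.pair()
            fa, fb = sparse.select(za), dense.select(zb)
            assert fa == fb
            sparse.fire(fa)
            dense.fire(fb)
            np.testing.assert_array_equal(sparse.propensities, dense.propensities)
            np.testing.assert_array_equal(sparse._cum, dense._cum)

    def test_refresh_counter_and_interval(self, random64):
        engine = BlockedEngine(random64, refresh_interval=100, rel_tol=None)
        rng = RngStream(7)
        for _ in range(350):
            z1, _ = rng.pair()
            engine.fire(engine.select(z1))
        assert engine.refresh_count == 3


class TestWorkTradeoff:
    def test_selection_down_update_up_with_block_count(self, random256):
        """More blocks -> finer elimination (less selection work) but more
        per-firing block-sum maintenance (more update work)."""
        works = []
        for p in (1, 2, 4, 8, 16):
            part = BlockPartition.for_reactions(256, num_blocks=p, chunk_size=16, lane_width=16)
            engine = BlockedEngine(random256, partition=part)
            rng = RngStream(8)
            for _ in range(600):
                z1, _ = rng.pair()
                engine.fire(engine.select(z1))
            works.append((engine.selection_work, engine.update_work))
        sel = [w[0] for w in works]
        upd = [w[1] for w in works]
        assert all(b < a for a, b in zip(sel, sel[1:]))
        assert all(b > a for a, b in zip(upd, upd[1:]))
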