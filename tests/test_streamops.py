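"""Streaming operators vs their whole-stream oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import full_sort_oracle, offline_sync_oracle, run_reorder, random_sorted_stream
from spikelink.model import Spike, SpikeChunk
from spikelink.streamops import (
    BinState,
    FilterState,
    ReorderState,
    SyncFilterState,
    apply_filter_option,
    bin_step,
    filter_sync_step,
    filter_unsorted,
    flush_bin,
    flush_filter_option,
    flush_reorder,
    flush_sync,
    itemize_chunk,
    reorder_step,
)
from spikelink.synthetic import GeneratorConfig, chunk_stream, generate_stream

US = 1e-6


def sp(t, ch=1, unit=1):
    return Spike(t, ch, unit)


class TestReorder:
    def test_first_chunk_only_primes(self):
        out, state = reorder_step(ReorderState(), SpikeChunk(0, [sp(1), sp(3), sp(5)]))
        assert out == []
        assert sorted(s.t for s in state.rs) == [1, 3, 5]
        assert state.k_prev == 5

    def test_empty_chunk_empty_state_noop(self):
        out, state = reorder_step(ReorderState(), SpikeChunk(0, []))
        assert out == []
        assert state.rs == [] and state.k_prev is None

    def test_second_step_hand_trace(self):
        _, state = reorder_step(ReorderState(), SpikeChunk(0, [sp(1), sp(3), sp(5)]))
        out, state = reorder_step(state, SpikeChunk(1, [sp(6), sp(4), sp(8)]))
        assert [s.t for s in out] == [1, 3, 4, 5]
        assert sorted(s.t for s in state.rs) == [6, 8]

    def test_flush_sorts_remainder(self):
        assert flush_reorder(ReorderState(rs=[])) == []
        out = flush_reorder(ReorderState(k_prev=1.0, rs=[sp(8), sp(6)]))
        assert [s.t for s in out] == [6, 8]

    def test_tie_break_deterministic(self):
        # equal timestamps sort by (channel, unit)
        _, state = reorder_step(
            ReorderState(), SpikeChunk(0, [sp(1.0, 5, 2), sp(1.0, 2, 1), sp(1.0, 2, 0)])
        )
        out, _ = reorder_step(state, SpikeChunk(1, [sp(2.0)]))
        assert out == [sp(1.0, 2, 0), sp(1.0, 2, 1), sp(1.0, 5, 2)]

    def test_equivalence_with_full_sort_on_straggler_streams(self):
        # one-chunk displacement is the generator's model of occasional disorder
        for seed in range(30):
            gcfg = GeneratorConfig(
                n_channels=8, duration=2.0, rate_total=300.0, sync_rate=2.0,
                seed=seed,
            )
            spikes, _ = generate_stream(gcfg)
            chunks = chunk_stream(spikes, 0.01, p_straggler=0.2, seed=seed + 1)
            assert run_reorder(chunks) == full_sort_oracle(spikes)

    def test_output_nondecreasing_across_steps(self, rng):
        spikes = random_sorted_stream(rng, 2000, duration=1.0)
        chunks = chunk_stream(spikes, 0.01, p_straggler=0.1, seed=6)
        out = run_reorder(chunks)
        assert all(a.t <= b.t for a, b in zip(out, out[1:]))


class TestFilterUnsorted:
    def test_identity_when_all_sorted(self):
        spikes = [sp(0.1, 1, 1), sp(0.2, 2, 3)]
        assert filter_unsorted(spikes) == spikes

    def test_all_unsorted_removed(self):
        assert filter_unsorted([sp(0.1, 1, 0), sp(0.2, 2, 0)]) == []

    def test_counting_oracle_mixed(self, rng):
        spikes = random_sorted_stream(rng, 100, p_unsorted=0.0)
        idx = rng.choice(100, size=17, replace=False)
        spikes = [
            s._replace(unit=0) if i in set(idx.tolist()) else s
            for i, s in enumerate(spikes)
        ]
        out = filter_unsorted(spikes)
        assert len(out) == 83
        assert out == [s for s in spikes if s.unit != 0]  # order preserved


class TestSyncFilter:
    def test_single_open_window_deferred(self):
        state = SyncFilterState(T=25 * US)
        out, state = filter_sync_step(state, [sp(10 * US)])
        assert out == []
        assert [s.t for s in state.rs] == [10 * US]

    def test_doublet_window_removed(self):
        state = SyncFilterState(T=25 * US)
        out, state = filter_sync_step(state, [sp(10 * US), sp(20 * US, ch=2), sp(60 * US)])
        assert out == []
        assert [s.t for s in state.rs] == [60 * US]

    def test_singletons_kept(self):
        state = SyncFilterState(T=25 * US)
        out, state = filter_sync_step(state, [sp(10 * US), sp(30 * US), sp(60 * US)])
        assert [s.t for s in out] == [10 * US, 30 * US]
        assert [s.t for s in state.rs] == [60 * US]

    def test_flush_singleton_survives_doublet_removed(self):
        assert [s.t for s in flush_sync(SyncFilterState(T=25 * US, rs=[sp(60 * US)]))] == [60 * US]
        assert flush_sync(SyncFilterState(T=25 * US, rs=[sp(60 * US), sp(61 * US, ch=2)])) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="time-sorted"):
            filter_sync_step(SyncFilterState(T=25 * US), [sp(2.0), sp(1.0)])

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=400),
                st.integers(min_value=1, max_value=4),
            ),
            max_size=60,
        ),
        st.sampled_from([25e-6, 1e-3]),
        st.integers(min_value=1, max_value=7),
    )
    def test_streaming_equals_offline_oracle(self, raw, T, batching):
        # timestamps on a microsecond grid to exercise exact window edges
        spikes = sorted(
            (Spike(k * US, ch, 1) for k, ch in raw), key=lambda s: (s.t, s.channel)
        )
        state = SyncFilterState(T=T)
        out = []
        for i in range(0, len(spikes), batching):
            released, state = filter_sync_step(state, spikes[i : i + batching])
            out.extend(released)
        out.extend(flush_sync(state))
        assert out == offline_sync_oracle(spikes, T)

    def test_whole_stream_property_on_generated_data(self):
        gcfg = GeneratorConfig(
            n_channels=16, duration=0.5, rate_total=2000.0, sync_rate=50.0, seed=17
        )
        spikes, _ = generate_stream(gcfg)
        for T in (25e-6, 1e-3):
            state = SyncFilterState(T=T)
            out = []
            for i in range(0, len(spikes), 13):
                released, state = filter_sync_step(state, spikes[i : i + 13])
                out.extend(released)
            out.extend(flush_sync(state))
            assert out == offline_sync_oracle(spikes, T)


class TestBinning:
    def test_no_spikes_no_output(self):
        state = BinState(W=0.1)
        out, state2 = bin_step(state, [], 4)
        assert out == []
        assert state2 is state

    def test_counting_oracle_window_zero(self):
        state = BinState(W=0.1)
        spikes = [sp(0.010, 3), sp(0.020, 3), sp(0.050, 7), sp(0.150, 1)]
        out, state = bin_step(state, spikes, 8)
        assert len(out) == 1
        bv = out[0]
        assert bv.w == 0
        expected = np.zeros(8, dtype=np.int64)
        expected[3 - 1] = 2
        expected[7 - 1] = 1
        assert np.array_equal(bv.counts, expected)
        assert [s.t for s in state.rs] == [0.150]

    def test_empty_intermediate_windows_emitted(self):
        out, _ = bin_step(BinState(W=0.1), [sp(0.05), sp(0.55)], 2)
        assert [bv.w for bv in out] == [0, 1, 2, 3, 4]
        assert [bv.total() for bv in out] == [1, 0, 0, 0, 0]

    def test_late_spikes_dropped_and_counted(self):
        state = BinState(W=0.1, w=2)
        out, state = bin_step(state, [sp(0.05), sp(0.35)], 2)
        assert state.dropped_late == 1
        # 0.35 opens window 3, closing window 2 (empty: the late spike is excluded)
        assert [bv.w for bv in out] == [2]
        assert out[0].total() == 0
        assert [s.t for s in state.rs] == [0.35]

    def test_conservation_identity(self, rng):
        spikes = random_sorted_stream(rng, 5000, duration=3.0, n_channels=16)
        state = BinState(W=0.1)
        total = 0
        for i in range(0, len(spikes), 37):
            out, state = bin_step(state, spikes[i : i + 37], 16)
            total += sum(bv.total() for bv in out)
        total += sum(bv.total() for bv in flush_bin(state, 16))
        assert total + state.dropped_late == len(spikes)

    def test_single_window_reproduces_global_histogram(self, rng):
        spikes = random_sorted_stream(rng, 2000, duration=1.0, n_channels=16)
        state = BinState(W=10.0)  # wider than the stream
        out, state = bin_step(state, spikes, 16)
        assert out == []
        (bv,) = flush_bin(state, 16)
        hist = np.bincount([s.channel - 1 for s in spikes], minlength=16)
        assert np.array_equal(bv.counts, hist)

    def test_bad_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            bin_step(BinState(W=0.1), [sp(0.05, ch=99)], 8)


class TestItemize:
    def test_thirty_spikes_two_items(self, rng):
        spikes = random_sorted_stream(rng, 30)
        items = itemize_chunk(spikes, G=20, next_serial=5)
        assert [it.n_real for it in items] == [20, 10]
        assert [it.serial for it in items] == [5, 6]
        assert items[1].entries[10:] == (Spike(0.0, 0, 0),) * 10
        assert list(items[0].entries) + list(items[1].entries[:10]) == spikes

    def test_exact_fit_no_padding(self, rng):
        spikes = random_sorted_stream(rng, 20)
        (item,) = itemize_chunk(spikes, G=20)
        assert item.n_real == 20
        assert item.entries == tuple(spikes)

    def test_empty_input_no_items(self):
        assert itemize_chunk([], G=20) == []

    def test_real_count_sum_and_gapless_serials(self, rng):
        spikes = random_sorted_stream(rng, 173)
        serial = 0
        items = []
        for i in range(0, len(spikes), 31):  # arbitrary chunking
            batch = itemize_chunk(spikes[i : i + 31], G=20, next_serial=serial)
            serial += len(batch)
            items.extend(batch)
        assert sum(it.n_real for it in items) == 173
        assert [it.serial for it in items] == list(range(len(items)))


class TestFilterOptions:
    def test_no_filter_identity(self, rng):
        spikes = random_sorted_stream(rng, 50)
        state = FilterState.for_option("no_filter", 25 * US)
        out, state = apply_filter_option(spikes, state)
        assert out == spikes
        assert flush_filter_option(state) == []

    def test_unsort_sync_composition_order(self):
        # unsorted spike removed first, so the sorted survivor is solitary
        state = FilterState.for_option("unsort_sync", 25 * US)
        out, state = apply_filter_option([sp(10 * US, 1, 0), sp(12 * US, 2, 1)], state)
        out += flush_filter_option(state)
        assert out == [sp(12 * US, 2, 1)]

    @pytest.mark.parametrize("option", ["no_filter", "unsort", "sync", "unsort_sync"])
    def test_filters_only_remove(self, option, rng):
        spikes = random_sorted_stream(rng, 300, duration=0.01)
        state = FilterState.for_option(option, 25 * US)
        out, state = apply_filter_option(spikes, state)
        out += flush_filter_option(state)
        assert len(out) <= len(spikes)
        assert set(out) <= set(spikes)

    def test_unknown_option_rejected(self):
        with pytest.raises(ValueError, match="unknown filter option"):
            FilterState.for_option("median", 25 * US)
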