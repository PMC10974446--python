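import numpy as np
import pytest

from osmltr.fsa_scheduler import (
    CapacityError,
    CostModel,
    DeviceProfile,
    DeviceQueues,
    MemoryModel,
    ProtocolViolation,
    assign_jobs,
    build_machines,
    check_memory,
    default_device_pool,
    events_tsv,
    fsa_step,
    random_device_pool,
    run_scheduled_reconstruction,
    simulate_timeline,
    view_bytes_estimate,
)
from osmltr.geometry import partition_subsets
from osmltr.mltr_core import StoppingRule, run_os_mltr

GB = 2**30


def validate_trace(result, variant):
    """Every logged transition must appear in the bundled tables for the
    variant, with matching from/to states."""
    reference = build_machines(variant)
    short = {f"{mid}/{variant}": mid for mid in reference}
    for ev in result.events:
        machine = reference[short[ev.machine]]
        frm, to, _ = machine.transitions[ev.condition]
        assert (frm, to) == (ev.from_state, ev.to_state)
    times = [ev.time for ev in result.events]
    assert times == sorted(times) and len(set(times)) == len(times)


class TestBuildMachines:
    def test_fifo_outer_machine_has_eleven_transitions(self):
        m = build_machines("fifo")["OSEM_M"]
        assert len(m.transitions) == 11
        assert len(m.states) == 7

    def test_fifo_state_counts(self):
        ms = build_machines("fifo")
        assert sorted(ms["OSEM_Inner_S1"].states) == [f"S{i}" for i in range(9)]
        assert sorted(ms["OSEM_Inner_S2"].states) == [f"S{i}" for i in range(6)]

    def test_jobq_stage1_has_wait_for_refinement_self_loop(self):
        m = build_machines("jobq")["OSEM_Inner_S1"]
        frm, to, desc = m.transitions["C11"]
        assert (frm, to) == ("S6", "S6")
        assert "refinement" in desc.lower()

    def test_jobq_stage2_state_numbering_skips_s2_as_printed(self):
        m = build_machines("jobq")["OSEM_Inner_S2"]
        assert sorted(m.states) == ["S0", "S1", "S3", "S4", "S5"]
        assert m.unlisted_states == ("S2",)

    @pytest.mark.parametrize("variant", ["fifo", "jobq"])
    def test_closure_every_transition_endpoint_is_declared(self, variant):
        for m in build_machines(variant).values():
            declared = set(m.states) | set(m.unlisted_states)
            for frm, to, _ in m.transitions.values():
                assert frm in declared and to in declared

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            build_machines("lifo")


class TestFsaStep:
    def test_idle_queue_empty_self_loop(self):
        m = build_machines("fifo")["OSEM_M"]
        fsa_step(m, "C1")
        fsa_step(m, "C2")
        ev = fsa_step(m, "C3")
        assert (ev.from_state, ev.to_state) == ("S2", "S2")
        assert m.current_state == "S2"

    def test_memory_over_limit_path(self):
        m = build_machines("fifo")["OSEM_Inner_S1"]
        for c in ("C1", "C4", "C6", "C8", "C9"):
            fsa_step(m, c)
        assert m.current_state == "S5"
        fsa_step(m, "C10")
        assert m.current_state == "S6"

    def test_stage2_completion_returns_device_to_idle_state(self):
        m = build_machines("fifo")["OSEM_Inner_S2"]
        for c in ("C1", "C3", "C5", "C7", "C9"):
            fsa_step(m, c)
        assert m.current_state == "S5"
        fsa_step(m, "C10")
        assert m.current_state == "S0"

    def test_inapplicable_condition_is_a_protocol_violation(self):
        m = build_machines("fifo")["OSEM_M"]
        with pytest.raises(ProtocolViolation, match="C9"):
            fsa_step(m, "C9")  # S5→S6 not applicable in S0

    def test_event_log_records_every_step(self):
        m = build_machines("jobq")["OSEM_Inner_S2"]
        fsa_step(m, "C1", time=0)
        fsa_step(m, "C2", time=1)
        assert [e.condition for e in m.event_log] == ["C1", "C2"]


class TestDeviceQueues:
    def test_fifo_pop_order_matches_push_order(self):
        q = DeviceQueues([2, 0, 1])
        assert [q.pop_idle(), q.pop_idle(), q.pop_idle()] == [0, 1, 2]
        q.push_idle(2)
        q.push_idle(0)
        assert q.pop_idle() == 2

    def test_partition_violation_detected(self):
        q = DeviceQueues([0, 1])
        q.idle.pop()  # corrupt: device 1 vanishes
        with pytest.raises(ProtocolViolation, match="conservation"):
            q.assert_partition()


class TestCheckMemory:
    def test_zero_estimate_fits(self):
        d = DeviceProfile(0, 1000, 1.0)
        assert check_memory(0, d)

    def test_estimate_at_capacity_with_threshold_suspends(self):
        d = DeviceProfile(0, 1000, 1.0)
        assert not check_memory(1000, d, threshold_fraction=0.9)

    def test_monotone_in_estimate(self):
        d = DeviceProfile(0, 1000, 1.0)
        sizes = np.arange(0, 2000, 50)
        fits = [check_memory(int(s), d) for s in sizes]
        # once it stops fitting it never fits again
        assert fits == sorted(fits, reverse=True)


class TestAssignJobs:
    def test_capacity_proportional_largest_remainder(self):
        devices = [
            DeviceProfile(0, 12 * GB, 5.0, "titan-xp"),
            DeviceProfile(1, 6 * GB, 2.0, "gtx1060"),
            DeviceProfile(2, 4 * GB, 1.0, "gtx1050"),
        ]
        mm = MemoryModel(view_bytes=1024)
        jq = assign_jobs(list(range(36)), devices, mm)
        assert jq.sizes() == {0: 20, 1: 10, 2: 6}
        assert jq.pending == []
        all_views = sorted(v for p in jq.payloads.values() for v in p)
        assert all_views == list(range(36))

    def test_single_device_takes_everything(self):
        jq = assign_jobs(
            list(range(7)), [DeviceProfile(0, GB, 1.0)], MemoryModel(1024)
        )
        assert jq.sizes() == {0: 7} and jq.pending == []

    def test_equal_capacities_split_evenly(self):
        devices = [DeviceProfile(0, GB, 1.0), DeviceProfile(1, GB, 1.0)]
        jq = assign_jobs(list(range(10)), devices, MemoryModel(1024))
        assert jq.sizes() == {0: 5, 1: 5}

    def test_capacity_cap_spills_to_pending(self):
        devices = [DeviceProfile(0, 10 * 1024, 1.0), DeviceProfile(1, 10 * 1024, 1.0)]
        mm = MemoryModel(view_bytes=1024, threshold_fraction=1.0)
        jq = assign_jobs(list(range(30)), devices, mm)
        assert sum(jq.sizes().values()) == 20
        assert len(jq.pending) == 10

    def test_block_too_big_for_every_device(self):
        with pytest.raises(CapacityError):
            assign_jobs([0], [DeviceProfile(0, 100, 1.0)], MemoryModel(1024))


@pytest.fixture(scope="module")
def reference(small_projections, small_geom, small_grid, small_subsets):
    rule = StoppingRule(rmse_threshold=1e-9, max_iterations=3)
    image, _ = run_os_mltr(
        small_projections, small_geom, small_grid, small_subsets, rule
    )
    return image, rule


class TestScheduledReconstruction:
    @pytest.mark.parametrize("variant", ["fifo", "jobq"])
    def test_equivalence_with_single_worker(
        self, variant, reference, small_projections, small_geom, small_grid,
        small_subsets,
    ):
        ref_image, rule = reference
        res = run_scheduled_reconstruction(
            small_projections, small_geom, small_grid, small_subsets, rule,
            default_device_pool(), variant,
        )
        scale = np.max(np.abs(ref_image))
        assert np.max(np.abs(res.image - ref_image)) <= 1e-8 * scale
        validate_trace(res, variant)

    @pytest.mark.parametrize("variant", ["fifo", "jobq"])
    def test_device_conservation_at_every_event(
        self, variant, reference, small_projections, small_geom, small_grid,
        small_subsets,
    ):
        _, rule = reference
        res = run_scheduled_reconstruction(
            small_projections, small_geom, small_grid, small_subsets, rule,
            default_device_pool(), variant,
        )
        ids = {d.device_id for d in default_device_pool()}
        assert len(res.queue_snapshots) == len(res.events)
        for snap in res.queue_snapshots:
            members = snap["idle"] + snap["suspended"] + snap["busy"]
            assert sorted(members) == sorted(ids)

    def test_single_device_fifo_outer_trace_cycles(
        self, small_projections, small_geom, small_grid,
    ):
        """With one device the outer machine cycles S2→S3→S4→S2 once per
        dispatched view."""
        subsets = partition_subsets(small_geom.n_views, 2)
        rule = StoppingRule(rmse_threshold=1e-9, max_iterations=1)
        res = run_scheduled_reconstruction(
            small_projections, small_geom, small_grid, subsets, rule,
            [DeviceProfile(0, GB, 1.0)], "fifo",
        )
        outer = [e for e in res.events if e.machine.startswith("OSEM_M")]
        dispatch = [
            e.condition for e in outer if e.condition in ("C4", "C6", "C5")
        ]
        # per view: C4 (S2→S3), C6 (S3→S4), C5 (S4→S2)
        assert len(dispatch) == 3 * small_geom.n_views
        assert dispatch == ["C4", "C6", "C5"] * small_geom.n_views
        validate_trace(res, "fifo")

    def test_tiny_memory_device_gets_suspended(
        self, small_projections, small_geom, small_grid, small_subsets,
    ):
        vb = view_bytes_estimate(small_geom, small_grid)
        devices = [
            DeviceProfile(0, vb * 50, 4.0, "big"),
            DeviceProfile(1, int(vb * 1.5), 1.0, "tiny"),
        ]
        rule = StoppingRule(rmse_threshold=1e-9, max_iterations=1)
        res = run_scheduled_reconstruction(
            small_projections, small_geom, small_grid, small_subsets, rule,
            devices, "fifo", memory_model=MemoryModel(view_bytes=vb),
        )
        suspended_ever = {
            d for snap in res.queue_snapshots for d in snap["suspended"]
        }
        assert 1 in suspended_ever
        validate_trace(res, "fifo")

    def test_refinement_token_is_exclusive(
        self, reference, small_projections, small_geom, small_grid, small_subsets,
    ):
        _, rule = reference
        for variant in ("fifo", "jobq"):
            res = run_scheduled_reconstruction(
                small_projections, small_geom, small_grid, small_subsets,
                rule, default_device_pool(), variant,
            )
            intervals = sorted(res.token_history)
            assert intervals, "token never used"
            for (a0, a1, _), (b0, b1, _) in zip(intervals, intervals[1:]):
                assert a1 <= b0  # no overlap

    def test_block_exceeding_every_device_capacity(
        self, small_projections, small_geom, small_grid, small_subsets,
    ):
        rule = StoppingRule(rmse_threshold=1e-9, max_iterations=1)
        with pytest.raises(CapacityError):
            run_scheduled_reconstruction(
                small_projections, small_geom, small_grid, small_subsets,
                rule, [DeviceProfile(0, 10, 1.0)], "fifo",
                memory_model=MemoryModel(view_bytes=1000),
            )

    def test_events_tsv_render(
        self, reference, small_projections, small_geom, small_grid, small_subsets,
    ):
        _, rule = reference
        res = run_scheduled_reconstruction(
            small_projections, small_geom, small_grid, small_subsets, rule,
            default_device_pool(), "jobq",
        )
        text = events_tsv(res.events)
        lines = text.strip().splitlines()
        assert lines[0].split("\t") == [
            "time", "machine", "from_state", "condition", "to_state", "device_id",
        ]
        assert len(lines) == len(res.events) + 1


class TestTimeline:
    def test_homogeneous_pools_make_both_policies_equal(self):
        devices = [DeviceProfile(i, GB, 2.0) for i in range(3)]
        f = simulate_timeline([12, 12], devices, "fifo")
        j = simulate_timeline([12, 12], devices, "jobq")
        assert f.makespan == pytest.approx(j.makespan)

    def test_single_device_makespan_is_total_work(self):
        d = [DeviceProfile(0, GB, 4.0)]
        cost = CostModel(nnz_estimate=8.0)
        for variant in ("fifo", "jobq"):
            res = simulate_timeline([5, 3], d, variant, cost)
            assert res.makespan == pytest.approx(8 * 8.0 / 4.0)
            assert res.idle[0] == pytest.approx(0.0)

    def test_five_to_one_hand_enumerated_schedule(self):
        """2 devices, 4 tasks, throughputs 5:1 (cost 0.2 vs 1.0).

        FIFO with completions harvested in dispatch order: the fast device's
        second task cannot start before the slow device's first task is
        harvested → finishes at t=2.0. Job queue splits 3:1 by capacity →
        max(3·0.2, 1·1.0) = 1.0."""
        devices = [
            DeviceProfile(0, 5 * GB, 5.0, "fast"),
            DeviceProfile(1, 1 * GB, 1.0, "slow"),
        ]
        f = simulate_timeline([4], devices, "fifo")
        j = simulate_timeline([4], devices, "jobq")
        assert f.makespan == pytest.approx(2.0)
        assert j.makespan == pytest.approx(1.0)
        assert f.idle[0] > j.idle[0]

    def test_fast_device_idles_more_under_fifo(self):
        """Titan-class vs GTX-1050-class (throughput 5:1): the FIFO queue
        leaves the fast device waiting for the slow one."""
        devices = [
            DeviceProfile(0, 12 * GB, 5.0, "titan-class"),
            DeviceProfile(1, 4 * GB, 1.0, "gtx1050-class"),
        ]
        f = simulate_timeline([36], devices, "fifo")
        j = simulate_timeline([36], devices, "jobq")
        assert f.idle[0] > j.idle[0]
        assert j.makespan <= f.makespan

    def test_jobq_never_slower_on_random_heterogeneous_pools(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            pool = random_device_pool(rng, int(rng.integers(2, 5)))
            f = simulate_timeline([36] * 2, pool, "fifo")
            j = simulate_timeline([36] * 2, pool, "jobq")
            assert j.makespan <= f.makespan + 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_timeline([4], [], "fifo")
        with pytest.raises(ValueError):
            simulate_timeline([4], default_device_pool(), "rand")
        with pytest.raises(ValueError):
            simulate_timeline([0], default_device_pool(), "fifo")
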