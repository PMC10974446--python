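"""Event-triggered finite-state-automaton scheduling of OS-MLTR over
heterogeneous simulated devices.

Three automata coordinate each subset cycle: an outer machine (``OSEM_M``)
that owns the subset loop and the refinement step, a stage-1 machine
(``OSEM_Inner_S1``) that dispatches on-the-fly system-matrix computation to
devices, and a stage-2 machine (``OSEM_Inner_S2``) that performs the
forward-project/accumulate refinement work under a mutual-exclusion token on
the current predicted image. Two scheduling regimes are provided:

``fifo``
    Devices are dispensed from a first-in-first-out idle queue, one view at
    a time. A device accumulates computed view blocks in its simulated
    memory; when the next block would exceed its memory threshold the device
    is suspended (the view returns to the pending list) and is later drained
    by the stage-2 machine, which accumulates its held blocks into the
    device's partial U1/U2 images and frees the memory. A slow device at the
    head of the queue blocks faster ones — the head-of-line effect the
    job-queue regime removes.

``jobq``
    Each device receives an up-front payload of views sized proportionally
    to its memory capacity (largest-remainder rounding, capped by capacity);
    views that fit nowhere stay pending until the round's refinement work
    frees memory. Devices proceed independently within a round.

"Devices" here are simulated workers described by :class:`DeviceProfile`;
the automata are pure control flow and are driven by a deterministic
orchestrator that interleaves worker progress as a discrete sequence of
events. The transition tables are bundled data, so a run's event log can be
validated against them transition by transition. The scheduling layer never
changes the mathematics: per-device partial accumulators are reduced at each
subset boundary before the refinement update, so the scheduled
reconstruction equals the single-worker loop up to summation order.

A separate discrete-event timeline model (:func:`simulate_timeline`)
abstracts task durations as ``nnz / throughput`` and quantifies the
makespan and idle-time difference between the two regimes without running
any reconstruction.
"""

from __future__ import annotations

import importlib.resources
import io
import json
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageGrid, OrderedSubsets, ScanGeometry
from .mltr_core import (
    IterationRecord,
    ProjectionSet,
    ReconState,
    StoppingRule,
    _total_log_likelihood,
    check_stopping,
    refine_update,
    run_os_mltr,
    subset_accumulate,
)
from .projector import (
    ENTRY_BYTES,
    RowSums,
    compute_row_sums,
    compute_view_matrix,
)

__all__ = [
    "DeviceProfile",
    "DeviceQueues",
    "JobQueue",
    "FsaMachine",
    "FsaEvent",
    "SyncFlags",
    "MemoryModel",
    "CostModel",
    "ProtocolViolation",
    "CapacityError",
    "build_machines",
    "fsa_step",
    "check_memory",
    "assign_jobs",
    "run_scheduled_reconstruction",
    "simulate_timeline",
    "default_device_pool",
    "random_device_pool",
    "view_bytes_estimate",
    "events_tsv",
]

VARIANTS = ("fifo", "jobq")
MACHINE_IDS = ("OSEM_M", "OSEM_Inner_S1", "OSEM_Inner_S2")

#: Default fraction of device memory usable for view blocks.
DEFAULT_MEM_THRESHOLD = 0.9

#: Device classes the default pool is drawn from: (memory, relative
#: throughput). Memory is in simulated bytes, scaled to desk size (MB where
#: the modelled cards have GB); throughput follows the cards' core counts.
DEVICE_CLASSES = {
    "titan-xp": (12 * 2**20, 3840.0),
    "gtx1060": (6 * 2**20, 1280.0),
    "gtx1050": (4 * 2**20, 768.0),
}


class ProtocolViolation(RuntimeError):
    """An automaton was asked to take a transition its table does not allow
    from its current state — a scheduling-order bug, surfaced not swallowed."""


class CapacityError(ValueError):
    """A single view block exceeds every device's usable memory."""


# ---------------------------------------------------------------------------
# Devices and queues


@dataclass(frozen=True)
class DeviceProfile:
    """A simulated worker: memory capacity (bytes) and relative throughput
    (system-matrix weights per unit time)."""

    device_id: int
    memory_capacity: int
    relative_throughput: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.memory_capacity <= 0:
            raise ValueError("memory_capacity must be > 0")
        if self.relative_throughput <= 0:
            raise ValueError("relative_throughput must be > 0")


def default_device_pool() -> list[DeviceProfile]:
    """Three-device heterogeneous pool patterned on a Titan-Xp, a GTX-1060
    and a GTX-1050 (memory scaled to desk size)."""
    return [
        DeviceProfile(i, mem, thr, name)
        for i, (name, (mem, thr)) in enumerate(DEVICE_CLASSES.items())
    ]


def random_device_pool(
    rng: np.random.Generator, n_devices: int = 3
) -> list[DeviceProfile]:
    """Randomized heterogeneous pool: each device is a class draw with a
    joint ±20% scale jitter on memory and throughput, keeping the two
    correlated as they are across real GPU product lines."""
    names = list(DEVICE_CLASSES)
    pool = []
    for i in range(n_devices):
        name = names[rng.integers(len(names))]
        mem, thr = DEVICE_CLASSES[name]
        u = rng.uniform(0.8, 1.2)
        pool.append(
            DeviceProfile(i, max(1, int(mem * u)), thr * u, f"{name}~{u:.2f}")
        )
    return pool


class DeviceQueues:
    """FIFO idle and suspended queues plus the busy set.

    At every event the three structures partition the device pool; the
    orchestrator asserts this after each logged transition.
    """

    def __init__(self, device_ids):
        self.all_ids = frozenset(device_ids)
        self.idle: deque[int] = deque(sorted(self.all_ids))
        self.suspended: deque[int] = deque()
        self.busy: set[int] = set()

    def pop_idle(self) -> int:
        d = self.idle.popleft()
        self.busy.add(d)
        return d

    def pop_suspended(self) -> int:
        d = self.suspended.popleft()
        self.busy.add(d)
        return d

    def push_idle(self, d: int) -> None:
        self.busy.discard(d)
        self.idle.append(d)

    def push_suspended(self, d: int) -> None:
        self.busy.discard(d)
        self.suspended.append(d)

    def assert_partition(self) -> None:
        seen = list(self.idle) + list(self.suspended) + list(self.busy)
        if len(seen) != len(self.all_ids) or set(seen) != self.all_ids:
            raise ProtocolViolation(
                f"device conservation violated: idle={list(self.idle)} "
                f"suspended={list(self.suspended)} busy={sorted(self.busy)} "
                f"pool={sorted(self.all_ids)}"
            )

    def snapshot(self) -> dict:
        return {
            "idle": tuple(self.idle),
            "suspended": tuple(self.suspended),
            "busy": tuple(sorted(self.busy)),
        }


@dataclass
class JobQueue:
    """Per-device view payloads for one round of a subset — the JOB_Q(n1,
    n2, n3) structure — plus the views left pending for later rounds."""

    payloads: dict[int, list[int]]
    pending: list[int]

    def sizes(self) -> dict[int, int]:
        return {d: len(v) for d, v in self.payloads.items()}


@dataclass
class SyncFlags:
    """Thread-synchronization variables of the job-queue regime. The
    current-guess token is a mutual-exclusion contract: at most one consumer
    holds it at any time."""

    device_idle: dict[int, bool] = field(default_factory=dict)
    last_projection_done: bool = False
    current_guess_ready: bool = True
    refinement_done: bool = False


# ---------------------------------------------------------------------------
# Automata


@dataclass(frozen=True)
class FsaEvent:
    time: int
    machine: str
    from_state: str
    condition: str
    to_state: str
    device_id: int | None = None


class FsaMachine:
    """One automaton: a declared state set, a condition-indexed transition
    table, a current state and an ordered event log."""

    def __init__(
        self,
        machine_id: str,
        states: dict[str, str],
        transitions: dict[str, tuple[str, str, str]],
        unlisted_states: tuple[str, ...] = (),
        initial_state: str = "S0",
    ):
        self.machine_id = machine_id
        self.states = dict(states)
        self.unlisted_states = tuple(unlisted_states)
        self.transitions = {
            c: (frm, to, desc) for c, (frm, to, desc) in transitions.items()
        }
        known = set(self.states) | set(self.unlisted_states)
        for c, (frm, to, _) in self.transitions.items():
            if frm not in known or to not in known:
                raise ValueError(
                    f"{machine_id}: transition {c} references undeclared "
                    f"state ({frm}→{to})"
                )
        self.current_state = initial_state
        self.event_log: list[FsaEvent] = []

    def step(self, condition: str, time: int, device_id: int | None = None) -> FsaEvent:
        if condition not in self.transitions:
            raise ProtocolViolation(
                f"{self.machine_id}: unknown condition {condition}"
            )
        frm, to, _ = self.transitions[condition]
        if frm != self.current_state:
            raise ProtocolViolation(
                f"{self.machine_id}: condition {condition} applies in state "
                f"{frm}, machine is in {self.current_state}"
            )
        ev = FsaEvent(time, self.machine_id, frm, condition, to, device_id)
        self.current_state = to
        self.event_log.append(ev)
        return ev


def _load_tables() -> dict:
    ref = importlib.resources.files("osmltr") / "data" / "fsa_tables.json"
    return json.loads(ref.read_text())


def build_machines(variant: str) -> dict[str, FsaMachine]:
    """Instantiate the three automata of one scheduling regime from the
    bundled transition tables."""
    tables = _load_tables()
    if variant not in tables:
        raise ValueError(f"unknown scheduler variant {variant!r}; use fifo or jobq")
    machines = {}
    for mid in MACHINE_IDS:
        spec = tables[variant][mid]
        machines[mid] = FsaMachine(
            machine_id=f"{mid}/{variant}",
            states=spec["states"],
            transitions={c: tuple(t) for c, t in spec["transitions"].items()},
            unlisted_states=tuple(spec.get("unlisted_states", ())),
        )
    return machines


def fsa_step(
    machine: FsaMachine, condition: str, time: int = 0, device_id: int | None = None
) -> FsaEvent:
    """Advance one machine by one condition; raises
    :class:`ProtocolViolation` if the condition does not apply in the
    machine's current state."""
    return machine.step(condition, time, device_id)


def events_tsv(events: list[FsaEvent]) -> str:
    """Render an event log as TSV (time, machine, from, condition, to, device)."""
    buf = io.StringIO()
    buf.write("time\tmachine\tfrom_state\tcondition\tto_state\tdevice_id\n")
    for e in events:
        dev = "" if e.device_id is None else str(e.device_id)
        buf.write(
            f"{e.time}\t{e.machine}\t{e.from_state}\t{e.condition}\t"
            f"{e.to_state}\t{dev}\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Memory model and job assignment


@dataclass(frozen=True)
class MemoryModel:
    """Simulated memory cost of holding view blocks on a device."""

    view_bytes: int
    threshold_fraction: float = DEFAULT_MEM_THRESHOLD

    def capacity_views(self, device: DeviceProfile) -> int:
        """How many view blocks fit under the device's usable memory."""
        return int(
            self.threshold_fraction * device.memory_capacity // self.view_bytes
        )


def view_bytes_estimate(geom: ScanGeometry, grid: ImageGrid) -> int:
    """Upper-bound memory estimate of one view's sparse block: each ray
    crosses at most ~2n pixels of an n×n grid, each entry costing
    ``ENTRY_BYTES``."""
    return geom.n_det * 2 * grid.n * ENTRY_BYTES


def check_memory(
    estimate_bytes: int,
    device: DeviceProfile,
    threshold_fraction: float = DEFAULT_MEM_THRESHOLD,
) -> bool:
    """True when ``estimate_bytes`` fits under the device's memory
    threshold; False means the device must be suspended."""
    if estimate_bytes < 0:
        raise ValueError("estimate must be non-negative")
    return estimate_bytes <= threshold_fraction * device.memory_capacity


def _largest_remainder(total: int, weights: list[float]) -> list[int]:
    """Apportion ``total`` items proportionally to ``weights`` (largest
    remainder; ties broken by list order)."""
    w = np.asarray(weights, dtype=float)
    quota = total * w / w.sum()
    base = np.floor(quota).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(quota - base), kind="stable")
    for k in range(rem):
        base[order[k]] += 1
    return base.tolist()


def assign_jobs(
    subset_views: list[int],
    devices: list[DeviceProfile],
    memory_model: MemoryModel,
) -> JobQueue:
    """Split a subset's views into per-device payloads for one round.

    Payload sizes follow memory capacity (largest-remainder rounding), then
    are capped so each device's concurrent blocks fit its usable memory;
    capped-off views are offered to devices with spare room before going to
    the pending list for the next round.
    """
    views = list(subset_views)
    if not views:
        raise ValueError("subset must be non-empty")
    caps = [memory_model.capacity_views(d) for d in devices]
    if max(caps) < 1:
        raise CapacityError(
            f"a single view block of {memory_model.view_bytes} bytes fits no "
            "device in the pool"
        )
    sizes = _largest_remainder(len(views), [d.memory_capacity for d in devices])
    sizes = [min(s, c) for s, c in zip(sizes, caps)]
    spare_order = sorted(
        range(len(devices)), key=lambda i: -devices[i].memory_capacity
    )
    leftover = len(views) - sum(sizes)
    for i in spare_order:
        if leftover <= 0:
            break
        room = caps[i] - sizes[i]
        take = min(room, leftover)
        sizes[i] += take
        leftover -= take
    payloads: dict[int, list[int]] = {}
    cursor = 0
    for d, s in zip(devices, sizes):
        payloads[d.device_id] = views[cursor : cursor + s]
        cursor += s
    return JobQueue(payloads=payloads, pending=views[cursor:])


# ---------------------------------------------------------------------------
# Scheduled reconstruction


class _Coordinator:
    """Shared bookkeeping: machines, queues, logical clock, token."""

    def __init__(self, variant: str, devices: list[DeviceProfile]):
        self.variant = variant
        self.machines = build_machines(variant)
        self.queues = DeviceQueues([d.device_id for d in devices])
        self.devices = {d.device_id: d for d in devices}
        self.clock = 0
        self.events: list[FsaEvent] = []
        self.snapshots: list[dict] = []
        self.token_holder: int | None = None
        self.token_history: list[tuple[int, int, int]] = []  # (t_acq, t_rel, dev)
        self._token_acquired_at: int | None = None

    def step(self, machine_id: str, condition: str, device_id: int | None = None):
        ev = self.machines[machine_id].step(condition, self.clock, device_id)
        self.events.append(ev)
        self.queues.assert_partition()
        self.snapshots.append(self.queues.snapshot())
        self.clock += 1
        return ev

    def acquire_token(self, device_id: int) -> None:
        if self.token_holder is not None:
            raise ProtocolViolation(
                f"current-guess token already held by device "
                f"{self.token_holder}, requested by {device_id}"
            )
        self.token_holder = device_id
        self._token_acquired_at = self.clock

    def release_token(self, device_id: int) -> None:
        if self.token_holder != device_id:
            raise ProtocolViolation(
                f"device {device_id} released a token it does not hold"
            )
        self.token_history.append((self._token_acquired_at, self.clock, device_id))
        self.token_holder = None
        self._token_acquired_at = None


@dataclass
class ScheduledResult:
    """Outcome of an FSA-coordinated reconstruction."""

    image: np.ndarray
    log: list[IterationRecord]
    events: list[FsaEvent]
    machines: dict[str, FsaMachine]
    queue_snapshots: list[dict]
    token_history: list[tuple[int, int, int]]


def _drain_device(
    coord: _Coordinator,
    d: int,
    held: dict[int, list],
    used: dict[int, int],
    partials: dict[int, ReconState],
    mu: np.ndarray,
    ts: np.ndarray,
    proj: ProjectionSet,
) -> None:
    """Stage-2 work for one suspended device: under the current-guess token,
    accumulate every held view block into the device's partial U1/U2 and
    free the simulated memory."""
    coord.step("OSEM_Inner_S2", "C1", d)  # suspended queue not empty
    coord.step("OSEM_Inner_S2", "C3", d)  # current predicted image ready
    popped = coord.queues.pop_suspended()
    if popped != d:
        raise ProtocolViolation("suspended queue popped out of FIFO order")
    coord.acquire_token(d)
    coord.step("OSEM_Inner_S2", "C5", d)  # draw device, assign token
    coord.step("OSEM_Inner_S2", "C7", d)  # launch refinement task
    st = partials[d]
    st.mu = mu  # read-only view of the shared current guess
    for v, vm in held[d]:
        subset_accumulate(st, vm, ts[v], proj.y[v], proj.blank_for_view(v))
    held[d].clear()
    used[d] = 0
    coord.step("OSEM_Inner_S2", "C9", d)  # thread task complete
    coord.release_token(d)
    coord.step("OSEM_Inner_S2", "C10", d)  # device back to idle
    coord.queues.push_idle(d)


def _fifo_subset_cycle(
    coord: _Coordinator,
    views: list[int],
    mu: np.ndarray,
    ts: np.ndarray,
    proj: ProjectionSet,
    geom: ScanGeometry,
    grid: ImageGrid,
    memory_model: MemoryModel,
    partials: dict[int, ReconState],
) -> None:
    """One subset under the FIFO device-queue regime.

    Accumulates the subset's contributions into ``partials`` (per device);
    the caller reduces and refines. OSEM_M is assumed to be in S2 on entry
    and is left in S2 (after the outer refinement walk is handled by the
    caller)."""
    devices = coord.devices
    held: dict[int, list] = {d: [] for d in devices}
    used: dict[int, int] = {d: 0 for d in devices}
    pending = deque(views)
    if not any(
        check_memory(memory_model.view_bytes, dev, memory_model.threshold_fraction)
        for dev in devices.values()
    ):
        raise CapacityError(
            "a single view block fits no device in the pool"
        )

    while pending:
        if coord.queues.idle:
            d = coord.queues.pop_idle()
            coord.step("OSEM_M", "C4", d)  # idle queue not empty
            coord.step("OSEM_M", "C6", d)  # inner-loop function launched
            coord.step("OSEM_Inner_S1", "C4", d)  # idle queue not empty
            coord.step("OSEM_Inner_S1", "C6", d)  # candidate device obtained
            coord.step("OSEM_Inner_S1", "C8", d)  # check onboard memory
            coord.step("OSEM_Inner_S1", "C9", d)  # wait for the check
            v = pending[0]
            fits = check_memory(
                used[d] + memory_model.view_bytes,
                devices[d],
                memory_model.threshold_fraction,
            )
            if not fits:
                # Over the limit: abandon the subset index, suspend device.
                coord.step("OSEM_Inner_S1", "C10", d)
                coord.queues.push_suspended(d)
                coord.step("OSEM_Inner_S1", "C12", d)
            else:
                pending.popleft()
                coord.step("OSEM_Inner_S1", "C11", d)  # launch OTFSM task
                vm = compute_view_matrix(geom, grid, v)
                held[d].append((v, vm))
                used[d] += memory_model.view_bytes
                coord.step("OSEM_Inner_S1", "C13", d)
                coord.step("OSEM_Inner_S1", "C15", d)
                coord.queues.push_idle(d)
            coord.step("OSEM_M", "C5", d)  # inner loop completed
        elif coord.queues.suspended:
            coord.step("OSEM_M", "C3")  # idle queue is empty
            d = coord.queues.suspended[0]
            _drain_device(coord, d, held, used, partials, mu, ts, proj)
        else:  # pragma: no cover - sequential orchestration keeps a device free
            raise ProtocolViolation("no idle or suspended device but work pending")

    # End of subset: every device still holding blocks is suspended through
    # the stage-1 walk (end-of-subset acts as the memory barrier) and drained
    # so all partials are complete before the refinement step.
    still_idle: list[int] = []
    while coord.queues.idle:
        d = coord.queues.pop_idle()
        if held[d]:
            coord.step("OSEM_Inner_S1", "C4", d)
            coord.step("OSEM_Inner_S1", "C6", d)
            coord.step("OSEM_Inner_S1", "C8", d)
            coord.step("OSEM_Inner_S1", "C9", d)
            coord.step("OSEM_Inner_S1", "C10", d)
            coord.queues.push_suspended(d)
            coord.step("OSEM_Inner_S1", "C12", d)
        else:
            still_idle.append(d)
    for d in still_idle:
        coord.queues.push_idle(d)
    while coord.queues.suspended:
        d = coord.queues.suspended[0]
        _drain_device(coord, d, held, used, partials, mu, ts, proj)

    # Last projection of the subset done: stop the stage-1 machine.
    coord.step("OSEM_Inner_S1", "C2")
    coord.step("OSEM_Inner_S1", "C14")
    coord.step("OSEM_Inner_S1", "C15")


def _jobq_subset_cycle(
    coord: _Coordinator,
    views: list[int],
    mu: np.ndarray,
    ts: np.ndarray,
    proj: ProjectionSet,
    geom: ScanGeometry,
    grid: ImageGrid,
    memory_model: MemoryModel,
    partials: dict[int, ReconState],
) -> None:
    """One subset under the job-queue regime: rounds of capacity-sized
    payloads; each device computes its payload's blocks, then accumulates
    them under the current-guess token, freeing memory for the next round."""
    devices = list(coord.devices.values())
    remaining = list(views)
    coord.step("OSEM_M", "C4")  # inner-loop launch (device queue bypassed)
    coord.step("OSEM_M", "C6")
    while remaining:
        jq = assign_jobs(remaining, devices, memory_model)
        progressed = False
        for dev in devices:
            d = dev.device_id
            payload = jq.payloads.get(d, [])
            if not payload:
                coord.step("OSEM_Inner_S1", "C2", d)  # device idle flag true
                coord.step("OSEM_Inner_S1", "C5", d)  # nothing queued: back
                continue
            progressed = True
            # jobq bypasses the FIFO discipline: the device is taken directly.
            coord.queues.idle.remove(d)
            coord.queues.busy.add(d)
            coord.step("OSEM_Inner_S1", "C2", d)  # device idle flag true
            coord.step("OSEM_Inner_S1", "C4", d)  # degree indices → job queue
            coord.step("OSEM_Inner_S1", "C7", d)  # SM-calculation task created
            blocks = [(v, compute_view_matrix(geom, grid, v)) for v in payload]
            coord.step("OSEM_Inner_S1", "C9", d)  # SM task completed → pending
            coord.step("OSEM_Inner_S1", "C10", d)  # device awaits refinement
            coord.step("OSEM_Inner_S2", "C2", d)  # SM calculation complete
            coord.acquire_token(d)
            coord.step("OSEM_Inner_S2", "C4", d)  # guess ready; refine task
            coord.step("OSEM_Inner_S2", "C6", d)
            st = partials[d]
            st.mu = mu
            for v, vm in blocks:
                subset_accumulate(st, vm, ts[v], proj.y[v], proj.blank_for_view(v))
            coord.step("OSEM_Inner_S2", "C8", d)  # refinement complete
            coord.release_token(d)
            coord.step("OSEM_Inner_S2", "C9", d)  # device idle again
            coord.queues.push_idle(d)
        if not progressed:  # pragma: no cover - assign_jobs guarantees progress
            raise CapacityError("job assignment made no progress")
        remaining = jq.pending
    coord.step("OSEM_Inner_S1", "C3")  # last projection of the subset
    coord.step("OSEM_Inner_S1", "C11")  # wait for refinement completion
    coord.step("OSEM_M", "C7")  # inner loop not yet complete
    coord.step("OSEM_M", "C5")  # inner loop completed


def run_scheduled_reconstruction(
    proj: ProjectionSet,
    geom: ScanGeometry,
    grid: ImageGrid,
    subsets: OrderedSubsets,
    rule: StoppingRule,
    devices: list[DeviceProfile],
    variant: str,
    memory_model: MemoryModel | None = None,
    row_sums: RowSums | None = None,
) -> ScheduledResult:
    """OS-MLTR with the subset work coordinated by the chosen FSA regime.

    Per-device partial U1/U2 images are reduced at each subset boundary
    before the refinement update, so the result matches
    :func:`osmltr.mltr_core.run_os_mltr` up to floating-point summation
    order. Event logs, queue snapshots and the token history are returned
    for auditing.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown scheduler variant {variant!r}")
    if not devices:
        raise ValueError("at least one device is required")
    if memory_model is None:
        memory_model = MemoryModel(view_bytes=view_bytes_estimate(geom, grid))

    if row_sums is None:
        row_sums = compute_row_sums(geom, grid)
    ts = row_sums.ts

    coord = _Coordinator(variant, devices)
    coord.step("OSEM_M", "C1")
    coord.step("OSEM_M", "C2")
    coord.step("OSEM_Inner_S1", "C1")

    state = ReconState.zeros(grid)
    log: list[IterationRecord] = []
    cycle = _fifo_subset_cycle if variant == "fifo" else _jobq_subset_cycle

    while True:
        prev_mu = state.mu.copy()
        for s, views in enumerate(subsets):
            partials = {
                d.device_id: ReconState.zeros(grid) for d in devices
            }
            cycle(
                coord, list(views), state.mu, ts, proj, geom, grid,
                memory_model, partials,
            )
            coord.step("OSEM_M", "C8")  # inner complete → outer (S2→S5)
            coord.step("OSEM_M", "C9")  # outer-loop function launched
            # Reduction: per-device partials → global accumulators.
            state.reset_accumulators()
            for d in sorted(partials):
                state.u1 += partials[d].u1
                state.u2 += partials[d].u2
            refine_update(state)
            coord.step("OSEM_M", "C11")  # outer loop completed
            coord.step("OSEM_M", "C2")  # rebuild queues for the next subset
            if variant == "jobq":
                coord.step("OSEM_Inner_S1", "C12")  # refinement done → idle
        state.iter_count += 1
        L = _total_log_likelihood(proj, geom, grid, state.mu)
        rmse = float(np.sqrt(np.mean((state.mu - prev_mu) ** 2)))
        log.append(
            IterationRecord(
                iteration=state.iter_count,
                subset=subsets.n_subsets - 1,
                log_likelihood=L,
                rmse_consecutive=rmse,
                negatives_count=int(np.sum(state.mu < 0)),
            )
        )
        if check_stopping(prev_mu, state.mu, rule, state.iter_count):
            break

    return ScheduledResult(
        image=state.mu,
        log=log,
        events=coord.events,
        machines=coord.machines,
        queue_snapshots=coord.snapshots,
        token_history=coord.token_history,
    )


def reconstruct(
    proj: ProjectionSet,
    geom: ScanGeometry,
    grid: ImageGrid,
    subsets: OrderedSubsets,
    rule: StoppingRule,
    scheduler: str = "single",
    devices: list[DeviceProfile] | None = None,
    **kwargs,
):
    """Dispatch to the single-worker loop or an FSA-scheduled run."""
    if scheduler == "single":
        image, log = run_os_mltr(proj, geom, grid, subsets, rule, **kwargs)
        return ScheduledResult(
            image=image, log=log, events=[], machines={},
            queue_snapshots=[], token_history=[],
        )
    if devices is None:
        devices = default_device_pool()
    return run_scheduled_reconstruction(
        proj, geom, grid, subsets, rule, devices, scheduler, **kwargs
    )


# ---------------------------------------------------------------------------
# Discrete-event timeline model


@dataclass(frozen=True)
class CostModel:
    """Deterministic task-duration model: a view's system-matrix task costs
    ``nnz_estimate / relative_throughput`` time units on a device. With a
    fan covering the grid the per-view weight count is nearly
    view-independent, so a single constant is used."""

    nnz_estimate: float = 1.0

    def task_time(self, device: DeviceProfile) -> float:
        return self.nnz_estimate / device.relative_throughput


@dataclass
class TimelineResult:
    variant: str
    makespan: float
    busy: dict[int, float]
    idle: dict[int, float]
    trace: list[tuple[int, float, float, int]]  # (device, start, end, subset)


def simulate_timeline(
    subset_sizes: list[int],
    devices: list[DeviceProfile],
    variant: str,
    cost_model: CostModel = CostModel(),
) -> TimelineResult:
    """Discrete-event simulation of one scheduling regime.

    Tasks are the per-view system-matrix computations of each subset; a
    barrier (the refinement step) separates subsets. Under ``fifo`` a master
    dispatches one task at a time to the head of the idle device queue and
    harvests completions in dispatch order — the join-polling behaviour that
    makes fast devices wait behind a slow device dispatched earlier. Under
    ``jobq`` each device receives a capacity-proportional payload up front
    and runs independently until the barrier.

    Deterministic; returns the total makespan, per-device busy and idle
    time, and the task trace.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown scheduler variant {variant!r}")
    if not devices:
        raise ValueError("at least one device is required")
    busy = {d.device_id: 0.0 for d in devices}
    trace: list[tuple[int, float, float, int]] = []
    t0 = 0.0
    for s, size in enumerate(subset_sizes):
        if size < 1:
            raise ValueError("subset sizes must be positive")
        if variant == "fifo":
            t0 = _fifo_timeline(t0, s, size, devices, cost_model, busy, trace)
        else:
            t0 = _jobq_timeline(t0, s, size, devices, cost_model, busy, trace)
    idle = {d.device_id: t0 - busy[d.device_id] for d in devices}
    return TimelineResult(
        variant=variant, makespan=t0, busy=busy, idle=idle, trace=trace
    )


def _fifo_timeline(t0, subset, n_tasks, devices, cost_model, busy, trace):
    by_id = {d.device_id: d for d in devices}
    idle_q = deque(sorted(by_id))
    join_q: deque[tuple[int, float]] = deque()
    master = t0
    dispatched = harvested = 0
    while harvested < n_tasks:
        if dispatched < n_tasks and idle_q:
            d = idle_q.popleft()
            dt = cost_model.task_time(by_id[d])
            trace.append((d, master, master + dt, subset))
            busy[d] += dt
            join_q.append((d, master + dt))
            dispatched += 1
        else:
            d, fin = join_q.popleft()
            master = max(master, fin)
            harvested += 1
            idle_q.append(d)
    return master


def _jobq_timeline(t0, subset, n_tasks, devices, cost_model, busy, trace):
    sizes = _largest_remainder(n_tasks, [d.memory_capacity for d in devices])
    end = t0
    for d, k in zip(devices, sizes):
        dt = cost_model.task_time(d)
        fin = t0 + k * dt
        for i in range(k):
            trace.append((d.device_id, t0 + i * dt, t0 + (i + 1) * dt, subset))
        busy[d.device_id] += k * dt
        end = max(end, fin)
    return end
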