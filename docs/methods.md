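# Methods

## Forward model and reconstruction

The scanner model is a 2-D fan beam in the central slice: a point source at
distance `sod` from the isocenter, a flat equidistant detector at distance
`sid` from the source, and a square pixel grid centered on the isocenter.
View angle 0 places the source on the −x axis; angles are degrees,
counter-clockwise; all lengths are mm. Detector bin centers sit at
`(k − (n_det−1)/2)·det_pitch`, i.e. the fan is sampled symmetrically about
the central ray. Defaults follow a bench micro-CT (`sid = 127 mm`,
`sod = 78.5928 mm`, `det_pitch = 0.075 mm`) but every test and example uses
smaller, fully overridable desk-scale geometries.

Counts are monochromatic Beer–Lambert with Poisson statistics:
`ŷ_i = b_i exp(−Σ_j l_ij μ_j)` with a flat blank scan `b` (default 10⁴
counts per bin in simulation). The reconstruction maximises the Poisson
log-likelihood `L = Σ_i (y_i ln ŷ_i − ŷ_i)` with the additive MLTR update

    μ_j ← μ_j + U1_j / U2_j,
    U1_j = Σ_i l_ij (ŷ_i − y_i),   U2_j = Σ_i l_ij · ts_i · ŷ_i,

where `ts_i = Σ_h l_ih` is ray *i*'s full chord through the grid, computed
once before iterating. The placement of `ts` *inside* the backprojection sum
of U2 is deliberate: it is the separable-surrogate form that makes full
(1-subset) MLTR monotone in L, and the test suite asserts that monotonicity
numerically over 30 iterations.

Ordered subsets partition the view list by congruence class
(subset *s* = views ≡ *s* mod `n_subsets`), so each subset spans the full
arc. U1/U2 are reset at the start of every subset cycle; the update is
applied per subset. Choices worth stating:

- **Initial image** μ⁰ = 0.
- **Zero denominator**: pixels with `U2_j = 0` received no ray information
  in the subset and are left unchanged.
- **No nonnegativity clamp**: the additive update can drive pixels
  negative; the iteration log counts negative pixels instead of hiding
  them. (Clamping would break the fixed-point and adjointness properties
  the tests rely on.)
- **Stopping**: root-mean-square change between consecutive full-iteration
  images, strictly below the threshold, or an iteration cap. The default
  threshold 0.015 matches the bench protocol the geometry defaults come
  from; desk-scale tests use far smaller thresholds plus a cap because a
  16×16 phantom's consecutive RMSE falls below 0.015 almost immediately.
- **Overflow guard**: line integrals are clipped at ±700 before `exp`, so
  pathological inputs saturate instead of overflowing; within that range
  the model is exact.

Ordered subsets trade guaranteed monotonicity for speed and, on
underdetermined data, settle into a small limit cycle rather than a point.
On noiseless, fully sampled data the iteration converges to the
data-consistent solution, where the subset order no longer matters; the
order-insensitivity test therefore runs several hundred iterations before
comparing orders. At typical stopping points (10 iterations) images from
different subset orders differ at the 10⁻³ relative level.

## Projector

System-matrix weights `l_ij` are exact intersection lengths from a
parametric (Siddon-style) traversal: the ray is clipped to the grid
rectangle, all pixel-boundary crossing parameters are sorted, and each
inter-crossing segment is attributed to the pixel containing its midpoint.
Pixel intervals are half-open; segments shorter than 10⁻¹² of a pixel
(measure-zero corner touches) are dropped. Because the sorted crossing
parameters telescope, the weights of a ray sum to its clipped chord length
exactly up to float round-off — the suite checks 10³ random rays against
independent Liang–Barsky clipping at 10⁻⁶ relative.

One view's block is stored as a CSR matrix (`n_det × n_pixels`); forward
projection multiplies the block, backprojection its transpose, so the two
are an adjoint pair by construction (verified against dense oracles at
10⁻¹⁰). Blocks are recomputed on demand — the on-the-fly policy — and never
serialized; recomputation is stateless and bit-reproducible. The simulated
memory cost of a stored weight is 12 bytes (8-byte value + 4-byte index),
used only by the scheduler's memory model.

## FSA scheduling

The three automata (outer loop, stage-1 matrix computation, stage-2
refinement accumulation) are encoded as *data*: state lists and
condition-indexed transition tables bundled as JSON, loaded at run time.
This keeps the control flow auditable — every logged event can be checked
against the tables, and an orchestration bug surfaces as a
`ProtocolViolation`, never as silent misbehaviour. One printed
inconsistency is preserved deliberately: the job-queue stage-2 state list
omits S2 while its transition table routes through S2; the bundled data
keeps the printed list and records S2 as an unlisted state rather than
renumbering.

Devices are simulated workers (`DeviceProfile`: memory capacity, relative
throughput). The orchestrator drives them as a deterministic sequential
interleaving of events rather than OS threads. The synchronization contract
is a set of happens-before edges — payloads published before workers start;
all of a subset's partial U1/U2 reduced before the refinement update;
refinement finished before suspended work resumes — and a deterministic
interleaving honors all of them while making event logs, queue snapshots
and the single-worker equivalence exactly reproducible.

**FIFO regime.** Devices are dispensed from a FIFO idle queue one view at a
time. A device keeps its computed view blocks in simulated memory; when the
next block would push usage over `threshold_fraction × capacity` (default
0.9) the device is suspended, the triggering view returns to the pending
list, and the stage-2 machine later drains the device — accumulating its
held blocks into its partial U1/U2 under the current-guess token and
freeing the memory — before returning it to idle. End of subset acts as a
memory barrier: devices still holding blocks are suspended and drained the
same way so every partial is complete before refinement. Within a subset
the current guess is constant, so drain order cannot change the result.

**Job-queue regime.** Each round, the subset's remaining views are split
into per-device payloads proportional to memory capacity
(largest-remainder rounding, ties by device order), capped by how many
blocks fit under the device's usable memory; views that fit nowhere stay
pending for the next round, which begins after the round's accumulation has
freed memory. A single view block that fits no device at all raises a
capacity error.

In both regimes the per-device partial accumulators are reduced in device-id
order at the subset boundary, then the ordinary refinement update runs.
The only difference from the single-worker loop is floating-point summation
order, which is why the equivalence tests use a 10⁻⁸ relative tolerance.
The current-guess token is tracked explicitly (acquire/release intervals
are part of the result), making mutual exclusion checkable from the log.

## Timeline model

The discrete-event timeline abstracts a view's matrix computation as a task
of duration `nnz_estimate / relative_throughput`; a constant per-view
`nnz_estimate` is used because a fan covering the grid produces nearly
view-independent block sizes, and a constant makes the homogeneous-pool
FIFO/job-queue tie exact. Under FIFO the master dispatches one task at a
time to the queue head and harvests completions *in dispatch order* —
modelling join-based polling, where a fast device's completion is not acted
on while a slower, earlier-dispatched task is still running. This is the
head-of-line blocking mechanism; the job queue avoids it by handing each
device its whole payload up front, with a barrier (the refinement) between
subsets. Makespan, per-device busy/idle time and the task trace are
reported.

Randomized device pools for the dominance property draw each device from
three classes patterned on real cards (memory 12/6/4 GB, throughput
proportional to core counts 3840/1280/768) with a joint ±20% scale jitter
per device. Memory and throughput are jittered *together* because they are
correlated across real product lines; with capacity-proportional payloads
this correlation is what makes the job queue never slower than FIFO. A pool
whose slowest device had the largest memory would break that dominance, but
no realistic device class behaves that way.

## Synthetic phantom

The generator emulates a calcium-hydroxyapatite calibration phantom: a
resin background disk (μ = 0.02/mm, water-like) filling 88% of the grid
half-extent, housing five cylindrical inserts of densities 0, 100, 200,
400, 800 mg HA/cm³ at even 72° spacing on a ring at 55% of the background
radius, each insert 18% of the background radius. Density maps linearly to
attenuation at 6.25×10⁻⁵ (1/mm)/(mg/cm³), so the densest insert is
0.05/mm — a plausible magnitude at ~70 kV — and the insert ratios are
exactly 0:1:2:4:8. The physical phantom's insert layout is not public;
these fractions are this package's documented convention.

Rasterisation is by pixel center with no anti-aliasing (innermost shape
wins), keeping geometric oracles exact at the cost of staircase edges.
Projections reuse the reconstruction's own forward model; Poisson noise is
drawn with a seeded generator, so fixtures are bit-reproducible.

The simulation is deliberately idealised: monochromatic beam, no scatter,
no detector blur or afterglow, no geometric misalignment, no beam-hardening
or cupping. Passing tests therefore demonstrate correctness of the
algorithmic chain (projector ↔ model ↔ scheduler), not robustness to the
physics a real scanner adds; insert-recovery accuracy on real data would be
limited by those unmodelled effects well before the 10% level the synthetic
round trip achieves.

## Problem sizes

Unit fixtures use 16×16 grids with 20–40 views and 24–32 detector bins —
small enough for dense oracles and exhaustive traces. The end-to-end
recovery check scales the bench protocol down to a 128×128 grid, 60 views,
10 subsets and 10 iterations (256 bins, 0.4 mm pitch, fan sized to cover
the phantom), which reconstructs in a few seconds while preserving the
protocol's structure (interleaved subsets, count statistics, stopping by
iteration cap). These sizes are the package's chosen test conditions, not
algorithmic limits; the implementation is resolution-agnostic.

## Known limitations

- Central-slice 2-D only; no cone-beam/off-plane geometry, helical paths,
  curved detectors or detector tilt.
- No regularisation/penalty term (the stage-2 machine is where one would
  attach it).
- The FIFO regime's micro-protocol (what exactly a suspended device does)
  is this package's documented interpretation of underspecified control
  flow; alternatives exist, but any interpretation must leave the
  mathematics unchanged, which is the property the equivalence tests pin
  down.
- Worker parallelism is simulated deterministically; the package measures
  scheduling *policy* effects (makespan, idle time, blocking), not
  wall-clock concurrency.
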