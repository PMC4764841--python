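"""Synthetic MEG session generator.

Produces whole-head magnetometer recordings with the statistical structure a
slow-movement-field (SMF) decoding analysis relies on:

* a movement-related cortical field (MRCF) that ramps up before an execution
  cue and peaks shortly after it, projected to the sensors through a
  single-sphere lead field from a small cortical dipole patch whose location
  and strength depend on the movement type (grasp vs open);
* alpha/beta band oscillations whose power drops during the movement epoch
  (event-related desynchronization, ERD);
* 1/f^alpha background noise plus spatially white Gaussian sensor noise.

Sessions start with a task-free head segment (50 s by default) from which
baseline statistics for z-scoring are later estimated.  All generators are
reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import InvalidConfigError

RATE_HZ = 1000.0
LOWPASS_HZ = 200.0
N_PARIETAL = 84

GRASP = "grasp"
OPEN = "open"
MOVEMENT_TYPES = (GRASP, OPEN)


# --------------------------------------------------------------------------
# sensor geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SensorArray:
    """Hemispherical magnetometer cap.

    positions are in metres relative to the centre of the spherical volume
    conductor; orientations are the (radial) unit measurement directions.
    ``parietal_mask`` marks the 84-sensor posterior-superior subset used for
    decoding.
    """

    positions: np.ndarray      # (n_sensors, 3)
    orientations: np.ndarray   # (n_sensors, 3), unit norm
    parietal_mask: np.ndarray  # (n_sensors,), bool
    head_radius: float         # conductor sphere radius (m)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def parietal_indices(self) -> np.ndarray:
        return np.flatnonzero(self.parietal_mask)


def _fibonacci_cap(n: int, z_min: float) -> np.ndarray:
    """Near-uniform unit vectors on the spherical cap z >= z_min."""
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


# posterior-superior direction used to pick the parietal subset
# (+y anterior, so -y is posterior; +z up)
_PARIETAL_DIR = np.array([0.0, -0.45, 0.89])
_PARIETAL_DIR = _PARIETAL_DIR / np.linalg.norm(_PARIETAL_DIR)


def make_sensor_array(
    n_sensors: int = 160,
    head_radius: float = 0.09,
    seed: int = 0,
    cap_gap: float = 0.03,
    n_parietal: int = N_PARIETAL,
) -> SensorArray:
    """Build a whole-head cap of radial magnetometers.

    Sensors sit on a sphere of radius ``head_radius + cap_gap`` covering the
    upper head down to roughly ear level; the parietal mask selects the
    ``n_parietal`` sensors closest (in angle) to the posterior-superior
    direction.  A small seeded angular jitter makes the layout irregular the
    way a real helmet is, without changing the coverage.
    """
    if n_sensors < n_parietal:
        raise InvalidConfigError(
            f"need at least {n_parietal} sensors for the parietal decoding "
            f"subset, got {n_sensors}"
        )
    rng = np.random.default_rng(seed)
    units = _fibonacci_cap(n_sensors, z_min=-0.25)
    jitter = rng.normal(scale=0.01, size=units.shape)
    units = units + jitter
    units /= np.linalg.norm(units, axis=1, keepdims=True)
    positions = (head_radius + cap_gap) * units
    orientations = units.copy()

    angle_cos = units @ _PARIETAL_DIR
    order = np.argsort(-angle_cos)
    mask = np.zeros(n_sensors, dtype=bool)
    mask[order[:n_parietal]] = True
    return SensorArray(
        positions=positions,
        orientations=orientations,
        parietal_mask=mask,
        head_radius=head_radius,
    )


# --------------------------------------------------------------------------
# event schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EventSchedule:
    """Cue and instruction timing for a session.

    ``cue_times`` hold the execution cues (open loop) or the equivalent cue
    times of the injected movement bursts (closed loop; ground truth for
    evaluation).  Instructions are the block-level type announcements.
    """

    cue_times: np.ndarray          # seconds from session start
    cue_types: tuple[str, ...]     # one of MOVEMENT_TYPES per cue
    instruction_times: np.ndarray  # seconds
    instruction_types: tuple[str, ...]

    def cues_of_type(self, movement: str) -> np.ndarray:
        sel = [i for i, m in enumerate(self.cue_types) if m == movement]
        return self.cue_times[sel]


@dataclass(frozen=True)
class MEGSession:
    """Multichannel MEG recording plus its geometry and event schedule."""

    data: np.ndarray            # (n_sensors, n_samples)
    rate: float
    lowpass: float
    schedule: EventSchedule
    sensor_array: SensorArray
    seed: int
    config: dict                # generator provenance

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


# --------------------------------------------------------------------------
# simulation configuration
# --------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Generator parameters.

    Amplitudes are in the same arbitrary (tesla-scaled) units as the output
    data; the MRCF amplitude of a movement type is the peak cue-locked
    deflection at the best parietal sensor.  ``erd_depth_*`` is the
    fractional band-power suppression during the movement epoch (power ratio
    movement/baseline = 1 - depth).
    """

    mrcf_amplitude: dict = field(
        default_factory=lambda: {GRASP: 0.45, OPEN: 0.36}
    )
    mrcf_ramp_start_ms: float = -1000.0
    mrcf_peak_ms: float = 300.0
    mrcf_end_ms: float = 1000.0
    # unit direction of each type's dipole patch centre on the toy cortex
    # (left = contralateral to a right hand; posterior-superior)
    patch_center_dirs: dict = field(
        default_factory=lambda: {
            GRASP: (-0.42, -0.23, 0.88),
            OPEN: (-0.30, -0.34, 0.89),
        }
    )
    patch_radius_m: float = 0.02
    erd_depth_alpha: float = 0.45
    erd_depth_beta: float = 0.35
    alpha_sd: float = 0.55
    beta_sd: float = 0.40
    noise_1f_exponent: float = 1.0
    noise_1f_sd: float = 0.45
    white_noise_sd: float = 1.0
    erd_epoch_ms: tuple = (0.0, 1000.0)
    # open-loop trial structure
    cues_per_type: int = 40
    cues_per_block: int = 4
    inter_cue_s: float = 5.5
    head_s: float = 50.0
    tail_s: float = 3.0
    instruction_lead_s: float = 3.0
    # closed-loop structure
    instruction_interval_s: float = 7.0
    reaction_latency_ms: float = 500.0
    reaction_jitter_sd_ms: float = 100.0
    burst_probability: float = 0.95
    # internal toy cortex used for the forward projection; the anatomy seed
    # is subject-level and deliberately independent of the session seed, so
    # repeated sessions of one subject share their dipole topographies
    mesh_n_vertices: int = 400
    anatomy_seed: int = 0
    duration_s: float | None = None
    seed: int = 0

    def validate(self) -> None:
        for m in MOVEMENT_TYPES:
            if m not in self.mrcf_amplitude:
                raise InvalidConfigError(f"mrcf_amplitude missing type {m!r}")
            if self.mrcf_amplitude[m] < 0:
                raise InvalidConfigError("mrcf_amplitude must be >= 0")
            if m not in self.patch_center_dirs:
                raise InvalidConfigError(f"patch_center_dirs missing {m!r}")
        for d in (self.erd_depth_alpha, self.erd_depth_beta):
            if not 0.0 <= d <= 1.0:
                raise InvalidConfigError("erd_depth must lie in [0, 1]")
        if not 0.0 <= self.burst_probability <= 1.0:
            raise InvalidConfigError("burst_probability must lie in [0, 1]")
        if not (self.mrcf_ramp_start_ms < self.mrcf_peak_ms < self.mrcf_end_ms):
            raise InvalidConfigError(
                "need mrcf_ramp_start_ms < mrcf_peak_ms < mrcf_end_ms"
            )
        same_amp = (
            self.mrcf_amplitude[GRASP] == self.mrcf_amplitude[OPEN]
        )
        same_patch = (
            tuple(self.patch_center_dirs[GRASP])
            == tuple(self.patch_center_dirs[OPEN])
        )
        if same_amp and same_patch:
            raise InvalidConfigError(
                "the two movement types must differ in amplitude and/or "
                "dipole patch, otherwise type decoding is at chance by "
                "construction"
            )
        if self.cues_per_type % self.cues_per_block:
            raise InvalidConfigError(
                "cues_per_type must be a multiple of cues_per_block"
            )

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------------
# signal components
# --------------------------------------------------------------------------

def mrcf_template(
    times_ms: np.ndarray,
    ramp_start_ms: float = -1000.0,
    peak_ms: float = 300.0,
    end_ms: float = 1000.0,
) -> np.ndarray:
    """Raised-cosine MRCF time course, 0 outside [ramp_start, end], 1 at peak.

    Times are milliseconds relative to the execution cue.
    """
    t = np.asarray(times_ms, dtype=float)
    w = np.zeros_like(t)
    rise = (t >= ramp_start_ms) & (t <= peak_ms)
    fall = (t > peak_ms) & (t <= end_ms)
    w[rise] = 0.5 * (1.0 - np.cos(
        np.pi * (t[rise] - ramp_start_ms) / (peak_ms - ramp_start_ms)))
    w[fall] = 0.5 * (1.0 + np.cos(
        np.pi * (t[fall] - peak_ms) / (end_ms - peak_ms)))
    return w


def _template_from_config(config: SimulationConfig, times_ms) -> np.ndarray:
    return mrcf_template(
        times_ms,
        config.mrcf_ramp_start_ms,
        config.mrcf_peak_ms,
        config.mrcf_end_ms,
    )


def mrcf_topography(
    config: SimulationConfig, array: SensorArray, movement: str
) -> np.ndarray:
    """Sensor-space pattern of one movement type's dipole patch.

    Dipole currents are placed on the generator's toy cortical mesh with a
    Gaussian falloff around the patch centre and projected through the
    single-sphere lead field.  The pattern is scaled so its largest absolute
    value over the parietal sensors is 1; the configured amplitude then sets
    the peak sensor deflection directly.
    """
    from .source import make_cortical_mesh, compute_lead_field

    mesh = make_cortical_mesh(
        n_vertices=config.mesh_n_vertices,
        radius=0.78 * array.head_radius,
        seed=config.anatomy_seed % (2**31),
    )
    lf = compute_lead_field(mesh, array)
    center = np.asarray(config.patch_center_dirs[movement], dtype=float)
    center /= np.linalg.norm(center)
    center_pt = center * np.median(np.linalg.norm(mesh.vertices, axis=1))
    d = np.linalg.norm(mesh.vertices - center_pt, axis=1)
    weights = np.exp(-0.5 * (d / (config.patch_radius_m / 2.0)) ** 2)
    weights[d > 2.0 * config.patch_radius_m] = 0.0
    g = lf.matrix @ weights
    peak = np.max(np.abs(g[array.parietal_mask]))
    if peak == 0.0:
        raise InvalidConfigError(
            "dipole patch is magnetically silent at the parietal sensors"
        )
    return g / peak


def one_over_f_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    exponent: float,
    sd: float,
    rate: float = RATE_HZ,
) -> np.ndarray:
    """Per-channel 1/f^exponent noise normalized to the requested SD."""
    if sd == 0.0:
        return np.zeros((n_channels, n_samples))
    from scipy.fft import irfft, next_fast_len, rfft

    n_fft = next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, n_samples),
                                dtype=np.float32)
    spec = rfft(white, n=n_fft, axis=1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate).astype(np.float32)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    out = irfft(spec * scale, n=n_fft, axis=1)[:, :n_samples]
    out /= out.std(axis=1, keepdims=True)
    return sd * out


def _erd_envelope(
    n_samples: int,
    cue_times_s: np.ndarray,
    depth: float,
    epoch_ms: tuple,
    rate: float = RATE_HZ,
) -> np.ndarray:
    """Amplitude envelope: 1 at rest, sqrt(1 - depth) in movement epochs."""
    env = np.ones(n_samples)
    gain = np.sqrt(1.0 - depth)
    for t in np.atleast_1d(cue_times_s):
        i0 = int(round((t + epoch_ms[0] / 1000.0) * rate))
        i1 = int(round((t + epoch_ms[1] / 1000.0) * rate))
        env[max(i0, 0):min(i1, n_samples)] = gain
    return env


def _background(
    config: SimulationConfig,
    array: SensorArray,
    n_samples: int,
    cue_times_s: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise plus oscillations with movement-locked ERD.

    The alpha and beta components are carved out of a single white-noise
    draw by disjoint frequency masks; disjoint spectral supports of one
    Gaussian process are independent, so this halves the FFT work without
    changing the statistics.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    n_ch = array.n_sensors
    acc = np.asarray(one_over_f_noise(
        rng, n_ch, n_samples, config.noise_1f_exponent,
        config.noise_1f_sd), dtype=np.float32)
    if config.white_noise_sd > 0:
        acc += config.white_noise_sd * rng.standard_normal(
            (n_ch, n_samples), dtype=np.float32)
    bands = [((8.0, 13.0), config.alpha_sd, config.erd_depth_alpha),
             ((13.0, 30.0), config.beta_sd, config.erd_depth_beta)]
    if any(sd > 0 for _, sd, _ in bands):
        n_fft = next_fast_len(n_samples)
        spec = rfft(rng.standard_normal((n_ch, n_samples),
                                        dtype=np.float32), n=n_fft, axis=1)
        freqs = np.fft.rfftfreq(n_fft, d=1.0 / RATE_HZ).astype(np.float32)
        for (lo, hi), sd, depth in bands:
            if sd == 0.0:
                continue
            edge = max(0.5, (hi - lo) * 0.1)
            gain = np.clip((freqs - (lo - edge)) / edge, 0.0, 1.0) * \
                np.clip(((hi + edge) - freqs) / edge, 0.0, 1.0)
            gain = (0.5 * (1.0 - np.cos(np.pi * gain))).astype(np.float32)
            osc = irfft(spec * gain, n=n_fft, axis=1)[:, :n_samples]
            osc /= osc.std(axis=1, keepdims=True)
            env = _erd_envelope(n_samples, cue_times_s, depth,
                                config.erd_epoch_ms).astype(np.float32)
            acc += np.float32(sd) * osc * env
    return acc.astype(np.float64)


def _inject_mrcf(
    data: np.ndarray,
    config: SimulationConfig,
    array: SensorArray,
    cue_times_s: Sequence[float],
    cue_types: Sequence[str],
) -> None:
    n_samples = data.shape[1]
    span_ms = np.arange(
        config.mrcf_ramp_start_ms, config.mrcf_end_ms + 1.0)
    wave = _template_from_config(config, span_ms)
    topo = {m: mrcf_topography(config, array, m) for m in MOVEMENT_TYPES}
    for t, m in zip(cue_times_s, cue_types):
        amp = config.mrcf_amplitude[m]
        if amp == 0.0:
            continue
        i0 = int(round(t * RATE_HZ + config.mrcf_ramp_start_ms))
        i1 = i0 + wave.size
        lo, hi = max(i0, 0), min(i1, n_samples)
        if lo >= hi:
            continue
        data[:, lo:hi] += amp * np.outer(topo[m], wave[lo - i0:hi - i0])


# --------------------------------------------------------------------------
# public generators
# --------------------------------------------------------------------------

def open_loop_schedule(config: SimulationConfig) -> EventSchedule:
    """Blocked cue schedule: an instruction then 4 execution cues per block,
    cues on a uniform 5.5-s grid, block types balanced and seeded-random."""
    n_blocks = 2 * config.cues_per_type // config.cues_per_block
    rng = np.random.default_rng(config.seed + 101)
    block_types = [GRASP, OPEN] * (n_blocks // 2)
    rng.shuffle(block_types)
    cue_times, cue_types = [], []
    instr_times, instr_types = [], []
    t0 = config.head_s + config.instruction_lead_s
    k = 0
    for b in range(n_blocks):
        instr_times.append(
            t0 + k * config.inter_cue_s - config.instruction_lead_s)
        instr_types.append(block_types[b])
        for _ in range(config.cues_per_block):
            cue_times.append(t0 + k * config.inter_cue_s)
            cue_types.append(block_types[b])
            k += 1
    return EventSchedule(
        cue_times=np.array(cue_times),
        cue_types=tuple(cue_types),
        instruction_times=np.array(instr_times),
        instruction_types=tuple(instr_types),
    )


def simulate_open_loop(
    config: SimulationConfig, array: SensorArray
) -> MEGSession:
    """Generate an open-loop session: task-free head segment followed by
    blocked execution cues, each adding a type-dependent MRCF, ERD of the
    ongoing alpha/beta oscillations, and noise."""
    config.validate()
    schedule = open_loop_schedule(config)
    needed = float(schedule.cue_times[-1]) + max(
        config.mrcf_end_ms / 1000.0, 1.0) + config.tail_s
    duration = needed if config.duration_s is None else config.duration_s
    if duration < needed:
        raise InvalidConfigError(
            f"duration {duration} s too short; schedule needs {needed:.1f} s"
        )
    n_samples = int(round(duration * RATE_HZ))
    rng = np.random.default_rng(config.seed)
    data = _background(config, array, n_samples, schedule.cue_times, rng)
    _inject_mrcf(data, config, array, schedule.cue_times, schedule.cue_types)
    return MEGSession(
        data=data,
        rate=RATE_HZ,
        lowpass=LOWPASS_HZ,
        schedule=schedule,
        sensor_array=array,
        seed=config.seed,
        config=config.to_dict(),
    )


def default_closed_loop_instructions(n: int = 22, first: str = GRASP
                                     ) -> list[str]:
    other = OPEN if first == GRASP else GRASP
    return [first if i % 2 == 0 else other for i in range(n)]


def simulate_closed_loop_stream(
    config: SimulationConfig,
    array: SensorArray,
    instructions: Sequence[str] | None = None,
) -> MEGSession:
    """Generate a continuous closed-loop stream.

    Instructions alternate (default 22 of them, one every 7 s).  After each
    instruction the subject reacts: with probability ``burst_probability`` an
    MRCF burst of the instructed type begins ``reaction_latency_ms`` (plus
    Gaussian jitter) after the instruction.  The schedule's ``cue_times``
    record the equivalent execution-cue times of the injected bursts (ground
    truth for scoring).
    """
    config.validate()
    if instructions is None:
        instructions = default_closed_loop_instructions()
    instructions = list(instructions)
    if not instructions:
        raise InvalidConfigError("instruction list must be non-empty")
    for a, b in zip(instructions, instructions[1:]):
        if a == b:
            raise InvalidConfigError("instructions must alternate")
    rng = np.random.default_rng(config.seed)
    instr_times = config.head_s + config.instruction_lead_s + \
        config.instruction_interval_s * np.arange(len(instructions))
    burst_cues, burst_types = [], []
    for t, m in zip(instr_times, instructions):
        if rng.uniform() >= config.burst_probability:
            continue
        jitter = (config.reaction_jitter_sd_ms / 1000.0) * rng.standard_normal() \
            if config.reaction_jitter_sd_ms > 0 else 0.0
        onset = t + config.reaction_latency_ms / 1000.0 + jitter
        # the burst begins (ramp start) at the reaction time
        burst_cues.append(onset - config.mrcf_ramp_start_ms / 1000.0)
        burst_types.append(m)
    needed = instr_times[-1] + config.instruction_interval_s + 1.0
    duration = needed if config.duration_s is None else config.duration_s
    if duration < needed:
        raise InvalidConfigError(
            f"duration {duration} s too short; schedule needs {needed:.1f} s"
        )
    n_samples = int(round(duration * RATE_HZ))
    data = _background(config, array, n_samples, np.array(burst_cues), rng)
    _inject_mrcf(data, config, array, burst_cues, burst_types)
    schedule = EventSchedule(
        cue_times=np.array(burst_cues),
        cue_types=tuple(burst_types),
        instruction_times=instr_times,
        instruction_types=tuple(instructions),
    )
    return MEGSession(
        data=data,
        rate=RATE_HZ,
        lowpass=LOWPASS_HZ,
        schedule=schedule,
        sensor_array=array,
        seed=config.seed,
        config=config.to_dict(),
    )
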