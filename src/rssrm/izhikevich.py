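"""Generator of the twenty canonical firing behaviors of the Izhikevich neuron.

The simplified two-variable Izhikevich system

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with the after-spike reset ``v >= 30 mV  ->  v <- c, u <- u + d`` is integrated
with the forward Euler method.  Each of the twenty behavior labels (a)-(t)
carries its own hyperparameters ``a, b, c, d``, initial state and injected
current protocol; together they reproduce the classic catalogue of cortical
firing patterns (tonic/phasic spiking and bursting, excitability classes,
resonance, rebound responses, bistability, ...).

Stored membrane potentials are clamped to the 30 mV spike peak at spike
samples so that the trace doubles as the ground truth for spike detection.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "StimulusProtocol",
    "BehaviorSpec",
    "SimulationTrace",
    "SpikeTrain",
    "DegenerateTraceError",
    "SimulationDivergedError",
    "BEHAVIOR_NAMES",
    "build_behavior_catalog",
    "simulate",
    "extract_spike_train",
    "classify_behavior",
]

SPIKE_PEAK = 30.0  # mV, reset threshold and stored clamp value
DEFAULT_DT = 0.25  # ms

#: the twenty behavior labels, in catalogue order
BEHAVIOR_NAMES = tuple("abcdefghijklmnopqrst")

ONE_SPIKE = "one-spike"
MULTIPLE_SPIKE = "multiple-spike"


class DegenerateTraceError(ValueError):
    """A trace without any ground-truth spike cannot be benchmarked."""


class SimulationDivergedError(FloatingPointError):
    """Euler integration diverged (v grew without reaching the reset)."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-linear injected-current protocol.

    ``segments`` are ``(start_ms, end_ms, amp)`` with ``amp`` either a scalar
    (constant current) or an ``(amp_start, amp_end)`` pair (linear ramp).
    Outside every segment the current equals ``baseline``.
    """

    segments: tuple = ()
    baseline: float = 0.0

    def __post_init__(self):
        last_end = -np.inf
        for seg in self.segments:
            start, end, _ = seg
            if end <= start:
                raise ValueError(f"empty stimulus segment {seg!r}")
            if start < last_end:
                raise ValueError("stimulus segments overlap")
            last_end = end

    def current(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the injected current on the time stamps ``t`` (ms)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, float(self.baseline))
        for start, end, amp in self.segments:
            mask = (t >= start) & (t < end)
            if np.ndim(amp) == 0:
                out[mask] = float(amp)
            else:
                a0, a1 = amp
                out[mask] = a0 + (a1 - a0) * (t[mask] - start) / (end - start)
        return out


@dataclass(frozen=True)
class BehaviorSpec:
    """One named firing behavior: model hyperparameters plus protocol."""

    name: str
    a: float
    b: float
    c: float
    d: float
    v0: float
    u0: float
    dt: float
    n_steps: int
    stimulus: StimulusProtocol
    label: str = ""

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        t_end = self.n_steps * self.dt
        for start, end, _ in self.stimulus.segments:
            if start < 0 or end > t_end + 1e-9:
                raise ValueError(
                    f"stimulus segment ({start}, {end}) outside [0, {t_end}] "
                    f"for behavior {self.name!r}"
                )

    @property
    def duration(self) -> float:
        """Total simulated time in ms."""
        return self.n_steps * self.dt


@dataclass
class SimulationTrace:
    """Euler-integrated trajectory of one behavior."""

    t: np.ndarray
    I: np.ndarray
    v: np.ndarray
    u: np.ndarray
    spike_times: np.ndarray
    dt: float
    name: str = ""

    def __post_init__(self):
        n = len(self.t)
        if not (len(self.I) == len(self.v) == len(self.u) == n):
            raise ValueError("trace arrays must share one length")
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return len(self.t)

    @property
    def spike_indices(self) -> np.ndarray:
        return np.rint(self.spike_times / self.dt).astype(int)


@dataclass
class SpikeTrain:
    """A spike train as a binary indicator over samples plus spike times."""

    indicator: np.ndarray
    times: np.ndarray
    dt: float
    t0: float = 0.0

    @property
    def r(self) -> float:
        """Firing proportion: spike count over sample count."""
        return float(np.count_nonzero(self.indicator)) / len(self.indicator)

    @property
    def n_spikes(self) -> int:
        return int(np.count_nonzero(self.indicator))

    @classmethod
    def from_indicator(cls, indicator, dt, t0=0.0) -> "SpikeTrain":
        indicator = np.asarray(indicator).astype(np.int8)
        idx = np.flatnonzero(indicator)
        return cls(indicator=indicator, times=t0 + idx * dt, dt=dt, t0=t0)

    @classmethod
    def from_times(cls, times, n_steps, dt, t0=0.0) -> "SpikeTrain":
        times = np.sort(np.asarray(times, dtype=float))
        idx = np.rint((times - t0) / dt).astype(int)
        if len(idx) and (idx.min() < 0 or idx.max() >= n_steps):
            raise ValueError("spike time outside the sample grid")
        indicator = np.zeros(n_steps, dtype=np.int8)
        indicator[idx] = 1
        return cls(indicator=indicator, times=t0 + idx * dt, dt=dt, t0=t0)


# ---------------------------------------------------------------------------
# Default catalogue
# ---------------------------------------------------------------------------

def _default_catalog_text() -> str:
    return (
        importlib.resources.files("rssrm")
        .joinpath("data/default_catalog.yaml")
        .read_text()
    )


def _resolve_time(spec, T: float) -> float:
    """A protocol time is ``[fraction, offset_ms]`` resolved as frac*T + offset."""
    frac, offset = spec
    return frac * T + offset


def build_behavior_catalog(
    dt: float = DEFAULT_DT,
    scale: float = 1.0,
    config: str | dict | None = None,
) -> list[BehaviorSpec]:
    """Build the twenty-behavior catalogue.

    Parameters
    ----------
    dt : float
        Euler step in ms.
    scale : float
        Multiplies every behavior's default sample count; event times defined
        as fractions of the duration move with it while pulse widths and
        dynamically critical gaps stay absolute (in ms).
    config : str or dict, optional
        YAML text or parsed mapping overriding the packaged defaults.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if config is None:
        config = _default_catalog_text()
    if isinstance(config, str):
        config = yaml.safe_load(config)

    catalog = []
    for name, entry in config.items():
        if name not in BEHAVIOR_NAMES:
            raise KeyError(f"unknown behavior name {name!r}")
        n_steps = max(2, int(round(entry["n_steps"] * scale)))
        T = n_steps * dt
        segments = []
        for seg in entry.get("segments", ()):
            start = _resolve_time(seg["start"], T)
            end = _resolve_time(seg["end"], T)
            start = min(max(start, 0.0), T)
            end = min(max(end, 0.0), T)
            if end <= start:
                continue  # clipped away at small scales
            amp = seg["amp"]
            amp = tuple(amp) if isinstance(amp, (list, tuple)) else float(amp)
            segments.append((start, end, amp))
        # clipping at small scales can interleave pulse pairs; keep a sorted,
        # non-overlapping subset (earlier segment wins)
        segments.sort(key=lambda s: s[0])
        kept, last_end = [], -np.inf
        for seg in segments:
            if seg[0] >= last_end:
                kept.append(seg)
                last_end = seg[1]
        segments = kept
        params = entry["params"]
        v0 = float(entry["v0"])
        u0 = float(entry["u0"]) if "u0" in entry else params["b"] * v0
        catalog.append(
            BehaviorSpec(
                name=name,
                label=entry.get("label", name),
                a=params["a"],
                b=params["b"],
                c=params["c"],
                d=params["d"],
                v0=v0,
                u0=u0,
                dt=dt,
                n_steps=n_steps,
                stimulus=StimulusProtocol(
                    segments=tuple(segments),
                    baseline=float(entry.get("baseline", 0.0)),
                ),
            )
        )
    missing = set(BEHAVIOR_NAMES) - {s.name for s in catalog}
    if missing:
        raise KeyError(f"catalog is missing behaviors: {sorted(missing)}")
    catalog.sort(key=lambda s: BEHAVIOR_NAMES.index(s.name))
    return catalog


def get_behavior(name: str, **kwargs) -> BehaviorSpec:
    """Look a single behavior up in the default catalogue."""
    for spec in build_behavior_catalog(**kwargs):
        if spec.name == name:
            return spec
    raise KeyError(f"unknown behavior name {name!r}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_DIVERGENCE_LIMIT = 1e6


def simulate(spec: BehaviorSpec) -> SimulationTrace:
    """Forward-Euler integration of one behavior.  Deterministic.

    Whenever the updated potential reaches the 30 mV peak the stored sample is
    clamped to 30 mV, the sample time is recorded as a spike, and the state is
    reset to ``(c, u + d)`` before the next step.
    """
    n = spec.n_steps
    dt = spec.dt
    t = np.arange(n) * dt
    I = spec.stimulus.current(t)

    v_arr = np.empty(n)
    u_arr = np.empty(n)
    v, u = spec.v0, spec.u0
    v_arr[0], u_arr[0] = v, u
    spikes = []
    a, b, c, d = spec.a, spec.b, spec.c, spec.d

    for k in range(1, n):
        Ik = I[k - 1]
        v_new = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + Ik)
        u_new = u + dt * (a * (b * v - u))
        if v_new >= SPIKE_PEAK:
            v_arr[k] = SPIKE_PEAK
            u_arr[k] = u_new
            spikes.append(k)
            v, u = c, u_new + d
        else:
            if not np.isfinite(v_new) or abs(v_new) > _DIVERGENCE_LIMIT:
                raise SimulationDivergedError(
                    f"behavior {spec.name!r} diverged at step {k}"
                )
            v_arr[k] = v_new
            u_arr[k] = u_new
            v, u = v_new, u_new

    return SimulationTrace(
        t=t,
        I=I,
        v=v_arr,
        u=u_arr,
        spike_times=np.array(spikes, dtype=float) * dt,
        dt=dt,
        name=spec.name,
    )


def extract_spike_train(trace: SimulationTrace) -> SpikeTrain:
    """Ground-truth spike train of a trace as an indicator sequence."""
    return SpikeTrain.from_times(trace.spike_times, trace.n_steps, trace.dt)


def classify_behavior(trace: SimulationTrace) -> str:
    """Classify a trace as one-spike or multiple-spike by its spike count."""
    n = len(trace.spike_times)
    if n == 0:
        raise DegenerateTraceError(
            f"behavior {trace.name!r} produced no spikes; "
            "it cannot be assigned a firing class"
        )
    return ONE_SPIKE if n == 1 else MULTIPLE_SPIKE
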