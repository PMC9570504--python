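"""Stochastic simulator for dual whole-cell gap-junction recordings.

Each gap-junction channel is modelled as a three-state Markov chain — main
open, residual (subconductance) and fully closed — gated by the absolute
transjunctional voltage Vj with polarity-specific half-deactivation voltage
V0 and sensitivity A. The opening and closing rates split the Boltzmann
exponent symmetrically, so the stationary open probability is exactly
1/(1 + exp[A(|Vj| - V0)]), the two-state Boltzmann law that macroscopic
steady-state conductance analysis fits.

Currents are in pA, voltages in mV, conductances in pS; a channel at level
gamma (pS) under Vj (mV) passes gamma * Vj / 1000 pA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .filters import gaussian_lowpass

__all__ = [
    "StepProtocol",
    "GatingModel",
    "RecordingNoise",
    "Trace",
    "TraceSet",
    "steady_state_curve",
    "gating_rates",
    "simulate_channels",
    "write_traces",
    "read_traces",
]

# state indices
OPEN, RESIDUAL, CLOSED = 0, 1, 2

#: rates above this are clamped (with a warning) before discretization
DEFAULT_RATE_MAX = 1.0e4


@dataclass(frozen=True)
class StepProtocol:
    """Vj step schedule of a dual whole-cell recording.

    ``vj_steps`` are the pulse amplitudes in mV applied to the pulsing cell;
    each step is preceded by ``pre_step_baseline`` seconds at the holding
    potential ``inter_step_holding`` (0 mV by default, i.e. no junctional
    drive).
    """

    vj_steps: tuple[float, ...]
    step_duration: float
    sampling_rate: float = 10_000.0
    inter_step_holding: float = 0.0
    pre_step_baseline: float = 0.5

    def __post_init__(self) -> None:
        if len(self.vj_steps) == 0:
            raise ValueError("vj_steps must be non-empty")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.pre_step_baseline < 0:
            raise ValueError("pre_step_baseline must be >= 0")
        object.__setattr__(self, "vj_steps", tuple(float(v) for v in self.vj_steps))


@dataclass(frozen=True)
class GatingModel:
    """Boltzmann/kinetic parameters of one homotypic gap-junction construct.

    ``v0_pos``/``v0_neg`` are absolute half-deactivation voltages (mV) for the
    two Vj polarities, ``a_pos``/``a_neg`` the gating sensitivities (1/mV).
    ``k0`` scales the kinetics: at |Vj| = V0 the opening and closing rates
    both equal ``k0``. ``gamma_main``/``gamma_res`` are the main-open and
    residual unitary conductances (pS); a closing transition enters the fully
    closed level with probability ``p_fullclose``, else the residual level.
    """

    v0_pos: float
    v0_neg: float
    a_pos: float
    a_neg: float
    k0: float
    gamma_main: float
    gamma_res: float
    p_fullclose: float = 0.2

    def __post_init__(self) -> None:
        if self.a_pos < 0 or self.a_neg < 0:
            raise ValueError("gating sensitivities must be >= 0")
        if not (0 <= self.gamma_res < self.gamma_main):
            raise ValueError("require 0 <= gamma_res < gamma_main")
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if not (0 <= self.p_fullclose <= 1):
            raise ValueError("p_fullclose must be in [0, 1]")

    def polarity_params(self, vj: float) -> tuple[float, float]:
        """(V0, A) for the polarity of ``vj`` (positive polarity at vj >= 0)."""
        if vj >= 0:
            return self.v0_pos, self.a_pos
        return self.v0_neg, self.a_neg

    @property
    def g_min(self) -> float:
        """Normalized residual conductance gamma_res / gamma_main."""
        return self.gamma_res / self.gamma_main


@dataclass(frozen=True)
class RecordingNoise:
    """White recording noise (pA, at the sampling rate) low-passed at the
    acquisition cutoff before storage, mimicking a 1 kHz acquisition chain."""

    sigma: float = 2.0
    acquisition_cutoff: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class Trace:
    """One junctional-current record: ``pre_step_baseline`` seconds at the
    holding potential followed by ``step_s`` seconds at ``vj``."""

    vj: float
    samples: np.ndarray
    sampling_rate: float
    baseline_s: float = 0.0
    step_s: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def onset_index(self) -> int:
        """Sample index of the Vj step onset."""
        return int(round(self.baseline_s * self.sampling_rate))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class TraceSet:
    """Ordered collection of traces (one per protocol step)."""

    traces: list[Trace] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    def __getitem__(self, i) -> Trace:
        return self.traces[i]


def steady_state_curve(model: GatingModel, vj) -> np.ndarray | float:
    """Stationary normalized conductance of the two-state Boltzmann law.

    Evaluates Gmin + (1 - Gmin) / (1 + exp[A(|vj| - V0)]) with the
    polarity-matched (V0, A) and Gmin = gamma_res/gamma_main; the value lies
    in [Gmin, 1]. Accepts scalars or arrays of vj.
    """
    vj_arr = np.asarray(vj, dtype=float)
    v0 = np.where(vj_arr >= 0, model.v0_pos, model.v0_neg)
    a = np.where(vj_arr >= 0, model.a_pos, model.a_neg)
    gmin = model.g_min
    with np.errstate(over="ignore"):
        p_open = 1.0 / (1.0 + np.exp(a * (np.abs(vj_arr) - v0)))
    out = gmin + (1.0 - gmin) * p_open
    if np.isscalar(vj) or vj_arr.ndim == 0:
        return float(out)
    return out


def gating_rates(
    model: GatingModel, vj: float, rate_max: float = DEFAULT_RATE_MAX
) -> tuple[float, float]:
    """Opening and closing rates (alpha, beta) in 1/s at ``vj``.

    The Boltzmann exponent is split symmetrically:
    alpha = k0 exp(-A(|vj| - V0)/2), beta = k0 exp(+A(|vj| - V0)/2), so that
    alpha/(alpha+beta) = 1/(1 + exp[A(|vj| - V0)]) exactly. Rates above
    ``rate_max`` are clamped with a warning.
    """
    v0, a = model.polarity_params(vj)
    x = a * (abs(vj) - v0) / 2.0
    alpha = model.k0 * math.exp(-x)
    beta = model.k0 * math.exp(x)
    if alpha > rate_max or beta > rate_max:
        warnings.warn(
            f"gating rate exceeds {rate_max:g}/s at vj={vj} mV; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        alpha = min(alpha, rate_max)
        beta = min(beta, rate_max)
    return alpha, beta


def _stationary_probs(model: GatingModel, vj: float) -> np.ndarray:
    alpha, beta = gating_rates(model, vj)
    p_open = alpha / (alpha + beta)
    p_gated = 1.0 - p_open
    return np.array(
        [
            p_open,
            (1.0 - model.p_fullclose) * p_gated,
            model.p_fullclose * p_gated,
        ]
    )


def _leave_probs(model: GatingModel, vj: float, dt: float) -> np.ndarray:
    """Per-sample probability of leaving each state at voltage ``vj``."""
    alpha, beta = gating_rates(model, vj)
    if dt * max(alpha, beta) > 0.1:
        raise ValueError(
            f"dt*rate = {dt * max(alpha, beta):.3g} > 0.1 at vj={vj} mV: "
            "discrete-time stepping invalid; reduce k0 or raise sampling_rate"
        )
    return np.array(
        [
            -math.expm1(-beta * dt),  # open -> gated
            -math.expm1(-alpha * dt),  # residual -> open
            -math.expm1(-alpha * dt),  # closed -> open
        ]
    )


def _evolve_channel(
    state: int,
    segments: list[tuple[np.ndarray, slice]],
    levels: np.ndarray,
    gsum: np.ndarray,
    rng: np.random.Generator,
    p_fullclose: float,
) -> int:
    """Advance one channel through the trace, adding its conductance level
    (pS) into ``gsum``. Sojourns are sampled geometrically, which is exactly
    the law of per-sample Markov stepping; memorylessness makes re-sampling
    at segment boundaries exact."""
    for p_leave, seg in segments:
        t = seg.start
        remaining = seg.stop - seg.start
        while remaining > 0:
            p = p_leave[state]
            if p <= 0.0:
                gsum[t : t + remaining] += levels[state]
                t += remaining
                break
            k = int(rng.geometric(p))
            stay = min(k, remaining)
            gsum[t : t + stay] += levels[state]
            t += stay
            remaining -= stay
            if k == stay:
                # dwell ended inside this segment (or exactly at its end, in
                # which case the new state takes over from the next sample)
                if state == OPEN:
                    state = CLOSED if rng.random() < p_fullclose else RESIDUAL
                else:
                    state = OPEN
            # else k > stay: dwell outlasts the segment; carry the state over
            # (exact by memorylessness of the geometric dwell)
    return state


def simulate_channels(
    model: GatingModel,
    protocol: StepProtocol,
    n_channels: int,
    noise: RecordingNoise | None = None,
    seed: int = 0,
    construct: str = "model",
) -> TraceSet:
    """Simulate one trace per protocol step for ``n_channels`` channels.

    Channels are initialized at the stationary distribution of the holding
    potential and evolve as discrete-time Markov chains at the sampling
    interval; the trace current is vj * sum(state conductances) / 1000 plus
    filtered Gaussian noise. Identical seeds give bit-identical traces.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    dt = 1.0 / protocol.sampling_rate
    n_base = int(round(protocol.pre_step_baseline * protocol.sampling_rate))
    n_step = int(round(protocol.step_duration * protocol.sampling_rate))
    n_total = n_base + n_step
    v_hold = protocol.inter_step_holding

    levels = np.array([model.gamma_main, model.gamma_res, 0.0])
    p_stat_hold = _stationary_probs(model, v_hold)
    # validate discretization up-front for every voltage actually simulated
    if n_base > 0:
        p_leave_hold = _leave_probs(model, v_hold, dt)
    for vj in protocol.vj_steps:
        _leave_probs(model, vj, dt)

    traces: list[Trace] = []
    for vj in protocol.vj_steps:
        p_leave_step = _leave_probs(model, vj, dt)
        segments = []
        if n_base > 0:
            segments.append((p_leave_hold, slice(0, n_base)))
        segments.append((p_leave_step, slice(n_base, n_total)))

        gsum = np.zeros(n_total)
        states = rng.choice(3, size=n_channels, p=p_stat_hold)
        for ch in range(n_channels):
            _evolve_channel(
                int(states[ch]), segments, levels, gsum, rng, model.p_fullclose
            )
        current = np.empty(n_total)
        current[:n_base] = gsum[:n_base] * v_hold / 1000.0
        current[n_base:] = gsum[n_base:] * vj / 1000.0

        if noise is not None and noise.sigma > 0:
            white = rng.normal(0.0, noise.sigma, n_total)
            current = current + gaussian_lowpass(
                white, noise.acquisition_cutoff, protocol.sampling_rate
            )

        traces.append(
            Trace(
                vj=vj,
                samples=current,
                sampling_rate=protocol.sampling_rate,
                baseline_s=n_base * dt,
                step_s=n_step * dt,
                metadata={
                    "construct": construct,
                    "seed": int(seed),
                    "n_channels": int(n_channels),
                },
            )
        )
    return TraceSet(traces)


# ---------------------------------------------------------------------------
# trace file format: UTF-8 text, '## trace <i>' blocks, '# key = value'
# headers, then one sample (pA) per line

_REQUIRED_KEYS = ("vj_mV", "sampling_rate_Hz", "construct", "seed", "n_channels")
_SAMPLE_FMT = "%.4f"


def write_traces(traces: TraceSet | Sequence[Trace], path) -> None:
    """Write a trace set as columnar UTF-8 text (samples to 4 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, tr in enumerate(traces):
            md = tr.metadata
            fh.write(f"## trace {i}\n")
            fh.write(f"# vj_mV = {tr.vj:g}\n")
            fh.write(f"# sampling_rate_Hz = {tr.sampling_rate:g}\n")
            fh.write(f"# construct = {md.get('construct', 'unknown')}\n")
            fh.write(f"# seed = {md.get('seed', 0)}\n")
            fh.write(f"# n_channels = {md.get('n_channels', 1)}\n")
            fh.write(f"# baseline_s = {tr.baseline_s:g}\n")
            fh.write(f"# step_s = {tr.step_s:g}\n")
            np.savetxt(fh, tr.samples, fmt=_SAMPLE_FMT)


def _parse_header_value(key: str, value: str, lineno: int):
    try:
        if key in ("vj_mV", "sampling_rate_Hz", "baseline_s", "step_s"):
            return float(value)
        if key in ("seed", "n_channels"):
            return int(value)
    except ValueError:
        raise ValueError(
            f"line {lineno}: malformed header value for '{key}': {value!r}"
        ) from None
    return value


def read_traces(path) -> TraceSet:
    """Read a trace set written by :func:`write_traces`.

    Malformed headers, missing required keys, non-numeric or non-finite
    samples are rejected with the offending line number.
    """
    blocks: list[tuple[dict, list[float], int]] = []
    header: dict | None = None
    samples: list[float] | None = None
    block_line = 0

    def finish() -> None:
        if header is not None:
            blocks.append((header, samples, block_line))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("## trace"):
                finish()
                header, samples, block_line = {}, [], lineno
                continue
            if header is None:
                raise ValueError(f"line {lineno}: content before first '## trace' block")
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise ValueError(f"line {lineno}: malformed header line {line!r}")
                key, _, value = body.partition("=")
                key, value = key.strip(), value.strip()
                header[key] = _parse_header_value(key, value, lineno)
                continue
            try:
                x = float(line)
            except ValueError:
                raise ValueError(
                    f"line {lineno}: non-numeric sample value {line!r}"
                ) from None
            if not math.isfinite(x):
                raise ValueError(f"line {lineno}: non-finite sample value {line!r}")
            samples.append(x)
        finish()

    traces = []
    for header, samples, lineno in blocks:
        missing = [k for k in _REQUIRED_KEYS if k not in header]
        if missing:
            raise ValueError(
                f"line {lineno}: trace block missing required keys {missing}"
            )
        if header["sampling_rate_Hz"] <= 0:
            raise ValueError(f"line {lineno}: non-positive sampling rate")
        traces.append(
            Trace(
                vj=header["vj_mV"],
                samples=np.asarray(samples, dtype=float),
                sampling_rate=header["sampling_rate_Hz"],
                baseline_s=header.get("baseline_s", 0.0),
                step_s=header.get(
                    "step_s",
                    len(samples) / header["sampling_rate_Hz"]
                    - header.get("baseline_s", 0.0),
                ),
                metadata={
                    "construct": header["construct"],
                    "seed": header["seed"],
                    "n_channels": header["n_channels"],
                },
            )
        )
    return TraceSet(traces)
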