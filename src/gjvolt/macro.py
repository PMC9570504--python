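"""Macroscopic junctional-current analysis.

Reduces step-protocol trace sets to peak and steady-state currents and
conductances (Gj = Ij/Vj), normalized steady-state conductance
Gj,ss = Gss/Gpeak per step, pair-level coupling conductance and coupling
status, and fits the two-state Boltzmann equation

    Gj,ss(Vj) = (Gmax - Gmin) / (1 + exp[A(|Vj| - V0)]) + Gmin

independently per Vj polarity, where V0 is the half-deactivation voltage
and A the gating sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .sim import Trace, TraceSet

__all__ = [
    "MacroSummary",
    "BoltzmannFit",
    "measure_peak",
    "measure_steady_state",
    "summarize_pair",
    "boltzmann",
    "fit_boltzmann",
    "fit_polarities",
]

#: pairs with Gj at or above this (nS) are excluded from Vj-gating analysis
#: to limit voltage-clamp error
GJ_EXCLUSION_NS = 9.0

#: a pair counts as coupled above this conductance (nS), ~3x the
#: noise-limited conductance resolution at the default recording noise
COUPLING_THRESHOLD_NS = 0.01


def _baseline(trace: Trace) -> float:
    onset = trace.onset_index
    if onset <= 0:
        return 0.0
    return float(np.mean(trace.samples[:onset]))


def measure_peak(
    trace: Trace, blank: float = 0.005, peak_window: float = 0.010
) -> float:
    """Peak junctional current (pA) at the beginning of the step.

    Mean over [onset + blank, onset + blank + peak_window], baseline
    subtracted; the blank skips the capacitive transient.
    """
    fs = trace.sampling_rate
    i0 = trace.onset_index + int(round(blank * fs))
    i1 = i0 + int(round(peak_window * fs))
    if i1 > trace.n_samples or i0 >= i1:
        raise ValueError(
            f"peak window [{i0}, {i1}) exceeds trace of {trace.n_samples} samples"
        )
    return float(np.mean(trace.samples[i0:i1])) - _baseline(trace)


def measure_steady_state(trace: Trace, ss_window: float = 0.5) -> float:
    """Steady-state current (pA): mean of the last 500 ms of the step,
    baseline subtracted. Steps shorter than the window are an error."""
    if trace.step_s < ss_window:
        raise ValueError(
            f"step of {trace.step_s:.3f} s is shorter than the "
            f"{ss_window:.3f} s steady-state window"
        )
    n = int(round(ss_window * trace.sampling_rate))
    return float(np.mean(trace.samples[trace.n_samples - n :])) - _baseline(trace)


@dataclass
class MacroSummary:
    """Per-step measurements plus pair-level conductance and coupling call."""

    steps: pd.DataFrame  # columns: vj, i_peak, i_ss, g_peak, g_ss, g_norm
    g_j: float  # pair coupling conductance (nS), from the +/-20 mV steps
    coupled: bool
    gating_excluded: bool  # True when g_j >= 9 nS


def summarize_pair(
    traces: TraceSet,
    blank: float = 0.005,
    peak_window: float = 0.010,
    ss_window: float = 0.5,
    coupling_threshold: float = COUPLING_THRESHOLD_NS,
    gj_exclusion: float = GJ_EXCLUSION_NS,
) -> MacroSummary:
    """Reduce one cell pair's trace set to a :class:`MacroSummary`.

    Per step: g = i/vj (nS from pA/mV), g_norm = g_ss/g_peak. The pair Gj is
    the mean peak conductance of the +/-20 mV steps (smallest |vj| recorded
    if no 20 mV step exists). Steps at vj = 0 are skipped with a warning.
    """
    rows = []
    for tr in traces:
        if tr.vj == 0:
            warnings.warn("skipping step at vj = 0 mV", RuntimeWarning, stacklevel=2)
            continue
        i_peak = measure_peak(tr, blank=blank, peak_window=peak_window)
        i_ss = measure_steady_state(tr, ss_window=ss_window)
        g_peak = i_peak / tr.vj  # pA/mV == nS
        g_ss = i_ss / tr.vj
        g_norm = g_ss / g_peak if g_peak != 0 else np.nan
        rows.append(
            {
                "vj": tr.vj,
                "i_peak": i_peak,
                "i_ss": i_ss,
                "g_peak": g_peak,
                "g_ss": g_ss,
                "g_norm": g_norm,
            }
        )
    if not rows:
        raise ValueError("no analyzable steps in trace set")
    steps = pd.DataFrame(rows)

    abs_vj = steps["vj"].abs()
    ref = abs_vj[np.isclose(abs_vj, 20.0)]
    if ref.empty:
        ref_mask = np.isclose(abs_vj, abs_vj.min())
    else:
        ref_mask = np.isclose(abs_vj, 20.0)
    g_j = float(steps.loc[ref_mask, "g_peak"].mean())
    g_j = max(g_j, 0.0)
    return MacroSummary(
        steps=steps,
        g_j=g_j,
        coupled=bool(g_j > coupling_threshold),
        gating_excluded=bool(g_j >= gj_exclusion),
    )


def boltzmann(vj_abs, g_max: float, g_min: float, v0: float, a: float):
    """Two-state Boltzmann steady-state conductance at |vj|."""
    vj_abs = np.asarray(vj_abs, dtype=float)
    with np.errstate(over="ignore"):
        return (g_max - g_min) / (1.0 + np.exp(a * (vj_abs - v0))) + g_min


@dataclass
class BoltzmannFit:
    polarity: str  # '+' or '-'
    g_max: float
    g_min: float
    v0: float  # absolute value, mV
    a: float  # 1/mV
    rss: float
    converged: bool
    degenerate: bool = False
    n_points: int = 0

    def predict(self, vj_abs):
        return boltzmann(vj_abs, self.g_max, self.g_min, self.v0, self.a)


_BOUNDS_LO = np.array([0.0, 0.0, 0.0, 0.0])  # g_max, g_min, v0, a
_BOUNDS_HI = np.array([1.5, 1.5, 150.0, 1.0])
_V0_STARTS = (20.0, 40.0, 60.0, 80.0)


def fit_boltzmann(points, polarity: str) -> BoltzmannFit:
    """Least-squares Boltzmann fit of (vj, g_norm) points on one polarity.

    ``points`` is an iterable of (vj, g_norm); only points whose vj sign
    matches ``polarity`` are used and at least 4 distinct |vj| are required.
    Bounded least squares (0 <= g_min, g_max <= 1.5, 0 <= v0 <= 150 mV,
    0 <= a <= 1 /mV) with multistart over v0 in {20, 40, 60, 80} mV; the
    best converged start is reported. A fit pinned at a ~ 0 (or with an
    essentially flat plateau span) is flagged degenerate.
    """
    if polarity not in ("+", "-"):
        raise ValueError("polarity must be '+' or '-'")
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (vj, g_norm) pairs")
    mask = pts[:, 0] > 0 if polarity == "+" else pts[:, 0] < 0
    sel = pts[mask]
    vj_abs = np.abs(sel[:, 0])
    g = sel[:, 1]
    if len(np.unique(np.round(vj_abs, 6))) < 4:
        raise ValueError(
            f"need >= 4 distinct |vj| on polarity '{polarity}', "
            f"got {len(np.unique(vj_abs))}"
        )

    def resid(theta):
        return boltzmann(vj_abs, *theta) - g

    g_hi = float(np.clip(np.max(g), 0.05, 1.5))
    g_lo = float(np.clip(np.min(g), 0.0, g_hi))
    best = None
    for v0_start in _V0_STARTS:
        x0 = np.clip(
            [g_hi, g_lo, v0_start, 0.1], _BOUNDS_LO + 1e-12, _BOUNDS_HI - 1e-12
        )
        try:
            res = least_squares(
                resid, x0, bounds=(_BOUNDS_LO, _BOUNDS_HI), method="trf", xtol=1e-12,
                ftol=1e-12, gtol=1e-12,
            )
        except Exception:  # pragma: no cover - optimizer failure path
            continue
        if not res.success:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return BoltzmannFit(
            polarity, np.nan, np.nan, np.nan, np.nan, np.nan,
            converged=False, n_points=len(g),
        )
    g_max, g_min, v0, a = best.x
    degenerate = bool(a < 1e-3 or (g_max - g_min) < 0.02 or g_min > g_max)
    return BoltzmannFit(
        polarity=polarity,
        g_max=float(g_max),
        g_min=float(g_min),
        v0=float(v0),
        a=float(a),
        rss=float(2.0 * best.cost),
        converged=True,
        degenerate=degenerate,
        n_points=len(g),
    )


def fit_polarities(points) -> dict[str, BoltzmannFit]:
    """Fit both Vj polarities; polarities lacking points raise inside
    :func:`fit_boltzmann` and are reported as non-converged fits."""
    out = {}
    for pol in ("+", "-"):
        try:
            out[pol] = fit_boltzmann(points, pol)
        except ValueError:
            out[pol] = BoltzmannFit(
                pol, np.nan, np.nan, np.nan, np.nan, np.nan, converged=False
            )
    return out
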