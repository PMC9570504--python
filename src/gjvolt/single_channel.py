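"""Unitary-current analysis: amplitude histograms, slope conductance, dwells.

The chain mirrors standard single-channel practice: traces are low-pass
filtered with a 200 Hz Gaussian filter, an all-point amplitude histogram of
the first ~2 s of each step is decomposed into a sum of Gaussian components
(shared noise width, 2-4 components selected by BIC), the unitary current
i_j is the distance from the baseline component (nearest 0 pA) to the main
open component, and the slope unitary conductance gamma_j is the linear
regression slope of i_j against |Vj| across cell pairs. Open dwell times
come from half-amplitude threshold idealization with a fixed dead time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .filters import RISETIME_FC, gaussian_lowpass
from .sim import Trace

__all__ = [
    "AmplitudeEstimate",
    "EventList",
    "GammaFit",
    "gaussian_filter",
    "all_point_histogram",
    "fit_levels",
    "estimate_amplitude",
    "slope_gamma",
    "idealize",
    "dwell_stats",
]

DEFAULT_FC = 200.0  # Hz, analysis filter cutoff
DEFAULT_WINDOW_S = 2.0  # s of the step used for the all-point histogram
MIN_BIN_PA = 0.05  # floor on the histogram bin width
MAX_BIN_PA = 0.2  # cap: Freedman-Diaconis overestimates on multimodal data
MAIN_OPEN_MIN_WEIGHT = 0.05  # minimum sample fraction of the open component


def gaussian_filter(trace: Trace, fc: float = DEFAULT_FC) -> Trace:
    """Gaussian low-pass filter (-3 dB at ``fc``) preserving trace length."""
    return Trace(
        vj=trace.vj,
        samples=gaussian_lowpass(trace.samples, fc, trace.sampling_rate),
        sampling_rate=trace.sampling_rate,
        baseline_s=trace.baseline_s,
        step_s=trace.step_s,
        metadata=dict(trace.metadata),
    )


def all_point_histogram(
    trace: Trace,
    window_s: float = DEFAULT_WINDOW_S,
    pre_s: float = 0.0,
    min_bin: float = MIN_BIN_PA,
    max_bin: float = MAX_BIN_PA,
) -> tuple[np.ndarray, np.ndarray]:
    """All-point amplitude histogram of the first ``window_s`` of the step.

    ``pre_s`` seconds of pre-step baseline may be prepended to the segment
    to anchor the zero-current level. Bin width follows Freedman-Diaconis,
    clipped to [0.05, 0.2] pA: the floor avoids empty-bin noise, the cap
    keeps multimodal amplitude distributions (whose large IQR inflates the
    Freedman-Diaconis width) resolvable. Counts conserve the sample number.
    """
    fs = trace.sampling_rate
    onset = trace.onset_index
    i0 = max(0, onset - int(round(pre_s * fs)))
    i1 = min(trace.n_samples, onset + int(round(window_s * fs)))
    seg = trace.samples[i0:i1]
    if len(seg) == 0:
        raise ValueError("empty histogram segment")
    q75, q25 = np.percentile(seg, [75, 25])
    width = 2.0 * (q75 - q25) / max(len(seg), 1) ** (1.0 / 3.0)
    width = float(np.clip(width, min_bin, max_bin))
    lo = np.floor(seg.min() / width) * width
    n_bins = max(1, int(np.ceil((seg.max() - lo) / width + 1e-9)))
    edges = lo + width * np.arange(n_bins + 1)
    counts, _ = np.histogram(seg, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


@dataclass
class AmplitudeEstimate:
    """Gaussian decomposition of an all-point histogram at one Vj."""

    vj: float
    mu_baseline: float  # pA
    sd_baseline: float
    mu_open: float  # pA, main open component
    sd_open: float
    i_j: float  # |mu_open - mu_baseline|, pA
    sign: int  # sign of (mu_open - mu_baseline)
    n_components: int
    mu_sub: tuple[float, ...] = ()  # other (sub)conductance components
    residual: float = np.nan


def _sum_gaussians(x, sigma, *amp_mu):
    amps = np.asarray(amp_mu[0::2])
    mus = np.asarray(amp_mu[1::2])
    return np.sum(
        amps[:, None] * np.exp(-0.5 * ((x[None, :] - mus[:, None]) / sigma) ** 2),
        axis=0,
    )


def fit_levels(
    centers: np.ndarray,
    counts: np.ndarray,
    vj: float = np.nan,
    max_components: int = 4,
    min_weight: float = MAIN_OPEN_MIN_WEIGHT,
) -> AmplitudeEstimate | None:
    """Decompose a histogram into 2-4 Gaussian components.

    Components share one width (recording noise is level-independent); the
    component count K is chosen by BIC among {2..4}, seeded from
    prominence-based peak detection. The baseline is the component nearest
    0 pA and the main open level the component farthest from baseline
    carrying at least 5% of the samples. Returns ``None`` (no events) for
    unimodal histograms or when no open component passes the weight cut.
    """
    centers = np.asarray(centers, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(centers) < 4:
        return None
    bw = float(np.median(np.diff(centers)))
    n_samples = float(counts.sum())
    if n_samples <= 0:
        return None

    min_distance = max(1, int(round(0.3 / bw)))
    peaks, props = find_peaks(
        counts, prominence=0.05 * counts.max(), distance=min_distance
    )
    if len(peaks) < 2:
        return None
    order = np.argsort(props["prominences"])[::-1]
    peak_centers = centers[peaks[order][:max_components]]
    peak_heights = counts[peaks[order][:max_components]]

    span = centers[-1] - centers[0]
    best = None
    for k in range(2, max_components + 1):
        mus = list(peak_centers[:k])
        amps = list(peak_heights[:k])
        while len(mus) < k:
            # seed extra components in the widest gap between current means
            ms = np.sort(np.concatenate([mus, [centers[0], centers[-1]]]))
            gaps = np.diff(ms)
            j = int(np.argmax(gaps))
            mus.append(0.5 * (ms[j] + ms[j + 1]))
            amps.append(0.1 * counts.max())
        p0 = [max(2 * bw, 0.15)]
        for a, m in zip(amps, mus):
            p0 += [max(a, 1.0), m]
        lo = [bw / 2.0] + [0.0, centers[0] - bw] * k
        hi = [span] + [np.inf, centers[-1] + bw] * k
        w = np.sqrt(np.maximum(counts, 1.0))  # Poisson standard deviations
        try:
            popt, _ = curve_fit(
                _sum_gaussians, centers, counts, p0=p0, bounds=(lo, hi),
                sigma=w, absolute_sigma=True, maxfev=6000,
            )
        except (RuntimeError, ValueError):
            continue
        chi2 = float(np.sum(((_sum_gaussians(centers, *popt) - counts) / w) ** 2))
        bic = chi2 + (1 + 2 * k) * np.log(len(centers))
        if best is None or bic < best[0]:
            best = (bic, k, popt, chi2)
    if best is None:
        return None
    _, k, popt, rss = best
    sigma = float(popt[0])
    amps = np.asarray(popt[1::2])
    mus = np.asarray(popt[2::2])
    weights = amps * sigma * np.sqrt(2.0 * np.pi) / bw / n_samples

    # drop numerically empty components
    keep = weights > 1e-4
    if keep.sum() < 2:
        return None
    amps, mus, weights = amps[keep], mus[keep], weights[keep]

    i_base = int(np.argmin(np.abs(mus)))
    mu_b = float(mus[i_base])
    dist = np.abs(mus - mu_b)
    candidates = [
        i for i in range(len(mus)) if i != i_base and weights[i] >= min_weight
    ]
    if not candidates:
        return None
    i_open = max(candidates, key=lambda i: dist[i])
    mu_o = float(mus[i_open])
    subs = tuple(
        float(mus[i]) for i in range(len(mus)) if i not in (i_base, i_open)
    )
    return AmplitudeEstimate(
        vj=vj,
        mu_baseline=mu_b,
        sd_baseline=sigma,
        mu_open=mu_o,
        sd_open=sigma,
        i_j=abs(mu_o - mu_b),
        sign=int(np.sign(mu_o - mu_b) or 1),
        n_components=int(len(mus)),
        mu_sub=subs,
        residual=rss,
    )


def estimate_amplitude(
    trace: Trace,
    fc: float = DEFAULT_FC,
    window_s: float = DEFAULT_WINDOW_S,
    pre_s: float = 0.3,
) -> AmplitudeEstimate | None:
    """Filter -> all-point histogram -> Gaussian decomposition for one trace.

    A short stretch of pre-step baseline (``pre_s``) is included in the
    histogram so the zero-current level is always represented.
    """
    filt = gaussian_filter(trace, fc)
    pre_avail = min(pre_s, filt.baseline_s)
    centers, counts = all_point_histogram(filt, window_s=window_s, pre_s=pre_avail)
    return fit_levels(centers, counts, vj=trace.vj)


@dataclass
class GammaFit:
    """Slope unitary conductance from i_j-|Vj| linear regression."""

    slope: float  # pS, pooled regression on pair-averaged points
    intercept: float  # pA
    per_pair: dict[str, float]  # pair label -> slope (pS)
    mean: float  # mean of per-pair slopes (pS)
    sd: float  # SD of per-pair slopes (pS)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return float(slope), float(ym - slope * xm)


def slope_gamma(
    pair_amplitudes: dict[str, list[tuple[float, float]]],
    level_consistency: float = 0.6,
) -> GammaFit:
    """Slope unitary conductance gamma_j from per-pair (vj, i_j) sets.

    Per pair, i_j (pA, magnitudes) is averaged per |vj| regardless of
    polarity and regressed against |vj| (mV) with a free intercept; the
    slope in pA/mV times 1000 is pS. Pairs with fewer than two distinct
    |vj| are excluded with a warning. The headline slope is the pooled
    regression on pair-averaged points; per-pair slopes give mean +/- SD.

    When a sweep's histogram resolves only a subconductance level (the
    channel deactivated before sampling the main open state), its amplitude
    is far below replicate sweeps at the same |vj|; amplitudes below
    ``level_consistency`` times the largest replicate are discarded before
    averaging, mirroring the manual identification of the main open level.
    """
    per_pair: dict[str, float] = {}
    averaged: dict[float, list[float]] = {}
    for label, pts in pair_amplitudes.items():
        by_vj: dict[float, list[float]] = {}
        for vj, ij in pts:
            by_vj.setdefault(round(abs(vj), 6), []).append(abs(ij))
        for v, vals in by_vj.items():
            top = max(vals)
            by_vj[v] = [x for x in vals if x >= level_consistency * top]
        if len(by_vj) < 2:
            warnings.warn(
                f"pair {label!r} has < 2 distinct |vj|; excluded from gamma fit",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        x = np.array(sorted(by_vj))
        y = np.array([np.mean(by_vj[v]) for v in x])
        slope, _ = _ols(x, y)
        per_pair[label] = slope * 1000.0
        for v, yy in zip(x, y):
            averaged.setdefault(v, []).append(yy)
    if not per_pair:
        raise ValueError("no pair contributed >= 2 distinct |vj|")
    x = np.array(sorted(averaged))
    y = np.array([np.mean(averaged[v]) for v in x])
    if len(x) >= 2:
        slope, intercept = _ols(x, y)
    else:  # single shared |vj| across pairs: fall back to per-pair mean
        slope, intercept = np.mean(list(per_pair.values())) / 1000.0, 0.0
    slopes = np.array(list(per_pair.values()))
    return GammaFit(
        slope=slope * 1000.0,
        intercept=intercept,
        per_pair=per_pair,
        mean=float(slopes.mean()),
        sd=float(slopes.std(ddof=1)) if len(slopes) > 1 else 0.0,
    )


@dataclass
class EventList:
    """Alternating open/closed sojourns from threshold idealization.

    The residual and fully closed levels both fall below the half-amplitude
    threshold and are lumped as 'closed'.
    """

    events: list[tuple[str, float]] = field(default_factory=list)  # (state, s)
    dead_time: float = 0.0

    def open_durations(self) -> np.ndarray:
        return np.array([d for s, d in self.events if s == "open"])

    def __len__(self) -> int:
        return len(self.events)


def _runs(mask: np.ndarray) -> list[list]:
    """Run-length encode a boolean array into [state, length] pairs."""
    changes = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate([[0], changes, [len(mask)]])
    return [
        [bool(mask[b0]), int(b1 - b0)] for b0, b1 in zip(bounds[:-1], bounds[1:])
    ]


def _merge_short_runs(runs: list[list], min_len: int) -> list[list]:
    """Absorb runs shorter than ``min_len`` into their flanking sojourns,
    shortest first. Never increases the event count."""
    runs = [list(r) for r in runs]
    while len(runs) > 1:
        short = [i for i, (_, n) in enumerate(runs) if n < min_len]
        if not short:
            break
        i = min(short, key=lambda j: runs[j][1])
        if i == 0:
            runs[1][1] += runs[0][1]
            del runs[0]
        elif i == len(runs) - 1:
            runs[-2][1] += runs[-1][1]
            del runs[-1]
        else:
            runs[i - 1][1] += runs[i][1] + runs[i + 1][1]
            del runs[i : i + 2]
    return runs


def idealize(
    trace: Trace,
    levels: AmplitudeEstimate,
    fc: float = DEFAULT_FC,
    dead_time: float | None = None,
) -> EventList:
    """Half-amplitude threshold idealization of the step portion.

    The 200 Hz-filtered current is compared against the midpoint between
    the baseline and main-open levels; events shorter than the dead time
    (default 2x the filter rise time, ~3.3 ms at 200 Hz) are merged into
    the flanking sojourn.
    """
    if dead_time is None:
        dead_time = 2.0 * RISETIME_FC / fc
    filt = gaussian_lowpass(trace.samples, fc, trace.sampling_rate)
    x = filt[trace.onset_index :]
    thr = 0.5 * (levels.mu_baseline + levels.mu_open)
    s = np.sign(levels.mu_open - levels.mu_baseline)
    if s == 0 or len(x) == 0:
        return EventList(dead_time=dead_time)
    open_mask = s * x > s * thr
    if open_mask.all() or (~open_mask).all():
        # threshold outside the trace range: no crossings, no events
        return EventList(dead_time=dead_time)
    dt = 1.0 / trace.sampling_rate
    min_len = max(1, int(round(dead_time / dt)))
    runs = _merge_short_runs(_runs(open_mask), min_len)
    events = [("open" if st else "closed", n * dt) for st, n in runs]
    return EventList(events=events, dead_time=dead_time)


def dwell_stats(events_by_vj: dict[float, EventList]) -> pd.DataFrame:
    """Mean open dwell time per Vj (suitable for log-scale plotting).

    Vj entries with zero open events are absent from the output, not zero.
    """
    rows = []
    for vj, ev in sorted(events_by_vj.items()):
        opens = ev.open_durations()
        if len(opens) == 0:
            continue
        rows.append(
            {"vj": vj, "mean_open_s": float(opens.mean()), "n_events": len(opens)}
        )
    return pd.DataFrame(rows, columns=["vj", "mean_open_s", "n_events"])
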