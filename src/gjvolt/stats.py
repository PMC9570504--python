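"""Group-comparison tests implemented from first principles.

Kruskal-Wallis with tie correction, Dunn's post hoc z-tests against a
reference group (Bonferroni-adjusted by default), the Mann-Whitney U test
(exact enumeration of the U null distribution for small samples, normal
approximation with tie correction otherwise) and the pooled-variance
Student's t-test. Only tail areas of the chi-square, normal and t
distributions are taken from scipy.special; the test procedures themselves
carry no external statistical dependency.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "rankdata",
    "kruskal_wallis",
    "dunn_posthoc",
    "mann_whitney",
    "student_t",
    "KruskalResult",
    "MannWhitneyResult",
    "TTestResult",
]

EXACT_MW_LIMIT = 400  # exact U enumeration when n_a * n_b <= this


def rankdata(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based, midranks for ties)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(x: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups."""
    _, counts = np.unique(np.asarray(x, dtype=float), return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _chi2_sf(x: float, df: int) -> float:
    return float(special.gammaincc(df / 2.0, x / 2.0))


def _norm_sf(z: float) -> float:
    return float(0.5 * special.erfc(z / np.sqrt(2.0)))


@dataclass
class KruskalResult:
    h: float
    p: float
    df: int


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        out = {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}
    else:
        out = {str(i): np.asarray(v, dtype=float) for i, v in enumerate(groups)}
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for k, v in out.items():
        if len(v) < 1:
            raise ValueError(f"group {k!r} is empty")
    return out


def kruskal_wallis(groups) -> KruskalResult:
    """Kruskal-Wallis H test with tie correction.

    ``groups`` is a mapping label -> measurements (or a sequence of
    samples). p comes from the chi-square distribution with k-1 degrees of
    freedom. If all pooled values are identical, p = 1 by convention.
    """
    gs = _as_groups(groups)
    pooled = np.concatenate(list(gs.values()))
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need a total of at least 3 observations")
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for v in gs.values():
        r = ranks[start : start + len(v)]
        h += r.sum() ** 2 / len(v)
        start += len(v)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    df = len(gs) - 1
    if correction <= 0:  # every value identical
        return KruskalResult(h=0.0, p=1.0, df=df)
    h /= correction
    return KruskalResult(h=float(h), p=_chi2_sf(h, df), df=df)


def dunn_posthoc(groups, reference: str, adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post hoc z-tests of each group against ``reference``.

    Uses pooled mid-ranks with tie correction; the Bonferroni adjustment
    (default) multiplies each p by the number of performed comparisons.
    ``adjust='none'`` reports raw p.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError("adjust must be 'bonferroni' or 'none'")
    gs = _as_groups(groups)
    reference = str(reference)
    if reference not in gs:
        raise ValueError(f"reference group {reference!r} not found")
    pooled = np.concatenate(list(gs.values()))
    n_total = len(pooled)
    ranks = rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for k, v in gs.items():
        mean_ranks[k] = ranks[start : start + len(v)].mean()
        sizes[k] = len(v)
        start += len(v)
    var_term = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (
        12.0 * (n_total - 1)
    )
    others = [k for k in gs if k != reference]
    n_comp = len(others)
    rows = []
    for k in others:
        se = np.sqrt(var_term * (1.0 / sizes[k] + 1.0 / sizes[reference]))
        z = (mean_ranks[k] - mean_ranks[reference]) / se if se > 0 else 0.0
        p_raw = 2.0 * _norm_sf(abs(z))
        p_adj = min(1.0, p_raw * n_comp) if adjust == "bonferroni" else p_raw
        rows.append(
            {"group": k, "reference": reference, "z": float(z),
             "p_raw": float(p_raw), "p_adj": float(p_adj)}
        )
    return pd.DataFrame(rows)


@lru_cache(maxsize=128)
def _u_counts(n: int, m: int) -> tuple:
    """Null distribution of U for sample sizes (n, m) without ties:
    counts[u] arrangements with U = u, via the standard recursion
    f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u)."""
    tables: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n + 1):
        for j in range(m + 1):
            t = np.zeros(i * j + 1)
            if i == 0 or j == 0:
                t[0] = 1.0
            else:
                a = tables[(i - 1, j)]
                t[j : j + len(a)] += a
                b = tables[(i, j - 1)]
                t[: len(b)] += b
            tables[(i, j)] = t
    return tuple(tables[(n, m)])


@dataclass
class MannWhitneyResult:
    u: float
    p: float
    method: str  # 'exact' or 'normal'


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U is computed from mid-ranks of the first sample. Without ties and with
    n_a * n_b <= 400 the two-sided p sums both tails of the exact U null
    distribution; otherwise a normal approximation with tie correction and
    continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 1 or nb < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    tie_term = _tie_term(pooled)
    if tie_term == 0 and na * nb <= EXACT_MW_LIMIT:
        counts = np.asarray(_u_counts(na, nb))
        total = counts.sum()
        mid = na * nb / 2.0
        dev = abs(u - mid)
        mask = np.abs(np.arange(len(counts)) - mid) >= dev - 1e-9
        return MannWhitneyResult(u=u, p=float(counts[mask].sum() / total),
                                 method="exact")
    n = na + nb
    mu = na * nb / 2.0
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return MannWhitneyResult(u=u, p=1.0, method="normal")
    # continuity correction toward the mean
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return MannWhitneyResult(u=u, p=min(1.0, 2.0 * _norm_sf(z)), method="normal")


@dataclass
class TTestResult:
    t: float
    p: float
    df: int


def student_t(a, b) -> TTestResult:
    """Two-sided pooled-variance Student's t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("both samples need at least 2 observations")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, p=1.0, df=df)
        return TTestResult(t=float(np.sign(diff) * np.inf), p=0.0, df=df)
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(special.stdtr(df, -abs(t)))
    return TTestResult(t=float(t), p=p, df=df)
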