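"""Cohort-level summaries: distance statistics, quadrant tables, rank tests.

All tests are two-sided and unadjusted.  The paired comparison between
hole-to-corneal-center and pupil-to-corneal-center metrics uses the Wilcoxon
signed-rank test with zero differences dropped; correlations are Spearman
with average ranks for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .centration import CentrationRecord
from .errors import InputError

__all__ = [
    "TestResult",
    "CorrResult",
    "CohortSummary",
    "percent",
    "summarize",
    "wilcoxon_signed_rank",
    "spearman",
    "kappa_correlations",
    "format_p",
]

QUADRANTS = ["superior-nasal", "superior-temporal", "inferior-nasal", "inferior-temporal"]

DISTANCE_METRICS = ["d_hc_mm", "d_pc_mm", "d_hp_mm", "dhx_mm", "dhy_mm", "dpx_mm", "dpy_mm"]


def percent(count: int, total: int) -> float:
    """Percentage ``100*count/total`` rounded half-away-from-zero to 2 decimals."""
    if total <= 0:
        raise InputError("total must be positive")
    if not 0 <= count <= total:
        raise InputError(f"count {count} outside [0, {total}]")
    val = Decimal(count) * 100 / Decimal(total)
    return float(val.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def format_p(p: float) -> str:
    """p-value to 3 decimals, with '< 0.001' below that resolution."""
    if math.isnan(p):
        return "n/a"
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    flag: str = ""  # e.g. "all-zero-differences", "unavailable"


@dataclass(frozen=True)
class CorrResult:
    r: float
    p_value: float
    n: int
    flag: str = ""


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 25


def _wilcoxon_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic, ties allowed.

    Enumerates the null distribution of W+ by dynamic programming over the
    doubled (hence integer) midranks; the distribution is symmetric about
    half the rank sum, so the two-sided p doubles the smaller tail.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    s = int(np.rint(2 * w_plus))
    lower = dist[: s + 1].sum()
    upper = dist[s:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(a, b) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped.  The null distribution is exact (via
    enumeration over midranks) for up to 25 nonzero pairs and a normal
    approximation with tie and continuity corrections above.  The reported
    statistic is min(W+, W-).  If every difference is zero the test carries
    no information: p = 1 with a flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("paired samples must be 1-D and of equal length")
    if len(a) < 5:
        raise InputError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, n=0, flag="all-zero-differences")
    ranks = sps.rankdata(np.abs(d), method="average")
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)
    if n <= _EXACT_MAX_N:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        # tie correction on the variance
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        if var <= 0:
            return TestResult(statistic=stat, p_value=1.0, n=n, flag="zero-variance")
        diff = w_plus - mean
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)  # continuity correction
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(statistic=stat, p_value=p, n=n)


def spearman(a, b) -> CorrResult:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("samples must be 1-D and of equal length")
    if len(a) < 5:
        raise InputError("need at least 5 observations")
    if np.all(a == a[0]) or np.all(b == b[0]):
        return CorrResult(r=math.nan, p_value=math.nan, n=len(a), flag="zero-variance")
    res = sps.spearmanr(a, b)
    return CorrResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(a))


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    n: int
    metrics: dict = field(default_factory=dict)       # metric -> {mean, sd, min, max}
    quadrants: dict = field(default_factory=dict)     # table -> {label: {count, percent}}
    wilcoxon: dict = field(default_factory=dict)      # pair-name -> TestResult
    spearman: dict = field(default_factory=dict)      # pair-name -> CorrResult
    kappa: dict = field(default_factory=dict)         # pair-name -> CorrResult

    def to_dict(self) -> dict:
        def _tr(t: TestResult) -> dict:
            return {"statistic": t.statistic, "p_value": t.p_value, "n": t.n, "flag": t.flag}

        def _cr(c: CorrResult) -> dict:
            return {"r": c.r, "p_value": c.p_value, "n": c.n, "flag": c.flag}

        return {
            "n": self.n,
            "metrics": self.metrics,
            "quadrants": self.quadrants,
            "wilcoxon": {k: _tr(v) for k, v in self.wilcoxon.items()},
            "spearman": {k: _cr(v) for k, v in self.spearman.items()},
            "kappa": {k: _cr(v) for k, v in self.kappa.items()},
        }


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.to_row() for r in records])
    if df.empty:
        raise InputError("no records to summarize")
    return df


def _quadrant_table(labels: pd.Series, n: int) -> dict:
    counts = labels.value_counts().to_dict()
    return {
        q: {"count": int(counts.get(q, 0)), "percent": percent(int(counts.get(q, 0)), n)}
        for q in QUADRANTS
    }


def kappa_correlations(records) -> dict[str, CorrResult]:
    """Spearman correlations between kappa offsets and hole-position metrics.

    Pairs: (K-x, |x_H|), (K-y, |y_H|), (K-x, x_{H-P}), (K-y, y_{H-P}).
    Flagged absent when kappa offsets are missing.
    """
    df = _records_frame(records)
    pairs = {
        "kx_vs_dhx": ("kappa_x_mm", "dhx_mm"),
        "ky_vs_dhy": ("kappa_y_mm", "dhy_mm"),
        "kx_vs_dhpx": ("kappa_x_mm", "dhpx_mm"),
        "ky_vs_dhpy": ("kappa_y_mm", "dhpy_mm"),
    }
    out: dict[str, CorrResult] = {}
    for name, (ka, met) in pairs.items():
        if ka not in df.columns or df[ka].isna().any():
            out[name] = CorrResult(r=math.nan, p_value=math.nan, n=0, flag="kappa-absent")
        else:
            out[name] = spearman(df[ka].to_numpy(), df[met].to_numpy())
    return out


def summarize(records) -> CohortSummary:
    """Aggregate per-eye centration records into the cohort summary.

    SD is the sample (n-1) standard deviation.  Rank tests require n >= 5
    and are otherwise flagged unavailable; dispersion requires n >= 2.
    """
    df = _records_frame(records)
    n = len(df)
    if n < 2:
        raise InputError("need at least 2 records for dispersion statistics")
    summary = CohortSummary(n=n)
    for m in DISTANCE_METRICS:
        col = df[m].astype(float)
        summary.metrics[m] = {
            "mean": float(col.mean()),
            "sd": float(col.std(ddof=1)),
            "min": float(col.min()),
            "max": float(col.max()),
        }
    for table, col in (
        ("hole_vs_cornea", "quadrant_hc"),
        ("hole_vs_pupil", "quadrant_hp"),
        ("pupil_vs_cornea", "quadrant_pc"),
    ):
        summary.quadrants[table] = _quadrant_table(df[col], n)

    test_pairs = {
        "d_hc_vs_d_pc": ("d_hc_mm", "d_pc_mm"),
        "dhx_vs_dpx": ("dhx_mm", "dpx_mm"),
        "dhy_vs_dpy": ("dhy_mm", "dpy_mm"),
    }
    if n >= 5:
        for name, (ca, cb) in test_pairs.items():
            summary.wilcoxon[name] = wilcoxon_signed_rank(df[ca].to_numpy(), df[cb].to_numpy())
            summary.spearman[name] = spearman(df[ca].to_numpy(), df[cb].to_numpy())
        summary.kappa = kappa_correlations(df)
    else:
        unavailable = TestResult(math.nan, math.nan, n, flag="unavailable")
        for name in test_pairs:
            summary.wilcoxon[name] = unavailable
            summary.spearman[name] = CorrResult(math.nan, math.nan, n, flag="unavailable")
    return summary


def summary_markdown(summary: CohortSummary) -> str:
    """Human-readable Markdown rendering of a cohort summary."""
    lines = [f"# Centration cohort summary (n = {summary.n})", ""]
    lines += ["## Distances (mm)", "", "| metric | mean | SD | min | max |", "|---|---|---|---|---|"]
    for m, s in summary.metrics.items():
        lines.append(
            f"| {m} | {s['mean']:.4f} | {s['sd']:.4f} | {s['min']:.4f} | {s['max']:.4f} |"
        )
    for table, rows in summary.quadrants.items():
        lines += ["", f"## Quadrants: {table.replace('_', ' ')}", "",
                  "| quadrant | count | percent |", "|---|---|---|"]
        for q, v in rows.items():
            lines.append(f"| {q} | {v['count']} | {v['percent']:.2f} |")
    if summary.wilcoxon:
        lines += ["", "## Wilcoxon signed-rank (two-sided)", "",
                  "| pair | statistic | p |", "|---|---|---|"]
        for name, t in summary.wilcoxon.items():
            stat = "n/a" if math.isnan(t.statistic) else f"{t.statistic:.1f}"
            lines.append(f"| {name} | {stat} | {format_p(t.p_value)} |")
    if summary.spearman:
        lines += ["", "## Spearman correlations", "", "| pair | r | p |", "|---|---|---|"]
        for name, c in summary.spearman.items():
            r = "n/a" if math.isnan(c.r) else f"{c.r:.3f}"
            lines.append(f"| {name} | {r} | {format_p(c.p_value)} |")
    usable_kappa = {k: v for k, v in summary.kappa.items() if v.flag != "kappa-absent"}
    if usable_kappa:
        lines += ["", "## Kappa-offset correlations", "", "| pair | r | p |", "|---|---|---|"]
        for name, c in usable_kappa.items():
            lines.append(f"| {name} | {c.r:.3f} | {format_p(c.p_value)} |")
    elif summary.kappa:
        lines += ["", "_Kappa offsets absent from input; kappa correlations omitted._"]
    return "\n".join(lines) + "\n"
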