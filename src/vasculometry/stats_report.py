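"""Group-level statistics: mean +- SD summaries and Student's t-test.

The between-group comparison is the classic pooled-variance two-sided
Student's t-test (df = n1 + n2 - 2); Welch's unequal-variance variant is
available behind a flag.  No multiple-testing correction is applied across
metrics — a documented limitation of the reporting contract this module
mirrors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GroupSummary:
    label: str
    n: int
    metrics: dict[str, tuple[float, float | None]]  # name -> (mean, sd or None)

    def mean(self, metric: str) -> float:
        return self.metrics[metric][0]

    def sd(self, metric: str) -> float | None:
        return self.metrics[metric][1]


@dataclass
class ComparisonResult:
    metric: str
    t: float
    df: float
    p: float
    alpha: float
    significant: bool


def mean_sd(values) -> tuple[float, float | None]:
    """Mean and sample SD (n-1 denominator); SD is None for n < 2."""
    v = np.asarray(list(values), float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size >= 2 else None
    return mean, sd


def summarize_group(values, label: str = "group") -> GroupSummary:
    """Summarize one group as mean +- SD per metric.

    ``values`` is either a flat sequence (summarized under the metric name
    ``"value"``) or a mapping metric -> sequence of per-specimen values.
    """
    if isinstance(values, dict):
        metrics = {k: mean_sd(v) for k, v in values.items()}
        n = len(next(iter(values.values()))) if values else 0
    else:
        metrics = {"value": mean_sd(values)}
        n = len(list(values))
    return GroupSummary(label, n, metrics)


def two_sample_ttest(a, b, alpha: float = 0.05, welch: bool = False,
                     metric: str = "value") -> ComparisonResult:
    """Two-sided Student's t-test (pooled variance by default)."""
    from scipy import stats

    a = np.asarray(list(a), float)
    b = np.asarray(list(b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            if ma == mb:
                return ComparisonResult(metric, 0.0, float(na + nb - 2), 1.0, alpha, False)
            raise ValueError("zero variance with unequal means: t undefined")
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if sp2 == 0:
            if ma == mb:
                return ComparisonResult(metric, 0.0, df, 1.0, alpha, False)
            raise ValueError("zero pooled variance with unequal means: t undefined")
        t = (ma - mb) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return ComparisonResult(metric, float(t), float(df), p, alpha, p < alpha)


DEFAULT_METRICS = ("VV_mm3", "VN", "VNN", "VD_mean_um")


def compare_morphometry(normal_reports, injured_reports, alpha: float = 0.05,
                        metrics=DEFAULT_METRICS, welch: bool = False) -> pd.DataFrame:
    """One pooled t-test per metric between the normal and injured arms.

    ``*_reports`` are sequences of ``MorphometryReport`` (or of plain
    metric dicts).  Returns a table with one row per metric: group means
    +- SD, t, df, p and the significance flag — the layout of a standard
    normal-vs-injury morphometry table.
    """
    def extract(reports, metric):
        out = []
        for r in reports:
            d = r if isinstance(r, dict) else r.metrics()
            if metric not in d:
                raise ValueError(f"report lacks metric {metric!r}")
            out.append(float(d[metric]))
        return out

    if len(normal_reports) < 2 or len(injured_reports) < 2:
        raise ValueError("need >= 2 reports per arm")
    rows = []
    for metric in metrics:
        a = extract(normal_reports, metric)
        b = extract(injured_reports, metric)
        res = two_sample_ttest(a, b, alpha=alpha, welch=welch, metric=metric)
        (man, sdn), (mai, sdi) = mean_sd(a), mean_sd(b)
        rows.append({
            "metric": metric,
            "normal_mean": man, "normal_sd": sdn,
            "injured_mean": mai, "injured_sd": sdi,
            "t": res.t, "df": res.df, "p": res.p,
            "significant": res.significant,
        })
    return pd.DataFrame(rows)
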