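"""Paired statistics and study report generation.

The study design is paired: every heart is measured at baseline and
again under the intervention, so continuous endpoints use the paired
Student t-test and categorical endpoints (inducibility) use Fisher's
exact test.  Both are implemented from first principles here — the t
statistic and its two-sided p through the regularized incomplete beta
function, Fisher's p by exact integer hypergeometric enumeration with
the point-probability (sum of all tables no more probable than the
observed one) two-sided convention.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.special import betainc


@dataclass
class PairedSample:
    """Per-heart measurements under two conditions (same hearts)."""

    heart_ids: list
    value_a: np.ndarray
    value_b: np.ndarray

    def __post_init__(self) -> None:
        self.value_a = np.asarray(self.value_a, dtype=float)
        self.value_b = np.asarray(self.value_b, dtype=float)
        if not (len(self.heart_ids) == len(self.value_a) == len(self.value_b)):
            raise ValueError("paired sample lengths differ")
        if np.any(~np.isfinite(self.value_a)) or np.any(~np.isfinite(self.value_b)):
            raise ValueError("paired sample contains missing values")


@dataclass
class PairedTResult:
    t: float
    df: int
    p_two_sided: float
    mean_diff: float
    sd_diff: float
    n: int


def t_sf(t: float, df: int) -> float:
    """Two-sided tail probability of the t distribution via the
    regularized incomplete beta function."""
    if not np.isfinite(t):
        return 0.0
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def paired_t_test(sample: PairedSample) -> PairedTResult:
    """Paired Student t-test: t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.

    All-zero-variance differences are an edge case: p is reported as
    exactly 1.0 when the mean difference is zero and 0.0 otherwise
    (a degenerate, perfectly consistent shift).
    """
    d = sample.value_b - sample.value_a
    n = len(d)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return PairedTResult(math.inf if mean != 0 else 0.0, n - 1,
                             0.0 if mean != 0 else 1.0, mean, 0.0, n)
    t = mean / (sd / math.sqrt(n))
    return PairedTResult(float(t), n - 1, t_sf(t, n - 1), mean, sd, n)


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] of condition x outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    With margins fixed, every admissible table's probability is an
    exact rational C(r1, x) C(r2, k - x) / C(n, k); the two-sided p
    sums those no larger than the observed table's (point-probability
    convention).  Degenerate margins give p = 1.  Exact integer
    arithmetic: no rounding error for any table size used here.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    k = a + c  # first-column total
    n = a + b + c + d
    if r1 == 0 or r2 == 0 or k == 0 or k == n:
        return 1.0
    # all terms share the denominator C(n, k): compare integer numerators,
    # so ties are exact and no floating comparison is ever needed
    num_obs = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for x in range(max(0, k - r2), min(k, r1) + 1):
        num_x = math.comb(r1, x) * math.comb(r2, k - x)
        if num_x <= num_obs:
            total += num_x
    return float(min(Fraction(total, math.comb(n, k)), Fraction(1)))


def summarize(metrics: dict, tests: dict | None = None, config: dict | None = None) -> dict:
    """Machine-readable study report.

    ``metrics`` maps metric name -> {condition -> {mean, sd, n}};
    ``tests`` maps metric name -> test-result dict.  The report echoes
    every configured threshold for provenance and adds the direction of
    each paired change.  Deterministic given inputs.
    """
    report: dict = {"metrics": {}, "tests": {}, "config": config or {}}
    for name in sorted(metrics):
        report["metrics"][name] = metrics[name]
        conds = metrics[name]
        if len(conds) == 2:
            (ca, va), (cb, vb) = sorted(conds.items())
            if "mean" in va and "mean" in vb:
                delta = vb["mean"] - va["mean"]
                report["metrics"][name]["direction"] = (
                    "increase" if delta > 0 else "decrease" if delta < 0 else "unchanged"
                )
                report["metrics"][name]["delta"] = delta
    for name in sorted(tests or {}):
        report["tests"][name] = tests[name]
    return report


def report_to_text(report: dict) -> str:
    """Human-readable rendering of a summary report."""
    lines = []
    for name, entry in report.get("metrics", {}).items():
        parts = [name]
        for cond, v in entry.items():
            if isinstance(v, dict) and "mean" in v:
                sd = v.get("sd", float("nan"))
                parts.append(f"{cond}: {v['mean']:.2f} +/- {sd:.2f} (n={v.get('n', '?')})")
        if "direction" in entry:
            parts.append(entry["direction"])
        lines.append("  ".join(parts))
    for name, tr in report.get("tests", {}).items():
        keys = ", ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                         for k, v in tr.items())
        lines.append(f"{name}: {keys}")
    return "\n".join(lines)


def report_roundtrip_ok(report: dict) -> bool:
    """A report must survive JSON serialization unchanged."""
    return json.loads(json.dumps(report)) == json.loads(json.dumps(report))
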