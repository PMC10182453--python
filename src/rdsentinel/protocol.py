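"""Multi-seed evaluation protocol: repetitions, CIs, and input comparison.

Experiments are repeated over several random seeds (five by default); each
metric is reported as the mean with a 95% t-distribution confidence
interval.  Query-input and session-input results are compared with a
two-sided Welch t-test over the per-seed values, together with the
headline statistic — the relative decrease in error achieved by the
session input, (mean_query - mean_session) / mean_query x 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RunSet",
    "confidence_interval",
    "repeat_runs",
    "ComparisonResult",
    "compare_inputs",
    "report_table",
]


def confidence_interval(values, level: float = 0.95) -> tuple[float, float]:
    """t-distribution CI: mean +/- t_{n-1, (1+level)/2} * sd / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("confidence interval needs at least two values")
    mean = values.mean()
    sem = values.std(ddof=1) / np.sqrt(n)
    t_crit = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return float(mean - t_crit * sem), float(mean + t_crit * sem)


@dataclass(frozen=True)
class RunSet:
    """One metric's values over repeated seeded runs, with a 95% CI."""

    metric: str
    values: tuple[float, ...]
    level: float = 0.95

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def ci(self) -> tuple[float, float]:
        return confidence_interval(self.values, self.level)

    @property
    def ci_low(self) -> float:
        return self.ci[0]

    @property
    def ci_high(self) -> float:
        return self.ci[1]


def repeat_runs(
    run: Callable[[int], Mapping[str, float]],
    seeds: Sequence[int],
) -> dict[str, RunSet]:
    """Run a seeded experiment per seed and collect each metric's RunSet.

    ``run(seed)`` returns a metric -> value mapping; a failure in any run
    aborts the whole set with the offending seed named.
    """
    if len(seeds) < 2:
        raise ValueError("need at least two seeds")
    collected: dict[str, list[float]] = {}
    for seed in seeds:
        try:
            result = run(seed)
        except Exception as exc:  # identify which repetition broke
            raise RuntimeError(f"run failed for seed {seed}: {exc}") from exc
        for k, v in result.items():
            collected.setdefault(k, []).append(float(v))
    lengths = {len(v) for v in collected.values()}
    if lengths != {len(seeds)}:
        raise ValueError("runs reported inconsistent metric sets")
    return {k: RunSet(metric=k, values=tuple(v)) for k, v in collected.items()}


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    relative_decrease_pct: float


def compare_inputs(
    runset_query: RunSet,
    runset_session: RunSet,
    paired: bool = False,
) -> ComparisonResult:
    """Compare query-input vs session-input results on the same metric.

    Two-sided Welch t-test (or paired t-test when runs share seeds) on the
    per-seed values; the relative decrease is the percentage by which the
    session input lowers the mean error relative to the query input.
    """
    if runset_query.metric != runset_session.metric:
        raise ValueError("RunSets measure different metrics")
    q = np.asarray(runset_query.values, dtype=float)
    s = np.asarray(runset_session.values, dtype=float)
    if q.std(ddof=0) == 0 and s.std(ddof=0) == 0:
        p = 1.0 if q.mean() == s.mean() else 0.0
    elif paired:
        p = float(stats.ttest_rel(q, s).pvalue)
    else:
        p = float(stats.ttest_ind(q, s, equal_var=False).pvalue)
    if runset_query.mean == 0:
        raise ValueError("relative decrease undefined: query mean is zero")
    decrease = (runset_query.mean - runset_session.mean) / runset_query.mean * 100.0
    return ComparisonResult(p_value=p, relative_decrease_pct=decrease)


def report_table(results: Mapping[str, Mapping[str, Mapping[str, RunSet]]]) -> str:
    """Markdown table of variant x input-type results with CIs and p-values.

    ``results[variant][input_type][metric]`` is a RunSet; input types are
    "query" and "session".
    """
    lines = [
        "| Model | Input | RER (95% CI) | RMSE (95% CI) | P (RER) |",
        "|---|---|---|---|---|",
    ]
    for variant, by_input in results.items():
        p_txt = ""
        if "query" in by_input and "session" in by_input:
            cmp_ = compare_inputs(by_input["query"]["rer"], by_input["session"]["rer"])
            p_txt = f"{cmp_.p_value:.3g}"
        for input_type, metrics in by_input.items():
            rer_rs = metrics["rer"]
            rmse_rs = metrics["rmse"]
            lines.append(
                f"| {variant} | {input_type} "
                f"| {rer_rs.mean:.3f} ({rer_rs.ci_low:.3f}-{rer_rs.ci_high:.3f}) "
                f"| {rmse_rs.mean:.3f} ({rmse_rs.ci_low:.3f}-{rmse_rs.ci_high:.3f}) "
                f"| {p_txt} |"
            )
            p_txt = ""
    return "\n".join(lines)
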