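"""Diagnostic-performance evaluation of an index test against a reference.

Builds the 2x2 ("fourfold") cross-tabulation of an index test (here
usually Kid-SMS, positive from the moderate category upward) against a
reference standard (Ghent-2 diagnosis), and derives sensitivity,
specificity, predictive values — each with an exact two-sided
Clopper-Pearson confidence interval — the positive likelihood ratio
sens/(1-spec), and the two-sided Fisher exact p-value
(probability-ordering convention, as implemented in scipy).

Statistics whose margin is empty are flagged undefined rather than
propagated as NaN.  Internal values are never pre-rounded; report
formatting (whole percents, two-decimal CI bounds, one-decimal LR) is
applied only in :func:`format_report` / :func:`report_keyvalues`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import scipy.stats

from .cohort import PhenotypeRecord


@dataclass(frozen=True)
class FourfoldTable:
    """TP/FP/FN/TN counts of index test vs. reference standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
        if self.total == 0:
            raise ValueError("fourfold table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class ProportionWithCI:
    numerator: int
    denominator: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Performance statistics; ``None`` fields are listed in ``undefined``."""

    sensitivity: Optional[ProportionWithCI]
    specificity: Optional[ProportionWithCI]
    ppv: Optional[ProportionWithCI]
    npv: Optional[ProportionWithCI]
    positive_lr: Optional[float]
    fisher_p: float
    undefined: tuple[str, ...]


def build_fourfold(
    cohort: Iterable[PhenotypeRecord],
    index_positive: Callable[[PhenotypeRecord], bool],
    reference_positive: Callable[[PhenotypeRecord], bool],
) -> FourfoldTable:
    """Cross-tabulate two predicates over a cohort."""
    tp = fp = fn = tn = 0
    for record in cohort:
        index = bool(index_positive(record))
        reference = bool(reference_positive(record))
        if index and reference:
            tp += 1
        elif index:
            fp += 1
        elif reference:
            fn += 1
        else:
            tn += 1
    if tp + fp + fn + tn == 0:
        raise ValueError("cannot build a fourfold table from an empty cohort")
    return FourfoldTable(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson_ci(
    numerator: int, denominator: int, level: float = 0.95
) -> ProportionWithCI:
    """Exact (Clopper-Pearson) two-sided binomial confidence interval.

    Bounds come from beta-distribution quantiles; at the boundaries the
    lower bound is exactly 0 for numerator 0 and the upper exactly 1
    for numerator = denominator.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    k, n = numerator, denominator
    low = 0.0 if k == 0 else float(scipy.stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(scipy.stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionWithCI(
        numerator=k,
        denominator=n,
        estimate=k / n,
        ci_low=low,
        ci_high=high,
        level=level,
    )


def fisher_exact(table: FourfoldTable, alternative: str = "two_sided") -> float:
    """Two-sided Fisher exact p-value for a fourfold table.

    Uses the probability-ordering convention: the p-value sums the
    hypergeometric probabilities of all tables with the observed
    margins that are no more probable than the observed one.  Only the
    two-sided alternative is exposed.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    return float(
        scipy.stats.fisher_exact(
            [[table.tp, table.fp], [table.fn, table.tn]], alternative="two-sided"
        ).pvalue
    )


def performance(table: FourfoldTable, level: float = 0.95) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV (each with exact CI), LR+, Fisher p.

    Any statistic whose denominator (margin) is zero is returned as
    ``None`` and named in ``undefined``.  The positive likelihood ratio
    is sens/(1-spec), +infinity when specificity is exactly 1, and
    undefined whenever sensitivity or specificity is.
    """
    margins = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.fp + table.tn),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.fn + table.tn),
    }
    stats: dict[str, Optional[ProportionWithCI]] = {}
    undefined: list[str] = []
    for name, (k, n) in margins.items():
        if n == 0:
            stats[name] = None
            undefined.append(name)
        else:
            stats[name] = clopper_pearson_ci(k, n, level)

    sens, spec = stats["sensitivity"], stats["specificity"]
    if sens is None or spec is None:
        positive_lr: Optional[float] = None
        undefined.append("positive_lr")
    elif spec.estimate == 1.0:
        positive_lr = math.inf
    else:
        positive_lr = sens.estimate / (1.0 - spec.estimate)

    return DiagnosticPerformance(
        sensitivity=stats["sensitivity"],
        specificity=stats["specificity"],
        ppv=stats["ppv"],
        npv=stats["npv"],
        positive_lr=positive_lr,
        fisher_p=fisher_exact(table),
        undefined=tuple(undefined),
    )


def unpaired_t_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Convenience two-sample (unpaired, equal-variance) t-test p-value.

    A thin wrapper for cohort summary comparisons of quantitative
    variables; not part of the diagnostic-performance surface.
    """
    return float(scipy.stats.ttest_ind(list(a), list(b), equal_var=True).pvalue)


# --- report formatting -------------------------------------------------
#
# Printing convention: proportions as whole percents, CI bounds to two
# decimals, likelihood ratio to one decimal.


def _pct(p: Optional[ProportionWithCI]) -> str:
    if p is None:
        return "undefined"
    return (
        f"{p.estimate * 100:.0f}% "
        f"(CI {p.level * 100:.0f}% {p.ci_low:.2f} to {p.ci_high:.2f})"
    )


def _lr(value: Optional[float]) -> str:
    if value is None:
        return "undefined"
    if math.isinf(value):
        return "inf"
    return f"{value:.1f}"


def format_report(table: FourfoldTable, perf: DiagnosticPerformance) -> str:
    """Human-readable evaluation report."""
    lines = [
        "Fourfold table (index test vs. reference standard)",
        f"  TP={table.tp}  FP={table.fp}",
        f"  FN={table.fn}  TN={table.tn}",
        f"Sensitivity: {_pct(perf.sensitivity)}",
        f"Specificity: {_pct(perf.specificity)}",
        f"PPV:         {_pct(perf.ppv)}",
        f"NPV:         {_pct(perf.npv)}",
        f"Positive likelihood ratio: {_lr(perf.positive_lr)}",
        f"Fisher exact p (two-sided): {perf.fisher_p:.3g}",
    ]
    if perf.undefined:
        lines.append(f"Undefined statistics: {', '.join(perf.undefined)}")
    return "\n".join(lines)


def report_keyvalues(
    table: FourfoldTable, perf: DiagnosticPerformance
) -> dict[str, str]:
    """Flat key-value form of the report for downstream tooling."""
    out: dict[str, str] = {
        "tp": str(table.tp),
        "fp": str(table.fp),
        "fn": str(table.fn),
        "tn": str(table.tn),
    }
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        stat: Optional[ProportionWithCI] = getattr(perf, name)
        if stat is None:
            out[name] = "undefined"
        else:
            out[f"{name}_percent"] = f"{stat.estimate * 100:.0f}"
            out[f"{name}_ci_low"] = f"{stat.ci_low:.2f}"
            out[f"{name}_ci_high"] = f"{stat.ci_high:.2f}"
    out["positive_lr"] = _lr(perf.positive_lr)
    out["fisher_p"] = repr(perf.fisher_p)
    return out


def write_keyvalues(values: dict[str, str], path: Union[str, Path]) -> None:
    """Write a flat ``key=value`` report file, one entry per line."""
    text = "".join(f"{key}={value}\n" for key, value in values.items())
    Path(path).write_text(text, encoding="utf-8")
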