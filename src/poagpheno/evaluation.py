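"""Chart-review performance arithmetic: confusion counts, PPV/NPV/sensitivity/
specificity/accuracy, and the percent formatter matching the published
convention.

All metrics are computed in exact rational arithmetic (``fractions.Fraction``)
before any formatting.  The published percentages are consistent with
*truncation* at one decimal place, not rounding — 138/267 = 51.68…% prints
as 51.6% — so truncation is the default formatter, with conventional
rounding available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "ppv",
    "npv",
    "accuracy",
    "sensitivity",
    "specificity",
    "format_percent_trunc",
    "format_percent",
    "UndefinedMetricError",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(
    predicted: dict[str, str],
    truth: dict[str, str],
) -> ConfusionCounts:
    """Exhaustive 2x2 tally of {positive, negative} labels over a shared key set."""
    if set(predicted) != set(truth):
        raise ValueError("predicted and truth must cover the same subjects")
    tp = fp = tn = fn = 0
    for sid, pred in predicted.items():
        true = truth[sid]
        if pred not in ("positive", "negative") or true not in ("positive", "negative"):
            raise ValueError(f"labels must be positive/negative, got {pred!r}/{true!r}")
        if pred == "positive":
            if true == "positive":
                tp += 1
            else:
                fp += 1
        else:
            if true == "negative":
                tn += 1
            else:
                fn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int, name: str) -> Fraction:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: zero denominator")
    return Fraction(num, den)


def ppv(c: ConfusionCounts) -> Fraction:
    """Positive predictive value TP/(TP+FP)."""
    return _ratio(c.tp, c.tp + c.fp, "PPV")


def npv(c: ConfusionCounts) -> Fraction:
    """Negative predictive value TN/(TN+FN)."""
    return _ratio(c.tn, c.tn + c.fn, "NPV")


def accuracy(c: ConfusionCounts) -> Fraction:
    """(TP+TN) over all positives (TP+FP) plus all negatives (TN+FN)."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def sensitivity(c: ConfusionCounts) -> Fraction:
    """TP/(TP+FN)."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> Fraction:
    """TN/(TN+FP)."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def format_percent_trunc(x: Fraction | float, decimals: int = 1) -> str:
    """Format a proportion as a percentage truncated (floored) at *decimals*.

    0.51685 -> "51.6" at one decimal; 0.999 -> "99" at zero.  Truncation
    reproduces the published percentages exactly; see :func:`format_percent`
    for conventional rounding.
    """
    if not 0 <= x <= 1:
        raise ValueError(f"proportion {x} outside [0, 1]")
    frac = x if isinstance(x, Fraction) else Fraction(str(x))
    scaled = frac * 100 * 10**decimals
    truncated = scaled.numerator // scaled.denominator
    if decimals == 0:
        return str(truncated)
    s = str(truncated).rjust(decimals + 1, "0")
    return f"{s[:-decimals]}.{s[-decimals:]}"


def format_percent(x: Fraction | float, decimals: int = 1) -> str:
    """Conventional half-up rounding of a proportion to a percentage string."""
    if not 0 <= x <= 1:
        raise ValueError(f"proportion {x} outside [0, 1]")
    frac = x if isinstance(x, Fraction) else Fraction(str(x))
    scaled = frac * 100 * 10**decimals
    # round half up, exact
    rounded = (2 * scaled.numerator + scaled.denominator) // (2 * scaled.denominator)
    if decimals == 0:
        return str(rounded)
    s = str(rounded).rjust(decimals + 1, "0")
    return f"{s[:-decimals]}.{s[-decimals:]}"
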