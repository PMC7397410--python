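"""Screening-performance and method-agreement statistics.

Sensitivity, specificity, PPV and NPV from a confusion table; overall
percent agreement (coincidence rate) and Cohen's Kappa from a 2x2
agreement table of two raters (here: the window-resolved caller vs the
plain whole-chromosome caller) on the same samples.

Percentages are rounded half-up to 2 decimal places for reports; raw
fractions are retained.  A metric whose denominator is zero is reported
as None (undefined), never silently 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ConfusionTable",
    "AgreementTable",
    "screening_metrics",
    "coincidence_rate",
    "cohen_kappa",
    "evaluate_cohort",
    "CohortEvaluation",
    "round_pct",
]


def round_pct(fraction: float | None, digits: int = 2) -> float | None:
    """Fraction -> percentage, rounded half-up to ``digits`` decimals."""
    if fraction is None:
        return None
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """Binary screening outcome counts against verified truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AgreementTable:
    """2x2 cross-classification of two raters: a=++, b=+-, c=-+, d=--."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def screening_metrics(t: ConfusionTable) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV as fractions (None if undefined)."""
    if t.total == 0:
        raise ValueError("empty confusion table")
    return {
        "sensitivity": _ratio(t.tp, t.tp + t.fn),
        "specificity": _ratio(t.tn, t.tn + t.fp),
        "ppv": _ratio(t.tp, t.tp + t.fp),
        "npv": _ratio(t.tn, t.tn + t.fn),
    }


def coincidence_rate(t: AgreementTable) -> float:
    """Overall percent agreement (a + d) / n, as a fraction."""
    if t.total == 0:
        raise ValueError("empty agreement table")
    return (t.a + t.d) / t.total


def cohen_kappa(t: AgreementTable) -> float | None:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    p_o is observed agreement; p_e the agreement expected from the
    marginals.  Returns None when p_e == 1 (degenerate marginals).
    """
    n = t.total
    if n == 0:
        raise ValueError("empty agreement table")
    p_o = (t.a + t.d) / n
    p_e = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / (n * n)
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class CohortEvaluation:
    """Per-target and overall confusion tables plus the method-agreement table."""

    per_target: dict[str, ConfusionTable]
    overall: ConfusionTable
    agreement: AgreementTable

    def summary(self) -> dict:
        out: dict = {}
        for name, table in {**self.per_target, "overall": self.overall}.items():
            m = screening_metrics(table)
            out[name] = {k: round_pct(v) for k, v in m.items()}
            out[name]["raw"] = m
        out["coincidence_rate_pct"] = round_pct(coincidence_rate(self.agreement))
        kappa = cohen_kappa(self.agreement)
        out["cohen_kappa"] = None if kappa is None else round(kappa, 2)
        return out


def evaluate_cohort(truth: dict[str, dict[str, bool]],
                    nnipt: dict[str, dict[str, bool]],
                    gnipt: dict[str, dict[str, bool]],
                    targets: tuple[str, ...] = ("T21", "T18", "T13")) -> CohortEvaluation:
    """Cross-tabulate verdicts of both callers against verified truth.

    Each argument maps sample id -> {target: positive?}.  The overall
    classification of a sample is positive when any target is positive.
    The confusion tables score the window-resolved (gNIPT) verdicts; the
    agreement table cross-classifies the two callers' overall calls.
    """
    ids = sorted(truth)
    if not ids:
        raise ValueError("empty cohort")
    if sorted(nnipt) != ids or sorted(gnipt) != ids:
        raise ValueError("sample ids of truth and verdict sets do not match")

    def any_pos(d: dict[str, bool]) -> bool:
        return any(d.get(t, False) for t in targets)

    per_target: dict[str, ConfusionTable] = {}
    for target in targets:
        tp = fp = fn = tn = 0
        for sid in ids:
            t = truth[sid].get(target, False)
            g = gnipt[sid].get(target, False)
            if t and g:
                tp += 1
            elif not t and g:
                fp += 1
            elif t and not g:
                fn += 1
            else:
                tn += 1
        per_target[target] = ConfusionTable(tp, fp, fn, tn)

    tp = fp = fn = tn = 0
    a = b = c = d = 0
    for sid in ids:
        t = any_pos(truth[sid])
        g = any_pos(gnipt[sid])
        n = any_pos(nnipt[sid])
        if t and g:
            tp += 1
        elif not t and g:
            fp += 1
        elif t and not g:
            fn += 1
        else:
            tn += 1
        if g and n:
            a += 1
        elif g and not n:
            b += 1
        elif not g and n:
            c += 1
        else:
            d += 1
    return CohortEvaluation(per_target, ConfusionTable(tp, fp, fn, tn),
                            AgreementTable(a, b, c, d))
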