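"""Validation statistics: PPV, Agresti-Coull intervals, Cohen kappa, and a
two-sample pooled proportion test, plus the summary validation report.

PPV is the fraction of algorithm-flagged cases confirmed by adjudication.
Under the primary convention the denominator is the cases with sufficient
evidence (definite + probable + possible + doubtful); the alternate
convention counts insufficient-evidence cases as false positives, so its
denominator is all reviewed cases.  Interval estimation uses the
Agresti-Coull adjusted-Wald interval, the standard recommendation for
binomial proportions at validation-study sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .adjudication import AdjudicationRecord, Classification, ReviewLabel
from .errors import UndefinedStatisticError
from .phenotype_engine import AttritionReport


@dataclass(frozen=True)
class ClassificationCounts:
    definite: int = 0
    probable: int = 0
    possible: int = 0
    doubtful: int = 0
    insufficient: int = 0

    def __post_init__(self) -> None:
        if min(self.definite, self.probable, self.possible,
               self.doubtful, self.insufficient) < 0:
            raise ValueError("classification counts must be non-negative")

    @property
    def true_positives(self) -> int:
        return self.definite + self.probable

    @property
    def false_positives(self) -> int:
        return self.possible + self.doubtful

    @property
    def n_sufficient(self) -> int:
        return self.true_positives + self.false_positives

    @property
    def n_total(self) -> int:
        return self.n_sufficient + self.insufficient

    @classmethod
    def from_adjudications(cls, records: Sequence[AdjudicationRecord]) -> "ClassificationCounts":
        finals = [r.final for r in records]
        return cls(
            definite=finals.count(Classification.definite),
            probable=finals.count(Classification.probable),
            possible=finals.count(Classification.possible),
            doubtful=finals.count(Classification.doubtful),
            insufficient=finals.count(Classification.insufficient_evidence),
        )


@dataclass(frozen=True)
class ProportionEstimate:
    x: int
    n: int
    point: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95
    method: str = "agresti-coull"


def agresti_coull_ci(x: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Agresti-Coull binomial interval, bounds clamped to [0, 1].

    With z the standard-normal quantile at (1 + conf)/2 the interval adds
    z^2 pseudo-trials and z^2/2 pseudo-successes: n~ = n + z^2,
    p~ = (x + z^2/2)/n~, half-width z * sqrt(p~ (1 - p~)/n~).
    """
    if n <= 0:
        raise UndefinedStatisticError("Agresti-Coull interval requires n > 0")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n]; got x={x}, n={n}")
    z = norm.ppf((1.0 + conf_level) / 2.0)
    n_tilde = n + z * z
    p_tilde = (x + z * z / 2.0) / n_tilde
    half = z * np.sqrt(p_tilde * (1.0 - p_tilde) / n_tilde)
    return (max(0.0, p_tilde - half), min(1.0, p_tilde + half))


def ppv(counts: ClassificationCounts, include_insufficient: bool = False,
        conf_level: float = 0.95) -> ProportionEstimate:
    """Positive predictive value with an Agresti-Coull interval.

    ``include_insufficient=False`` is the primary convention (denominator =
    cases with sufficient evidence); ``True`` is the sensitivity analysis
    treating insufficient-evidence cases as false positives.
    """
    x = counts.true_positives
    n = counts.n_total if include_insufficient else counts.n_sufficient
    if n == 0:
        raise UndefinedStatisticError("PPV undefined: empty denominator")
    low, high = agresti_coull_ci(x, n, conf_level)
    return ProportionEstimate(x=x, n=n, point=x / n, ci_low=low, ci_high=high,
                              conf_level=conf_level)


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement between two raters over a shared label set.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and p_e
    the expected agreement from the raters' marginal distributions.  When
    p_e = 1 (both raters constant with identical margins) kappa is
    undefined and an error is raised rather than silently returning 0.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError("label sequences must have equal length")
    n = len(labels_a)
    if n == 0:
        raise UndefinedStatisticError("kappa undefined for empty sequences")
    categories = sorted({str(c) for c in labels_a} | {str(c) for c in labels_b})
    a = [str(c) for c in labels_a]
    b = [str(c) for c in labels_b]
    p_o = sum(x == y for x, y in zip(a, b)) / n
    p_e = sum((a.count(c) / n) * (b.count(c) / n) for c in categories)
    if p_e >= 1.0:
        raise UndefinedStatisticError(
            "kappa undefined: expected agreement is 1 (constant identical raters)")
    return (p_o - p_e) / (1.0 - p_e)


def two_sample_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample z test for equality of two proportions.

    Returns (z, two-sided p).  The pooled variance is degenerate when the
    pooled proportion is 0 or 1; that case raises instead of dividing by 0.
    """
    if n1 <= 0 or n2 <= 0:
        raise UndefinedStatisticError("both sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("success counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise UndefinedStatisticError("degenerate pooled variance (pooled proportion 0 or 1)")
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _pct(value: Optional[float]) -> Optional[float]:
    return None if value is None else round(100.0 * value, 1)


def _estimate_dict(est: ProportionEstimate) -> dict:
    return {"x": est.x, "n": est.n, "point": est.point,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "point_pct": _pct(est.point), "ci_low_pct": _pct(est.ci_low),
            "ci_high_pct": _pct(est.ci_high), "conf_level": est.conf_level,
            "method": est.method}


def build_report(
    adjudications: Sequence[AdjudicationRecord],
    reviews: Optional[Sequence[tuple[ReviewLabel, ReviewLabel]]] = None,
    attrition: Optional[AttritionReport] = None,
    conf_level: float = 0.95,
) -> dict:
    """The validation summary: classification counts, both PPV conventions
    with intervals, the insufficient-evidence share, interrater kappa on the
    two primary reviewers (insufficient-evidence counted as its own
    category), and the attrition flow.

    Percentages are rounded to one decimal for display; underlying
    fractions are kept at full precision alongside them.  Undefined
    statistics (empty denominators, degenerate kappa) appear as null rather
    than raising, so an empty run still yields a report.
    """
    counts = ClassificationCounts.from_adjudications(adjudications)
    report: dict = {
        "classification_counts": {
            "definite": counts.definite, "probable": counts.probable,
            "possible": counts.possible, "doubtful": counts.doubtful,
            "insufficient_evidence": counts.insufficient,
        },
        "true_positives": counts.true_positives,
        "false_positives": counts.false_positives,
        "n_sufficient": counts.n_sufficient,
        "n_total": counts.n_total,
        "insufficient_evidence_fraction":
            counts.insufficient / counts.n_total if counts.n_total else None,
    }
    report["insufficient_evidence_pct"] = _pct(report["insufficient_evidence_fraction"])
    try:
        report["ppv"] = _estimate_dict(ppv(counts, include_insufficient=False,
                                           conf_level=conf_level))
    except UndefinedStatisticError:
        report["ppv"] = None
    try:
        report["ppv_alternate"] = _estimate_dict(ppv(counts, include_insufficient=True,
                                                     conf_level=conf_level))
    except UndefinedStatisticError:
        report["ppv_alternate"] = None
    if reviews is not None and reviews:
        a = [r1.classification.value for r1, _ in reviews]
        b = [r2.classification.value for _, r2 in reviews]
        try:
            report["interrater_kappa"] = cohen_kappa(a, b)
        except UndefinedStatisticError:
            report["interrater_kappa"] = None
        report["n_reviewed"] = len(reviews)
    else:
        report["interrater_kappa"] = None
        report["n_reviewed"] = len(adjudications)
    if attrition is not None:
        report["attrition"] = attrition.to_dict()
    return report


def render_markdown(report: dict) -> str:
    """A small human-readable rendering of the validation report."""
    c = report["classification_counts"]
    lines = [
        "# Validation sample results", "",
        "| Final case classification | Detected cases |",
        "| --- | --- |",
        f"| Definite, n | {c['definite']} |",
        f"| Probable, n | {c['probable']} |",
        f"| Possible, n | {c['possible']} |",
        f"| Doubtful, n | {c['doubtful']} |",
        f"| Total true positive cases (definite+probable), n | {report['true_positives']} |",
        f"| Total false positive cases (possible+doubtful), n | {report['false_positives']} |",
        f"| Total cases with sufficient evidence, n | {report['n_sufficient']} |",
    ]
    if report["ppv"]:
        p = report["ppv"]
        lines.append(f"| PPV, % (95% CI) | {p['point_pct']} "
                     f"({p['ci_low_pct']}-{p['ci_high_pct']}) |")
    else:
        lines.append("| PPV, % (95% CI) | undefined |")
    lines.append(f"| Possible (insufficient evidence), n | {c['insufficient_evidence']} |")
    lines.append(f"| Total cases, n | {report['n_total']} |")
    pct = report["insufficient_evidence_pct"]
    lines.append(f"| % of cases with insufficient evidence | "
                 f"{pct if pct is not None else 'undefined'} |")
    if report["ppv_alternate"]:
        p = report["ppv_alternate"]
        lines.append(f"| PPV (alternate), % (95% CI) | {p['point_pct']} "
                     f"({p['ci_low_pct']}-{p['ci_high_pct']}) |")
    kappa = report.get("interrater_kappa")
    lines += ["", f"Interrater Cohen kappa: "
              f"{round(kappa, 3) if kappa is not None else 'undefined'}"]
    return "\n".join(lines) + "\n"
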