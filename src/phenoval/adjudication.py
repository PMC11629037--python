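"""Two-reviewer adjudication bookkeeping and a truth-driven review simulator.

Each retrieved case is read independently by two clinicians who rate
diagnostic certainty as definite, probable, possible or doubtful; a case
whose documentation lacks elements required by the case definition is marked
insufficient-evidence instead.  When the two primary reviewers disagree, a
third reviewer makes the final determination.  Definite and probable finals
are true positives; possible and doubtful are false positives; insufficient
finals are excluded from the primary PPV denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping, Optional, Protocol, Sequence

import numpy as np

from .errors import ConfigError


class Classification(str, Enum):
    definite = "definite"
    probable = "probable"
    possible = "possible"
    doubtful = "doubtful"
    insufficient_evidence = "insufficient_evidence"


POSITIVE_CLASSES = frozenset({Classification.definite, Classification.probable})
NEGATIVE_CLASSES = frozenset({Classification.possible, Classification.doubtful})


@dataclass(frozen=True)
class ReviewLabel:
    case_id: str
    reviewer_id: str
    classification: Classification


@dataclass(frozen=True)
class AdjudicationRecord:
    case_id: str
    reviewer1: Classification
    reviewer2: Classification
    tiebreak: Optional[Classification]
    final: Classification

    @property
    def is_true_positive(self) -> bool:
        return self.final in POSITIVE_CLASSES

    @property
    def is_insufficient(self) -> bool:
        return self.final == Classification.insufficient_evidence


TiebreakProvider = Callable[[str, Classification, Classification], Classification]


def resolve(review1: ReviewLabel, review2: ReviewLabel,
            tiebreak_provider: TiebreakProvider) -> AdjudicationRecord:
    """Resolve one case: shared label wins, otherwise a third reviewer decides.

    The tiebreak provider is consulted exactly once and only on disagreement;
    a provider returning anything outside the classification enum is a fatal
    configuration error.
    """
    if review1.case_id != review2.case_id:
        raise ConfigError(
            f"reviews refer to different cases: {review1.case_id!r} vs {review2.case_id!r}")
    if review1.classification == review2.classification:
        return AdjudicationRecord(
            case_id=review1.case_id, reviewer1=review1.classification,
            reviewer2=review2.classification, tiebreak=None,
            final=review1.classification)
    decision = tiebreak_provider(review1.case_id, review1.classification,
                                 review2.classification)
    if not isinstance(decision, Classification):
        try:
            decision = Classification(decision)
        except ValueError:
            raise ConfigError(f"tiebreak provider returned non-classification {decision!r}") from None
    return AdjudicationRecord(
        case_id=review1.case_id, reviewer1=review1.classification,
        reviewer2=review2.classification, tiebreak=decision, final=decision)


def adjudicate_all(reviews: Sequence[tuple[ReviewLabel, ReviewLabel]],
                   tiebreak_provider: TiebreakProvider) -> list[AdjudicationRecord]:
    return [resolve(r1, r2, tiebreak_provider) for r1, r2 in reviews]


class TruthLike(Protocol):
    is_true_ae: bool
    evidence_complete: bool


@dataclass
class ReviewSimParams:
    """Behavioral parameters of the simulated reviewer pair.

    ``sensitivity_to_truth`` is the probability a reviewer rates a latent-true
    case positive (definite or probable) and a latent-false case negative
    (possible or doubtful); within each pair the label is uniform.
    ``agreement_rate`` is the probability reviewer 2 simply adopts reviewer
    1's label; otherwise reviewer 2 draws independently from the same scheme,
    so raw observed agreement exceeds ``agreement_rate`` by the chance-match
    probability of two independent draws.
    """

    sensitivity_to_truth: float = 0.9
    agreement_rate: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        for name in ("sensitivity_to_truth", "agreement_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


def _draw(rng: np.random.Generator, is_true: bool, sensitivity: float) -> Classification:
    positive = rng.random() < sensitivity if is_true else rng.random() >= sensitivity
    pool = (Classification.definite, Classification.probable) if positive \
        else (Classification.possible, Classification.doubtful)
    return pool[rng.integers(0, 2)]


def simulate_reviews(
    truth_labels: Mapping[str, TruthLike],
    case_ids: Sequence[str],
    params: ReviewSimParams,
) -> tuple[list[tuple[ReviewLabel, ReviewLabel]], TiebreakProvider]:
    """Simulate the two primary reviewers plus a tiebreaking third reviewer.

    Cases with withheld evidence are labeled insufficient by both reviewers;
    otherwise labels are drawn from the truth-driven scheme described on
    ``ReviewSimParams``.  Returns the review pairs and a seeded tiebreak
    provider drawing independently from the same scheme.  Deterministic under
    ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    reviews: list[tuple[ReviewLabel, ReviewLabel]] = []
    for case_id in case_ids:
        truth = truth_labels[case_id]
        if not truth.evidence_complete:
            cls = Classification.insufficient_evidence
            r1 = r2 = cls
        else:
            r1 = _draw(rng, truth.is_true_ae, params.sensitivity_to_truth)
            if rng.random() < params.agreement_rate:
                r2 = r1
            else:
                r2 = _draw(rng, truth.is_true_ae, params.sensitivity_to_truth)
        reviews.append((ReviewLabel(case_id, "R1", r1), ReviewLabel(case_id, "R2", r2)))

    def tiebreak(case_id: str, _a: Classification, _b: Classification) -> Classification:
        truth = truth_labels[case_id]
        if not truth.evidence_complete:
            return Classification.insufficient_evidence
        return _draw(rng, truth.is_true_ae, params.sensitivity_to_truth)

    return reviews, tiebreak
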