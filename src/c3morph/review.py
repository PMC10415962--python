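"""Clinician review protocol: 0-3 acceptability scores and Gwet's AC1.

Scores follow the external-review rubric: 0 wrong slice, 1 unacceptable
(>5% volume discrepancy), 2 acceptable with minor changes (<=5%), 3 no
difference from expert segmentation. A case is "acceptable" at score >= 2.

Gwet's first-order agreement coefficient AC1 = (pa - pe) / (1 - pe) uses the
category-variance chance term pe = 1/(K-1) * sum_k pi_k (1 - pi_k), with pi_k
the mean of the two raters' marginal proportions for category k. It is
reported both on the native 4-category scale and on the binarized
acceptable/unacceptable scale, since either convention is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ACCEPTABLE_MIN_SCORE = 2
VALID_SCORES = (0, 1, 2, 3)


@dataclass
class AgreementResult:
    ac1: float
    pa: float
    pe: float


def _validate_scores(scores: dict, valid) -> None:
    for case, score in scores.items():
        if score not in valid:
            raise ValueError(f"case {case!r} has out-of-range score {score!r}; "
                             f"valid scores are {sorted(valid)}")


def acceptability_rate(ratings: dict) -> float:
    """Fraction of cases one rater scored >= 2 (acceptable or better)."""
    if not ratings:
        raise ValueError("empty ratings")
    _validate_scores(ratings, VALID_SCORES)
    scores = np.array(list(ratings.values()))
    return float((scores >= ACCEPTABLE_MIN_SCORE).mean())


def gwet_ac1(ratings_a: dict, ratings_b: dict,
             categories=VALID_SCORES) -> AgreementResult:
    """Gwet's AC1 between two raters over a shared case set."""
    if set(ratings_a) != set(ratings_b):
        raise ValueError("raters scored different case sets")
    cases = sorted(ratings_a)
    if len(cases) < 2:
        raise ValueError("need at least 2 cases")
    categories = list(categories)
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    _validate_scores(ratings_a, set(categories))
    _validate_scores(ratings_b, set(categories))

    a = np.array([ratings_a[c] for c in cases])
    b = np.array([ratings_b[c] for c in cases])
    pa = float((a == b).mean())
    pi = np.array([((a == k).mean() + (b == k).mean()) / 2.0 for k in categories])
    pe = float((pi * (1 - pi)).sum() / (len(categories) - 1))
    if pe >= 1.0:
        raise ValueError("chance agreement pe = 1; AC1 undefined")
    return AgreementResult(ac1=(pa - pe) / (1 - pe), pa=pa, pe=pe)


def binarize_scores(ratings: dict) -> dict:
    """Collapse 0-3 scores to acceptable (1) vs unacceptable (0)."""
    _validate_scores(ratings, VALID_SCORES)
    return {case: int(score >= ACCEPTABLE_MIN_SCORE)
            for case, score in ratings.items()}


def agreement_report(ratings_a: dict, ratings_b: dict) -> dict:
    """Both AC1 variants plus each rater's acceptability rate."""
    full = gwet_ac1(ratings_a, ratings_b, categories=VALID_SCORES)
    binary = gwet_ac1(binarize_scores(ratings_a), binarize_scores(ratings_b),
                      categories=(0, 1))
    return {
        "ac1_four_category": full.ac1,
        "ac1_binary": binary.ac1,
        "pa_four_category": full.pa,
        "pe_four_category": full.pe,
        "acceptability_rate_a": acceptability_rate(ratings_a),
        "acceptability_rate_b": acceptability_rate(ratings_b),
    }
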