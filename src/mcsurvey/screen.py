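"""Acceptance screening of profile-HMM domain hits.

A hit survives iff its domain independent E-value is at or below the E-value
ceiling and its score/bias ratio is at or above the ratio floor (a hit with
zero bias passes the ratio test by convention: its ratio is +inf).  Profile
coverage — the fraction of model match states spanned by the hit — is computed
separately and only ever *flags* a hit as low-coverage; it never removes one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .io_formats import DomainHit


@dataclass(frozen=True)
class ScreenConfig:
    """Hit-acceptance thresholds.

    Defaults: E-value ceiling 0.01, score/bias ratio floor 10, low-coverage
    flag below 60% of model match states.
    """

    max_i_evalue: float = 0.01
    min_score_bias_ratio: float = 10.0
    low_coverage_threshold: float = 0.60

    def __post_init__(self) -> None:
        if self.max_i_evalue <= 0:
            raise ValidationError("max_i_evalue must be positive")
        if self.min_score_bias_ratio <= 0:
            raise ValidationError("min_score_bias_ratio must be positive")
        if not (0 < self.low_coverage_threshold <= 1):
            raise ValidationError("low_coverage_threshold must be in (0, 1]")


@dataclass(frozen=True)
class RejectedHit:
    """A screened-out hit together with the test(s) it failed."""

    hit: DomainHit
    reason: str  # "evalue" | "ratio" | "evalue+ratio"


def score_bias_ratio(hit: DomainHit) -> float:
    """Bit score divided by composition-bias correction; +inf when bias is 0."""
    if hit.bias == 0:
        return math.inf
    return hit.score / hit.bias


def screen_hits(
    hits: Iterable[DomainHit], cfg: ScreenConfig | None = None
) -> tuple[list[DomainHit], list[RejectedHit]]:
    """Partition hits into accepted and rejected under the thresholds.

    Accepted iff ``i_evalue <= max_i_evalue`` and
    ``score/bias >= min_score_bias_ratio``.  Screening is total: every input
    hit appears in exactly one of the two outputs, in input order.
    """
    cfg = cfg or ScreenConfig()
    accepted: list[DomainHit] = []
    rejected: list[RejectedHit] = []
    for hit in hits:
        reasons = []
        if hit.i_evalue > cfg.max_i_evalue:
            reasons.append("evalue")
        if score_bias_ratio(hit) < cfg.min_score_bias_ratio:
            reasons.append("ratio")
        if reasons:
            rejected.append(RejectedHit(hit, "+".join(reasons)))
        else:
            accepted.append(hit)
    return accepted, rejected


def hmm_coverage(hit: DomainHit) -> float:
    """Fraction of the profile's match states spanned by the hit.

    ``(hmm_to - hmm_from + 1) / model_length`` at full floating precision.
    """
    if hit.model_length <= 0:
        raise ValidationError("model_length must be positive")
    return (hit.hmm_to - hit.hmm_from + 1) / hit.model_length


def is_low_coverage(hit: DomainHit, cfg: ScreenConfig | None = None) -> bool:
    """Flag hits spanning less than the coverage threshold of the model."""
    cfg = cfg or ScreenConfig()
    return hmm_coverage(hit) < cfg.low_coverage_threshold


def coverage_table(
    hits: Sequence[DomainHit], cfg: ScreenConfig | None = None
) -> list[dict]:
    """Per-hit coverage report: protein, domain, coverage, low-coverage flag."""
    cfg = cfg or ScreenConfig()
    return [
        {
            "protein_id": h.protein_id,
            "domain_name": h.domain_name,
            "coverage": hmm_coverage(h),
            "low_coverage": is_low_coverage(h, cfg),
        }
        for h in hits
    ]
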