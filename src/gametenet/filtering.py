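"""High-confidence interaction selection.

Two independent routes produce high-confidence interaction sets:

* the *functional* route combines per-channel evidence probabilities with a
  noisy-OR combiner, ``S = 1 - prod_i(1 - S_i)``, and keeps pairs whose
  combined score is strictly greater than 0.700 (the conventional
  high-confidence cut for combined functional-association scores);
* the *physical* route keeps experimentally supported (physical) pairs
  backed by at least three publications, conserved in at least one other
  species, with a MINT-inspired (MI) confidence score of at least 0.431.

The 0.700 cut is strict-greater while the 0.431 MI cut is inclusive; both
thresholds, the publication minimum and the conservation minimum live in
:class:`FilterConfig` so either reading costs one configuration change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .model import EvidenceRecord, ValidationError

__all__ = ["FilterConfig", "combine_scores", "filter_functional", "filter_physical"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the two high-confidence selection routes.

    Attributes
    ----------
    combined_threshold
        Strict lower bound on the noisy-OR combined score (default 0.700).
    mi_threshold
        Inclusive lower bound on the MI score (default 0.431).
    min_publications
        Minimum supporting publications for a physical pair (default 3;
        pairs supported by fewer are excluded).
    min_conserved_species
        Minimum number of other species the pair is conserved in (default 1,
        i.e. "not conserved in any species" is an exclusion).
    """

    combined_threshold: float = 0.700
    mi_threshold: float = 0.431
    min_publications: int = 3
    min_conserved_species: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.combined_threshold <= 1.0:
            raise ValidationError("combined_threshold must be in [0, 1]")
        if not 0.0 <= self.mi_threshold <= 1.0:
            raise ValidationError("mi_threshold must be in [0, 1]")
        if self.min_publications < 0 or self.min_conserved_species < 0:
            raise ValidationError("minimum counts must be >= 0")

    def to_mapping(self) -> dict:
        return {
            "combined_threshold": self.combined_threshold,
            "mi_threshold": self.mi_threshold,
            "min_publications": self.min_publications,
            "min_conserved_species": self.min_conserved_species,
        }

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "FilterConfig":
        known = {
            k: mapping[k]
            for k in (
                "combined_threshold",
                "mi_threshold",
                "min_publications",
                "min_conserved_species",
            )
            if k in mapping
        }
        return cls(**known)


def combine_scores(channel_scores: Sequence[float]) -> float:
    """Noisy-OR combination of per-channel probabilities.

    ``S = 1 - prod_i(1 - S_i)``: the probability that at least one evidence
    channel is correct, assuming channel independence.  The empty list maps
    to 0 (no evidence, no confidence).
    """
    for s in channel_scores:
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"channel score {s} outside [0, 1]")
    return 1.0 - math.prod(1.0 - s for s in channel_scores)


def filter_functional(
    records: Sequence[EvidenceRecord], cfg: FilterConfig | None = None
) -> list[EvidenceRecord]:
    """Keep records whose combined channel score exceeds the threshold.

    The combined score is recomputed from ``channel_scores`` for every
    record (input ``combined_score`` values are ignored) and populated on
    every returned record.  The comparison is strictly greater-than.
    """
    cfg = cfg or FilterConfig()
    kept = []
    for r in records:
        s = combine_scores(r.channel_scores)
        if s > cfg.combined_threshold:
            kept.append(replace(r, combined_score=s))
    return kept


def filter_physical(
    records: Sequence[EvidenceRecord], cfg: FilterConfig | None = None
) -> list[EvidenceRecord]:
    """Keep physical pairs with enough publication, conservation and MI support.

    A record survives iff it is physical, is supported by at least
    ``min_publications`` publications, is conserved in at least
    ``min_conserved_species`` species, and has ``mi_score`` of at least
    ``mi_threshold`` (inclusive).
    """
    cfg = cfg or FilterConfig()
    return [
        r
        for r in records
        if r.is_physical
        and r.n_publications >= cfg.min_publications
        and r.n_conserved_species >= cfg.min_conserved_species
        and r.mi_score >= cfg.mi_threshold
    ]
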