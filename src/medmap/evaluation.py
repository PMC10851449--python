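"""Mapping-quality evaluation: sampling, relation schema, agreement.

Annotators classify each (MedDRA PT, ICD) pair by the semantic scope
relation between the two concepts, Venn-diagram style: the terms coincide
(exact match), the PT term is narrower or broader than the ICD term, the
scopes partially overlap, or they are irrelevant to each other.  Pairs from
the established crosswalk (the *mapped* group, sampled at a fixed fraction)
use the first four categories; PT terms without any crosswalk link (the
*unmapped* group, sampled per SOC) additionally allow "totally irrelevant",
"no response" (the search returned nothing) and "other".

Two raters annotate independently; agreement is quantified with Cohen's
kappa (chance correction from each rater's own marginals), gated by a
calibration round that must reach a raw-agreement threshold before
annotation proceeds, and disagreements are consolidated by adjudication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from medmap._util import round_half_up
from medmap.extraction import MappedPair
from medmap.vocab_io import MedDRAHierarchy


class RelationCategory(str, Enum):
    EXACT_MATCH = "EXACT_MATCH"
    PT_NARROWER = "PT_NARROWER"
    PT_BROADER = "PT_BROADER"
    PARTIAL_OVERLAP = "PARTIAL_OVERLAP"
    TOTALLY_IRRELEVANT = "TOTALLY_IRRELEVANT"
    NO_RESPONSE = "NO_RESPONSE"
    OTHER = "OTHER"


#: Relation schema for pairs drawn from the crosswalk.
MAPPED_CATEGORIES: tuple[RelationCategory, ...] = (
    RelationCategory.EXACT_MATCH,
    RelationCategory.PT_NARROWER,
    RelationCategory.PT_BROADER,
    RelationCategory.PARTIAL_OVERLAP,
)

#: Relation schema for PT terms without a crosswalk link.
UNMAPPED_CATEGORIES: tuple[RelationCategory, ...] = MAPPED_CATEGORIES + (
    RelationCategory.TOTALLY_IRRELEVANT,
    RelationCategory.NO_RESPONSE,
    RelationCategory.OTHER,
)


@dataclass
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float
    n_items: int
    degenerate: bool = False


@dataclass
class CategorySummary:
    """Counts and half-up two-decimal percentages per relation category."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float]


Labels = Mapping[str, object]


def _check_keys(labels1: Labels, labels2: Labels) -> None:
    if not labels1:
        raise ValueError("label maps must be non-empty")
    only1 = sorted(set(labels1) - set(labels2))
    only2 = sorted(set(labels2) - set(labels1))
    if only1 or only2:
        raise ValueError(
            f"label maps cover different items; only in first: {only1[:5]}, "
            f"only in second: {only2[:5]}"
        )


def cohen_kappa(labels1: Labels, labels2: Labels) -> KappaResult:
    """Cohen's kappa between two raters' item->category maps.

    kappa = (po - pe) / (1 - pe) with po the raw agreement and pe the
    chance agreement from the product of each rater's own category
    marginals.  When pe = 1 (both raters constant on one category) the
    ratio is undefined: the result is flagged degenerate, with kappa 1.0
    if the raters agree everywhere and NaN otherwise.
    """
    _check_keys(labels1, labels2)
    n = len(labels1)
    po = sum(1 for k in labels1 if labels1[k] == labels2[k]) / n
    marg1: dict[object, int] = {}
    marg2: dict[object, int] = {}
    for k in labels1:
        marg1[labels1[k]] = marg1.get(labels1[k], 0) + 1
        marg2[labels2[k]] = marg2.get(labels2[k], 0) + 1
    pe = sum(marg1.get(c, 0) * marg2.get(c, 0) for c in marg1) / (n * n)
    if pe >= 1.0 - 1e-15:
        return KappaResult(
            kappa=1.0 if po == 1.0 else math.nan,
            observed_agreement=po, expected_agreement=pe, n_items=n,
            degenerate=True,
        )
    return KappaResult(
        kappa=(po - pe) / (1.0 - pe),
        observed_agreement=po, expected_agreement=pe, n_items=n,
    )


def calibration_gate(
    labels1: Labels, labels2: Labels, threshold: float = 0.80
) -> tuple[bool, float]:
    """Pass when raw inter-rater agreement reaches the threshold (>=)."""
    _check_keys(labels1, labels2)
    po = sum(1 for k in labels1 if labels1[k] == labels2[k]) / len(labels1)
    return po >= threshold, po


def summarize_annotations(
    labels: Labels, allowed: Sequence[RelationCategory]
) -> CategorySummary:
    """Counts and percentages per category; zero-count categories included."""
    allowed_set = set(allowed)
    counts = {c.value: 0 for c in allowed}
    for item, cat in labels.items():
        if cat not in allowed_set:
            raise ValueError(f"item {item!r} has label {cat!r} outside the schema")
        counts[cat.value] += 1  # type: ignore[union-attr]
    total = len(labels)
    return CategorySummary(
        counts=counts,
        total=total,
        percentages=summarize_counts({c.value: counts[c.value] for c in allowed}),
    )


def summarize_counts(counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages (half-up, two decimals) from a category count vector."""
    total = sum(counts.values())
    if total == 0:
        return {c: 0.0 for c in counts}
    return {c: round_half_up(100.0 * n / total) for c, n in counts.items()}


def consolidate_annotations(
    labels1: Labels,
    labels2: Labels,
    resolutions: Optional[Labels] = None,
) -> dict[str, object]:
    """Adjudicated labels: agreed items keep their common label,
    disagreements take the supplied resolution."""
    _check_keys(labels1, labels2)
    resolutions = resolutions or {}
    disagreements = [k for k in labels1 if labels1[k] != labels2[k]]
    unresolved = sorted(set(disagreements) - set(resolutions))
    if unresolved:
        raise ValueError(f"missing resolutions for disagreement item(s): {unresolved}")
    out: dict[str, object] = {}
    for k in labels1:
        out[k] = labels1[k] if labels1[k] == labels2[k] else resolutions[k]
    return out


def sample_mapped(
    pt_pairs: Iterable[MappedPair], fraction: float, seed: int
) -> list[MappedPair]:
    """Uniform seeded sample, without replacement, of ceil(fraction * n)
    PT-level pairs from the crosswalk."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    pool = sorted(pt_pairs, key=lambda p: p.key)
    if not pool:
        raise ValueError("cannot sample from an empty pair set")
    k = math.ceil(fraction * len(pool))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def sample_unmapped(
    unmapped_pts: Iterable[str],
    hierarchy: MedDRAHierarchy,
    per_soc: int,
    seed: int,
) -> list[str]:
    """Per primary SOC, sample min(per_soc, available) unmapped PTs
    uniformly without replacement; SOCs with a shortfall contribute all
    their unmapped PTs."""
    if per_soc <= 0:
        raise ValueError("per_soc must be positive")
    by_soc: dict[str, list[str]] = {}
    for pt in sorted(set(unmapped_pts)):
        by_soc.setdefault(hierarchy.primary_soc(pt), []).append(pt)
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    for soc in sorted(by_soc):
        pool = by_soc[soc]
        k = min(per_soc, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        selected.extend(pool[i] for i in sorted(idx))
    return selected
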