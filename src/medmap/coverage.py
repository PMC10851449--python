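"""PT-level aggregation and mapping-coverage statistics.

Every MedDRA PT is self-contained at the LLT level, so LLT-level mapped
pairs can be collapsed onto their parent PT without loss; coverage is then
the fraction of all PTs in the release that carry at least one ICD link.
Per-SOC summaries attribute each PT to its primary SOC so the counts
partition the PT set (an ``all_socs`` mode counts multiaxially instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from medmap._util import round_half_up
from medmap.extraction import MappedPair, _dedupe, extract_umls_pairs
from medmap.vocab_io import Atom, MedDRAHierarchy

SourceKey = tuple[str, int, str]  # (meddra_level, icd_version, source)


@dataclass
class CoverageReport:
    """Unique-term mapping statistics at the PT level.

    ``per_source_counts`` counts distinct MedDRA terms (not pairs) per
    (level, ICD version, source) cell.  ``n_pt_in_source`` is the optional
    alternative denominator for snapshot trends: the number of PTs present
    in the source snapshot rather than in the full release.
    """

    n_pt_mapped: int
    n_pt_total: int
    per_source_counts: dict[SourceKey, int] = field(default_factory=dict)
    per_soc: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    n_pt_in_source: Optional[int] = None

    @property
    def pct_pt_mapped(self) -> float:
        if self.n_pt_total == 0:
            return 0.0
        return round_half_up(100.0 * self.n_pt_mapped / self.n_pt_total)

    @property
    def pct_of_source(self) -> Optional[float]:
        if not self.n_pt_in_source:
            return None
        return round_half_up(100.0 * self.n_pt_mapped / self.n_pt_in_source)


def llt_pairs_to_pt(
    pairs: Iterable[MappedPair], hierarchy: MedDRAHierarchy
) -> set[MappedPair]:
    """Replace each LLT-level pair by its parent-PT pair (same ICD side).

    PT-level pairs pass through; the result is deduplicated, so an LLT pair
    whose parent already carries the same ICD link collapses away.
    """
    unknown = sorted(
        {p.meddra_code for p in pairs
         if p.meddra_level == "LLT" and p.meddra_code not in hierarchy.llt_to_pt}
    )
    if unknown:
        raise KeyError(f"LLT code(s) absent from hierarchy: {', '.join(unknown)}")
    converted = []
    for p in pairs:
        if p.meddra_level == "PT":
            converted.append(p)
        else:
            parent = hierarchy.llt_to_pt[p.meddra_code]
            converted.append(
                replace(
                    p,
                    meddra_code=parent,
                    meddra_level="PT",
                    meddra_string=hierarchy.pt_strings.get(parent, p.meddra_string),
                )
            )
    return _dedupe(converted)


def per_source_term_counts(pairs: Iterable[MappedPair]) -> dict[SourceKey, int]:
    """Distinct MedDRA terms per (level, ICD version, source) cell."""
    cells: dict[SourceKey, set[str]] = {}
    for p in pairs:
        for source in p.provenance:
            cells.setdefault((p.meddra_level, p.icd_version, source), set()).add(
                p.meddra_code
            )
    return {k: len(v) for k, v in cells.items()}


def coverage_summary(
    pt_pairs: Iterable[MappedPair],
    hierarchy: MedDRAHierarchy,
    all_pairs: Optional[Iterable[MappedPair]] = None,
) -> CoverageReport:
    """Overall and per-SOC coverage of the PT set by a PT-level pair set.

    ``all_pairs`` (optionally including pre-conversion LLT pairs) feeds the
    per-source unique-term cells; the headline numerator/denominator always
    come from ``pt_pairs`` against the full hierarchy.
    """
    pt_pairs = list(pt_pairs)
    bad = [p for p in pt_pairs if p.meddra_level != "PT"]
    if bad:
        raise ValueError(f"coverage_summary expects PT-level pairs; got {len(bad)} LLT pair(s)")
    mapped = {p.meddra_code for p in pt_pairs}
    report = CoverageReport(
        n_pt_mapped=len(mapped & hierarchy.pts),
        n_pt_total=hierarchy.n_pt,
        per_source_counts=per_source_term_counts(
            pt_pairs if all_pairs is None else all_pairs
        ),
        per_soc=per_soc_summary(pt_pairs, hierarchy),
    )
    return report


def per_soc_summary(
    pt_pairs: Iterable[MappedPair],
    hierarchy: MedDRAHierarchy,
    all_socs: bool = False,
) -> dict[str, tuple[int, int, float]]:
    """Per-SOC (mapped, unmapped, percentage) over the hierarchy's PTs.

    By default each PT is attributed once, to its primary SOC, so mapped +
    unmapped sums over SOCs reproduce the PT total; with ``all_socs`` a PT
    counts under every SOC it belongs to.
    """
    mapped = {p.meddra_code for p in pt_pairs}
    per_soc_pts: dict[str, set[str]] = {}
    for pt, assignments in hierarchy.pt_to_socs.items():
        if all_socs:
            for soc, _ in assignments:
                per_soc_pts.setdefault(soc, set()).add(pt)
        else:
            per_soc_pts.setdefault(hierarchy.primary_soc(pt), set()).add(pt)
    out: dict[str, tuple[int, int, float]] = {}
    for soc in sorted(per_soc_pts):
        pts = per_soc_pts[soc]
        n_mapped = len(pts & mapped)
        n_unmapped = len(pts) - n_mapped
        pct = round_half_up(100.0 * n_mapped / len(pts)) if pts else 0.0
        out[soc] = (n_mapped, n_unmapped, pct)
    return out


def snapshot_trend(
    snapshots: Sequence[tuple[str, Sequence[Atom]]],
    hierarchy: MedDRAHierarchy,
) -> list[tuple[str, CoverageReport]]:
    """Coverage per vocabulary snapshot, in order, for trend tabulation.

    Each snapshot's atoms are run through the UMLS CUI join and LLT->PT
    conversion.  Two denominators are reported: the full release PT count
    (``pct_pt_mapped``) and the PTs actually present in the snapshot's MDR
    atoms (``pct_of_source``), since coverage trends differ depending on
    whether vocabulary growth itself is counted.
    """
    if not snapshots:
        raise ValueError("snapshot_trend requires at least one snapshot")
    out: list[tuple[str, CoverageReport]] = []
    for label, atoms in snapshots:
        pairs = extract_umls_pairs(atoms)
        pt_pairs = llt_pairs_to_pt(pairs, hierarchy)
        report = coverage_summary(pt_pairs, hierarchy, all_pairs=pairs)
        present = {
            a.code for a in atoms
            if a.sab == "MDR" and a.tty == "PT" and a.code in hierarchy.pts
        }
        report.n_pt_in_source = len(present)
        out.append((label, report))
    return out
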