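"""Construct MedDRA<->ICD mapped pairs from UMLS and OMOP vocabulary.

Three routes produce candidate pairs:

* **UMLS CUI join** — two atoms sharing a CUI are synonymous by UMLS
  assertion, so every (MedDRA atom, ICD atom) pair under one CUI is a
  mapped pair.  The CUI is used as the *only* mapping criterion; MRREL/
  MRMAP relationship rows are deliberately not used as mapping evidence
  (most SY rows are CUI-concordant anyway, and discordant RQ rows are
  dominated by classification links rather than synonymy — see
  :func:`rel_cui_concordance`, which quantifies this on a given release).
* **OMOP direct** — predefined MedDRA-ICD rows in CONCEPT_RELATIONSHIP.
* **OMOP indirect** — a two-leg chain: MedDRA equivalence to SNOMED, then
  a "Maps to" link between SNOMED and ICD.  In OMOP releases the second
  leg points from the non-standard ICD concept to the standard SNOMED
  concept, so both edge directions are accepted on both legs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Optional, Sequence

from medmap._util import normalize_term
from medmap.vocab_io import (
    Atom,
    MedDRAHierarchy,
    OMOPConcept,
    OMOPRelationship,
    Relationship,
)

logger = logging.getLogger(__name__)

MEDDRA_TERM_TYPES = frozenset({"PT", "LLT"})
ICD_SABS = {"ICD9CM": 9, "ICD10CM": 10}

PairKey = tuple[str, str, str, int]


@dataclass(frozen=True)
class MappedPair:
    """One MedDRA-term-to-ICD-code link with provenance.

    Pair identity is (meddra_code, meddra_level, icd_code, icd_version);
    strings and provenance are carried along but do not distinguish pairs.
    """

    meddra_code: str
    meddra_level: str  # "PT" or "LLT"
    meddra_string: str
    icd_code: str
    icd_version: int  # 9 or 10
    icd_string: str
    provenance: frozenset[str] = frozenset()
    cui: Optional[str] = None

    def __post_init__(self) -> None:
        if self.icd_version not in (9, 10):
            raise ValueError(f"icd_version must be 9 or 10, got {self.icd_version}")
        if self.meddra_level not in ("PT", "LLT"):
            raise ValueError(f"meddra_level must be PT or LLT, got {self.meddra_level}")
        if "UMLS" in self.provenance and self.cui is None:
            raise ValueError("UMLS-provenance pair requires a CUI")

    @property
    def key(self) -> PairKey:
        return (self.meddra_code, self.meddra_level, self.icd_code, self.icd_version)


@dataclass
class RelConcordance:
    """CUI concordance of MRREL rows for one relationship label."""

    rel_label: str
    n_total: int
    n_same_cui: int
    rela_breakdown: dict[str, int] = field(default_factory=dict)

    @property
    def fraction_same_cui(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return self.n_same_cui / self.n_total

    @property
    def defined(self) -> bool:
        return self.n_total > 0


def _dedupe(pairs: Iterable[MappedPair]) -> set[MappedPair]:
    by_key: dict[PairKey, MappedPair] = {}
    for p in pairs:
        existing = by_key.get(p.key)
        if existing is None:
            by_key[p.key] = p
        elif p.provenance - existing.provenance:
            by_key[p.key] = replace(
                existing, provenance=existing.provenance | p.provenance
            )
    return set(by_key.values())


def extract_umls_pairs(atoms: Iterable[Atom]) -> set[MappedPair]:
    """Cross every MedDRA atom with every ICD atom sharing its CUI.

    MDR atoms with term types outside {PT, LLT} are ignored; the result is
    deduplicated on (meddra_code, meddra_level, icd_code, icd_version), so
    atom order never matters.
    """
    by_cui: dict[str, tuple[list[Atom], list[Atom]]] = {}
    for a in atoms:
        if a.sab == "MDR" and a.tty in MEDDRA_TERM_TYPES:
            by_cui.setdefault(a.cui, ([], []))[0].append(a)
        elif a.sab in ICD_SABS:
            by_cui.setdefault(a.cui, ([], []))[1].append(a)

    pairs: list[MappedPair] = []
    for cui, (mdr_atoms, icd_atoms) in by_cui.items():
        for m in mdr_atoms:
            for i in icd_atoms:
                pairs.append(
                    MappedPair(
                        meddra_code=m.code,
                        meddra_level=m.tty,
                        meddra_string=m.string,
                        icd_code=i.code,
                        icd_version=ICD_SABS[i.sab],
                        icd_string=i.string,
                        provenance=frozenset({"UMLS"}),
                        cui=cui,
                    )
                )
    return _dedupe(pairs)


def _default_direct_predicate(relationship_id: str) -> bool:
    rid = relationship_id.lower()
    return "meddra" in rid and "icd" in rid


def _omop_icd_version(vocabulary_id: str) -> Optional[int]:
    return {"ICD9CM": 9, "ICD10CM": 10}.get(vocabulary_id)


def extract_omop_direct(
    concepts: Sequence[OMOPConcept],
    relationships: Sequence[OMOPRelationship],
    relationship_ids: Optional[set[str]] = None,
) -> set[MappedPair]:
    """Extract pairs from predefined MedDRA-ICD relationship rows.

    ``relationship_ids`` restricts to specific relationship_id strings; by
    default any relationship_id naming both MedDRA and ICD qualifies.
    Rows are accepted in either endpoint order.
    """
    by_id = {c.concept_id: c for c in concepts}
    if relationship_ids is not None:
        present = {r.relationship_id for r in relationships}
        missing = relationship_ids - present
        if missing:
            warnings.warn(
                "configured direct relationship_id(s) absent from table: "
                + ", ".join(sorted(missing)),
                stacklevel=2,
            )
        qualifies: Callable[[str], bool] = lambda rid: rid in relationship_ids
    else:
        qualifies = _default_direct_predicate

    pairs: list[MappedPair] = []
    for r in relationships:
        if not qualifies(r.relationship_id):
            continue
        c1, c2 = by_id.get(r.concept_id_1), by_id.get(r.concept_id_2)
        if c1 is None or c2 is None:
            continue
        for med, icd in ((c1, c2), (c2, c1)):
            version = _omop_icd_version(icd.vocabulary_id)
            if med.vocabulary_id == "MedDRA" and version is not None:
                if med.concept_class_id not in MEDDRA_TERM_TYPES:
                    continue
                pairs.append(
                    MappedPair(
                        meddra_code=med.concept_code,
                        meddra_level=med.concept_class_id,
                        meddra_string=med.concept_name,
                        icd_code=icd.concept_code,
                        icd_version=version,
                        icd_string=icd.concept_name,
                        provenance=frozenset({"OMOP_DIRECT"}),
                    )
                )
    return _dedupe(pairs)


def extract_omop_indirect(
    concepts: Sequence[OMOPConcept],
    relationships: Sequence[OMOPRelationship],
    eq_relationship_ids: Optional[set[str]] = None,
    mapsto_relationship_ids: Optional[set[str]] = None,
) -> set[MappedPair]:
    """Extract pairs via the SNOMED-mediated chain.

    Leg 1 links a MedDRA concept to a SNOMED concept ("MedDRA - SNOMED eq"
    by default); leg 2 links that SNOMED concept to an ICD concept ("Maps
    to" by default).  Each leg is traversed in either direction; only the
    single SNOMED hop is followed (no transitive closure).
    """
    by_id = {c.concept_id: c for c in concepts}
    if eq_relationship_ids is None:
        eq_qualifies = lambda rid: "meddra" in rid.lower() and "snomed" in rid.lower()
    else:
        eq_qualifies = lambda rid: rid in eq_relationship_ids
    if mapsto_relationship_ids is None:
        map_qualifies = lambda rid: rid.lower() in ("maps to", "mapped from")
    else:
        map_qualifies = lambda rid: rid in mapsto_relationship_ids

    med_to_snomed: dict[int, set[int]] = {}
    snomed_to_icd: dict[int, set[int]] = {}
    for r in relationships:
        c1, c2 = by_id.get(r.concept_id_1), by_id.get(r.concept_id_2)
        if c1 is None or c2 is None:
            continue
        if eq_qualifies(r.relationship_id):
            for med, sno in ((c1, c2), (c2, c1)):
                if med.vocabulary_id == "MedDRA" and sno.vocabulary_id == "SNOMED":
                    med_to_snomed.setdefault(med.concept_id, set()).add(sno.concept_id)
        if map_qualifies(r.relationship_id):
            for icd, sno in ((c1, c2), (c2, c1)):
                if sno.vocabulary_id == "SNOMED" and _omop_icd_version(icd.vocabulary_id):
                    snomed_to_icd.setdefault(sno.concept_id, set()).add(icd.concept_id)

    pairs: list[MappedPair] = []
    for med_id, snomed_ids in med_to_snomed.items():
        med = by_id[med_id]
        if med.concept_class_id not in MEDDRA_TERM_TYPES:
            continue
        for s in snomed_ids:
            for icd_id in snomed_to_icd.get(s, ()):
                icd = by_id[icd_id]
                pairs.append(
                    MappedPair(
                        meddra_code=med.concept_code,
                        meddra_level=med.concept_class_id,
                        meddra_string=med.concept_name,
                        icd_code=icd.concept_code,
                        icd_version=_omop_icd_version(icd.vocabulary_id),  # type: ignore[arg-type]
                        icd_string=icd.concept_name,
                        provenance=frozenset({"OMOP_INDIRECT"}),
                    )
                )
    return _dedupe(pairs)


def merge_pair_sets(sets: Iterable[Iterable[MappedPair]]) -> set[MappedPair]:
    """Union pair sets, deduplicating on pair identity.

    A pair found by several routes keeps the union of their provenance
    tags (and its CUI, if any contributing pair carried one).
    """
    by_key: dict[PairKey, MappedPair] = {}
    for pairs in sets:
        for p in pairs:
            existing = by_key.get(p.key)
            if existing is None:
                by_key[p.key] = p
            else:
                by_key[p.key] = replace(
                    existing,
                    provenance=existing.provenance | p.provenance,
                    cui=existing.cui if existing.cui is not None else p.cui,
                )
    return set(by_key.values())


def rel_cui_concordance(
    relationships: Sequence[Relationship],
    rel_labels: Iterable[str] = ("RQ", "SY"),
) -> list[RelConcordance]:
    """Per relationship label, how often do the two endpoints share a CUI?

    Among discordant rows (cui1 != cui2), RELA values are tallied; a high
    share of classification-type RELAs among discordant rows is the
    argument for not treating those relationship rows as synonymy.
    """
    out: list[RelConcordance] = []
    for label in rel_labels:
        rows = [r for r in relationships if r.rel == label]
        same = sum(1 for r in rows if r.cui1 == r.cui2)
        breakdown: dict[str, int] = {}
        for r in rows:
            if r.cui1 != r.cui2:
                breakdown[r.rela] = breakdown.get(r.rela, 0) + 1
        out.append(
            RelConcordance(
                rel_label=label,
                n_total=len(rows),
                n_same_cui=same,
                rela_breakdown=breakdown,
            )
        )
    return out


def crosscheck_with_meddra(
    pairs: Iterable[MappedPair], hierarchy: MedDRAHierarchy
) -> set[MappedPair]:
    """Retain pairs whose MedDRA string exists in the official release.

    Matching is by string, case-insensitive after whitespace
    normalization, at the pair's own level; when the source code differs
    from the official release's code for that string, the official code is
    attached.  Dropped pairs are logged with the offending string.
    """
    pt_lookup = {normalize_term(s): code for code, s in hierarchy.pt_strings.items()}
    llt_lookup = {normalize_term(s): code for code, s in hierarchy.llt_strings.items()}
    kept: list[MappedPair] = []
    for p in pairs:
        lookup = pt_lookup if p.meddra_level == "PT" else llt_lookup
        official = lookup.get(normalize_term(p.meddra_string))
        if official is None:
            logger.info(
                "dropping pair %s: string %r absent from MedDRA release",
                p.key, p.meddra_string,
            )
            continue
        kept.append(p if official == p.meddra_code else replace(p, meddra_code=official))
    return _dedupe(kept)
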