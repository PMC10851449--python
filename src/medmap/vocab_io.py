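"""Readers and writers for the vocabulary file formats the pipeline touches.

Four dialects:

* UMLS Rich Release Format (RRF): UTF-8, pipe-delimited, trailing pipe, no
  header.  ``MRCONSO.RRF`` carries one atom (a source string occurrence)
  per row; ``MRREL.RRF`` carries one inter-concept relationship per row.
* OMOP standardized-vocabulary tables ``CONCEPT`` and
  ``CONCEPT_RELATIONSHIP``: delimited text with a header row; comma or tab
  auto-detected from the header.
* MedDRA distribution ASCII: "$"-delimited rows, code first, term string
  second.  ``llt.asc`` links each LLT to its single parent PT; the PT file
  assigns each PT to its System Organ Classes, one row per (PT, SOC) with a
  Y/N primary flag (a flattening of the distribution's pt.asc + mdhier.asc
  pair into one file).
* Annotation label CSV: ``item_id,rater_id,category`` with a header.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

# Standard MRCONSO column layout (18 fields + trailing delimiter).
MRCONSO_COLUMNS = (
    "CUI", "LAT", "TS", "LUI", "STT", "SUI", "ISPREF", "AUI", "SAUI",
    "SCUI", "SDUI", "SAB", "TTY", "CODE", "STR", "SRL", "SUPPRESS", "CVF",
)
# Standard MRREL column layout (16 fields + trailing delimiter).
MRREL_COLUMNS = (
    "CUI1", "AUI1", "STYPE1", "REL", "CUI2", "AUI2", "STYPE2", "RELA",
    "RUI", "SRUI", "SAB", "SL", "RG", "DIR", "SUPPRESS", "CVF",
)

SUPPRESSIBLE_FLAGS = frozenset({"O", "E", "Y"})


@dataclass(frozen=True)
class Atom:
    """One vocabulary string occurrence from MRCONSO.

    ``cui`` links synonymous atoms across source vocabularies; ``sab`` is
    the source abbreviation (MDR, ICD9CM, ICD10CM, SNOMEDCT_US, ...);
    ``tty`` the source term type (PT, LLT, ...); ``code`` the source-native
    identifier; ``string`` the term text.
    """

    cui: str
    lat: str
    sab: str
    tty: str
    code: str
    string: str
    suppress: str = "N"

    def __post_init__(self) -> None:
        if not self.cui:
            raise ValueError("Atom.cui must be non-empty")
        if not self.sab:
            raise ValueError("Atom.sab must be non-empty")
        if not self.string.strip():
            raise ValueError("Atom.string must be non-empty after trimming")


@dataclass(frozen=True)
class Relationship:
    """One MRREL row: an asymmetric relationship between two CUIs."""

    cui1: str
    cui2: str
    rel: str
    rela: str = ""

    def __post_init__(self) -> None:
        if not self.cui1 or not self.cui2:
            raise ValueError("Relationship CUIs must be non-empty")


@dataclass(frozen=True)
class OMOPConcept:
    concept_id: int
    concept_name: str
    vocabulary_id: str
    concept_class_id: str
    concept_code: str


@dataclass(frozen=True)
class OMOPRelationship:
    concept_id_1: int
    concept_id_2: int
    relationship_id: str


@dataclass(frozen=True)
class AnnotationRecord:
    """One (item, rater, relation category) label."""

    item_id: str
    rater_id: str
    category: str


@dataclass
class MedDRAHierarchy:
    """LLT->PT and PT->SOC maps with term strings.

    Every LLT maps to exactly one parent PT; every PT has at least one SOC
    (multiaxiality) with exactly one flagged primary, and carries a
    self-referential LLT sharing its code.
    """

    llt_to_pt: dict[str, str] = field(default_factory=dict)
    pt_to_socs: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)
    pt_strings: dict[str, str] = field(default_factory=dict)
    llt_strings: dict[str, str] = field(default_factory=dict)
    llt_current: dict[str, bool] = field(default_factory=dict)

    @property
    def pts(self) -> set[str]:
        return set(self.pt_to_socs)

    @property
    def n_pt(self) -> int:
        return len(self.pt_to_socs)

    def primary_soc(self, pt_code: str) -> str:
        for soc, primary in self.pt_to_socs[pt_code]:
            if primary:
                return soc
        raise KeyError(f"PT {pt_code} has no primary SOC")

    def socs(self) -> list[str]:
        seen: dict[str, None] = {}
        for assignments in self.pt_to_socs.values():
            for soc, _ in assignments:
                seen.setdefault(soc)
        return list(seen)

    def validate(self) -> None:
        for pt, assignments in self.pt_to_socs.items():
            if not assignments:
                raise ValueError(f"PT {pt} lacks a SOC assignment")
            n_primary = sum(1 for _, primary in assignments if primary)
            if n_primary != 1:
                raise ValueError(
                    f"PT {pt} has {n_primary} primary SOCs; exactly 1 required"
                )
            if self.llt_to_pt.get(pt) != pt:
                raise ValueError(f"PT {pt} is missing its identical self-LLT")
        for llt, pt in self.llt_to_pt.items():
            if pt not in self.pt_to_socs:
                raise ValueError(f"LLT {llt} points to unknown PT {pt}")


# ---------------------------------------------------------------------------
# RRF


def _iter_rrf(path: Path, n_fields: int):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("|")
            # trailing delimiter produces one empty final element
            if len(parts) != n_fields + 1 or parts[-1] != "":
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_fields} "
                    f"pipe-delimited fields with trailing '|', "
                    f"got {len(parts) - 1}"
                )
            yield parts[:-1]


def read_mrconso(
    path: str | Path,
    filters: Optional[Iterable[str]] = None,
    english_only: bool = True,
    exclude_suppressed: bool = False,
) -> list[Atom]:
    """Parse an MRCONSO.RRF file into atoms, in file order.

    Parameters
    ----------
    filters : optional set of SAB values; only atoms from those sources are
        returned.  ``None`` keeps every source.
    english_only : keep only LAT == ENG rows (all terminologies mapped by
        this pipeline are English).
    exclude_suppressed : drop atoms whose SUPPRESS flag is O, E or Y.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MRCONSO file not found: {path}")
    wanted = set(filters) if filters is not None else None
    atoms: list[Atom] = []
    for row in _iter_rrf(path, len(MRCONSO_COLUMNS)):
        lat, sab, suppress = row[1], row[11], row[16]
        if english_only and lat != "ENG":
            continue
        if wanted is not None and sab not in wanted:
            continue
        if exclude_suppressed and suppress in SUPPRESSIBLE_FLAGS:
            continue
        atoms.append(
            Atom(
                cui=row[0],
                lat=lat,
                sab=sab,
                tty=row[12],
                code=row[13],
                string=row[14],
                suppress=suppress,
            )
        )
    return atoms


def write_mrconso(atoms: Iterable[Atom], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in atoms:
            row = [""] * len(MRCONSO_COLUMNS)
            row[0], row[1], row[11] = a.cui, a.lat, a.sab
            row[12], row[13], row[14], row[16] = a.tty, a.code, a.string, a.suppress
            fh.write("|".join(row) + "|\n")


def read_mrrel(path: str | Path) -> list[Relationship]:
    """Parse an MRREL.RRF file; REL and RELA columns are extracted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MRREL file not found: {path}")
    rels: list[Relationship] = []
    for row in _iter_rrf(path, len(MRREL_COLUMNS)):
        rels.append(Relationship(cui1=row[0], cui2=row[4], rel=row[3], rela=row[7]))
    return rels


def write_mrrel(relationships: Iterable[Relationship], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in relationships:
            row = [""] * len(MRREL_COLUMNS)
            row[0], row[3], row[4], row[7] = r.cui1, r.rel, r.cui2, r.rela
            fh.write("|".join(row) + "|\n")


# ---------------------------------------------------------------------------
# OMOP

_CONCEPT_REQUIRED = (
    "concept_id", "concept_name", "vocabulary_id", "concept_class_id", "concept_code",
)
_RELATIONSHIP_REQUIRED = ("concept_id_1", "concept_id_2", "relationship_id")


def _read_omop_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_omop_tables(
    concept_path: str | Path,
    relationship_path: str | Path,
    validate: bool = False,
) -> tuple[list[OMOPConcept], list[OMOPRelationship]]:
    """Read OMOP CONCEPT and CONCEPT_RELATIONSHIP tables.

    With ``validate=True`` every relationship endpoint must exist in the
    companion CONCEPT table.
    """
    cdf = _read_omop_table(Path(concept_path), _CONCEPT_REQUIRED)
    rdf = _read_omop_table(Path(relationship_path), _RELATIONSHIP_REQUIRED)
    concepts = [
        OMOPConcept(
            concept_id=int(row.concept_id),
            concept_name=row.concept_name,
            vocabulary_id=row.vocabulary_id,
            concept_class_id=row.concept_class_id,
            concept_code=row.concept_code,
        )
        for row in cdf.itertuples(index=False)
    ]
    relationships = [
        OMOPRelationship(
            concept_id_1=int(row.concept_id_1),
            concept_id_2=int(row.concept_id_2),
            relationship_id=row.relationship_id,
        )
        for row in rdf.itertuples(index=False)
    ]
    if validate:
        known = {c.concept_id for c in concepts}
        for r in relationships:
            for cid in (r.concept_id_1, r.concept_id_2):
                if cid not in known:
                    raise ValueError(
                        f"CONCEPT_RELATIONSHIP references concept_id {cid} "
                        f"absent from CONCEPT table"
                    )
    return concepts, relationships


def write_omop_tables(
    concepts: Iterable[OMOPConcept],
    relationships: Iterable[OMOPRelationship],
    concept_path: str | Path,
    relationship_path: str | Path,
) -> None:
    with open(concept_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CONCEPT_REQUIRED)
        for c in concepts:
            w.writerow([c.concept_id, c.concept_name, c.vocabulary_id,
                        c.concept_class_id, c.concept_code])
    with open(relationship_path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_RELATIONSHIP_REQUIRED)
        for r in relationships:
            w.writerow([r.concept_id_1, r.concept_id_2, r.relationship_id])


# ---------------------------------------------------------------------------
# MedDRA distribution ASCII


def _iter_dollar(path: Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            yield lineno, line.split("$")


def read_meddra_hierarchy(
    llt_path: str | Path, pt_path: str | Path
) -> MedDRAHierarchy:
    """Read the "$"-delimited LLT and PT files into a validated hierarchy.

    LLT rows: ``llt_code$llt_name$pt_code$currency$`` (currency Y/N,
    optional, defaults to current).  PT rows: ``pt_code$pt_name$soc_name$
    primary_flag$`` — one row per (PT, SOC) assignment, exactly one row per
    PT flagged Y.
    """
    hierarchy = MedDRAHierarchy()
    llt_path, pt_path = Path(llt_path), Path(pt_path)

    for lineno, fields in _iter_dollar(pt_path):
        if len(fields) < 4:
            raise ValueError(f"{pt_path}: line {lineno}: expected >=4 '$' fields")
        code, name, soc, flag = fields[0], fields[1], fields[2], fields[3]
        if not soc:
            raise ValueError(f"{pt_path}: line {lineno}: PT {code} lacks a SOC")
        hierarchy.pt_strings.setdefault(code, name)
        hierarchy.pt_to_socs.setdefault(code, []).append((soc, flag == "Y"))

    for lineno, fields in _iter_dollar(llt_path):
        if len(fields) < 3:
            raise ValueError(f"{llt_path}: line {lineno}: expected >=3 '$' fields")
        code, name, pt = fields[0], fields[1], fields[2]
        if not pt:
            raise ValueError(f"{llt_path}: line {lineno}: LLT {code} has no PT parent")
        if code in hierarchy.llt_to_pt and hierarchy.llt_to_pt[code] != pt:
            raise ValueError(f"{llt_path}: line {lineno}: LLT {code} has multiple PT parents")
        hierarchy.llt_to_pt[code] = pt
        hierarchy.llt_strings[code] = name
        currency = fields[3] if len(fields) > 3 and fields[3] else "Y"
        hierarchy.llt_current[code] = currency == "Y"

    hierarchy.validate()
    return hierarchy


def write_meddra_hierarchy(
    hierarchy: MedDRAHierarchy, llt_path: str | Path, pt_path: str | Path
) -> None:
    with open(pt_path, "w", encoding="utf-8") as fh:
        for pt in sorted(hierarchy.pt_to_socs):
            name = hierarchy.pt_strings.get(pt, "")
            for soc, primary in hierarchy.pt_to_socs[pt]:
                fh.write(f"{pt}${name}${soc}${'Y' if primary else 'N'}$\n")
    with open(llt_path, "w", encoding="utf-8") as fh:
        for llt in sorted(hierarchy.llt_to_pt):
            name = hierarchy.llt_strings.get(llt, "")
            current = "Y" if hierarchy.llt_current.get(llt, True) else "N"
            fh.write(f"{llt}${name}${hierarchy.llt_to_pt[llt]}${current}$\n")


# ---------------------------------------------------------------------------
# Annotation labels


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    records: list[AnnotationRecord] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in ("item_id", "rater_id", "category")
                   if c not in (reader.fieldnames or [])]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
        for row in reader:
            key = (row["item_id"], row["rater_id"])
            if key in seen:
                raise ValueError(f"{path}: duplicate (item_id, rater_id) {key}")
            seen.add(key)
            records.append(AnnotationRecord(row["item_id"], row["rater_id"], row["category"]))
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["item_id", "rater_id", "category"])
        for r in records:
            w.writerow([r.item_id, r.rater_id, r.category])


def annotations_by_rater(
    records: Iterable[AnnotationRecord],
) -> dict[str, dict[str, str]]:
    """Pivot annotation records into per-rater item->category maps."""
    out: dict[str, dict[str, str]] = {}
    for r in records:
        out.setdefault(r.rater_id, {})[r.item_id] = r.category
    return out
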