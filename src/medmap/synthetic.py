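"""Synthetic UMLS/OMOP/MedDRA fixtures with planted ground truth.

UMLS, MedDRA and the full OMOP vocabulary are licensed distributions, so
every downstream stage here is exercised on generated stand-ins instead.
The generator emits a self-consistent toy release — MRCONSO.RRF /
MRREL.RRF, OMOP CONCEPT / CONCEPT_RELATIONSHIP tables, and "$"-delimited
MedDRA hierarchy files — in exactly the dialects :mod:`medmap.vocab_io`
reads, with the relational structure the pipeline looks for planted at
configurable rates:

* a fraction of PT terms share a CUI with one or two ICD atoms (the UMLS
  crosswalk), and a fraction of the non-self LLTs likewise;
* a fraction of PT concepts carry a direct MedDRA-ICD relationship row,
  and another fraction a MedDRA->SNOMED equivalence plus an ICD->SNOMED
  "Maps to" row (the indirect chain);
* every unmapped PT gets an ICD-9-CM dictionary entry whose synonym
  strings are lexical variants of the PT string (token shuffling,
  single-token substitution, modifier insertion), graded by
  ``lexical_noise``, as retrieval targets for the BM25 ranker;
* two simulated raters label items with controllable agreement.

All randomness derives from ``SimConfig.seed`` through independent named
streams (one per file type), so fixture files are byte-identical across
runs and across changes in generation order elsewhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from medmap.evaluation import MAPPED_CATEGORIES
from medmap.vocab_io import (
    AnnotationRecord,
    Atom,
    MedDRAHierarchy,
    OMOPConcept,
    OMOPRelationship,
    Relationship,
    write_annotations,
    write_meddra_hierarchy,
    write_mrconso,
    write_mrrel,
    write_omop_tables,
)

#: The 27 MedDRA System Organ Classes.
SOC_NAMES: tuple[str, ...] = (
    "Blood and lymphatic system disorders",
    "Cardiac disorders",
    "Congenital, familial and genetic disorders",
    "Ear and labyrinth disorders",
    "Endocrine disorders",
    "Eye disorders",
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Hepatobiliary disorders",
    "Immune system disorders",
    "Infections and infestations",
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Metabolism and nutrition disorders",
    "Musculoskeletal and connective tissue disorders",
    "Neoplasms benign, malignant and unspecified (incl cysts and polyps)",
    "Nervous system disorders",
    "Pregnancy, puerperium and perinatal conditions",
    "Product issues",
    "Psychiatric disorders",
    "Renal and urinary disorders",
    "Reproductive system and breast disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Skin and subcutaneous tissue disorders",
    "Social circumstances",
    "Surgical and medical procedures",
    "Vascular disorders",
)

_LEXICON = (
    "acute", "chronic", "renal", "hepatic", "cardiac", "gastric", "pulmonary",
    "cerebral", "vascular", "dermal", "ocular", "auditory", "thyroid",
    "adrenal", "biliary", "bronchial", "colonic", "duodenal", "femoral",
    "glossal", "humeral", "iliac", "jejunal", "laryngeal", "mandibular",
    "nasal", "ovarian", "pancreatic", "quadriceps", "radial", "splenic",
    "tibial", "ulnar", "venous", "wrist", "zygomatic", "cyst", "abscess",
    "lesion", "fracture", "stenosis", "fibrosis", "necrosis", "oedema",
    "embolism", "thrombosis", "neuropathy", "myopathy", "dermatitis",
    "nephritis", "hepatitis", "gastritis", "carcinoma", "adenoma", "polyp",
    "ulcer", "rupture", "prolapse", "atrophy", "hypertrophy", "dysplasia",
    "haemorrhage", "infarction", "occlusion", "syndrome", "disorder",
)

_MODIFIERS = (
    "unspecified", "recurrent", "nos", "severe", "mild", "bilateral",
    "congenital", "secondary", "progressive", "idiopathic",
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic vocabulary release.

    Defaults emulate the regime the real crosswalk lives in: 27 SOCs;
    planting rates chosen so the *combined* PT-level coverage (direct PT
    mappings, LLT mappings collapsed onto parents, and both OMOP routes)
    lands near the 27 % observed for MedDRA-ICD; a handful of synonyms per
    ICD concept; moderate lexical noise on synonym strings; and two raters
    at 80 % raw agreement whose label distribution follows the observed
    mapped-group relation frequencies.
    """

    n_soc: int = 27
    n_pt_per_soc: int = 10
    n_llt_per_pt: int = 3  # includes the identical self-LLT
    frac_umls_mapped: float = 0.10
    frac_omop_direct: float = 0.05
    frac_omop_indirect: float = 0.04
    frac_llt_mapped: float = 0.06  # UMLS mapping rate for non-self LLTs
    n_synonyms_per_icd: int = 3
    lexical_noise: float = 0.10
    n_distractor_icd: int = 20
    n_raters: int = 2
    rater_agreement: float = 0.80
    categories: tuple[str, ...] = tuple(c.value for c in MAPPED_CATEGORIES)
    category_probs: tuple[float, ...] = (0.5144, 0.0377, 0.4213, 0.0266)
    disjoint_strings: bool = False  # unique tokens per term (retrieval tests)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_soc <= len(SOC_NAMES):
            raise ValueError(f"n_soc must be in [1, {len(SOC_NAMES)}], got {self.n_soc}")
        for name in ("n_pt_per_soc", "n_llt_per_pt", "n_synonyms_per_icd", "n_raters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_distractor_icd < 0:
            raise ValueError("n_distractor_icd must be non-negative")
        for name in (
            "frac_umls_mapped", "frac_omop_direct", "frac_omop_indirect",
            "frac_llt_mapped", "lexical_noise", "rater_agreement",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.categories) != len(self.category_probs):
            raise ValueError("categories and category_probs must have equal length")
        if abs(sum(self.category_probs) - 1.0) > 1e-9:
            raise ValueError(
                f"category_probs must sum to 1 within 1e-9, "
                f"got {sum(self.category_probs)!r}"
            )
        if any(p < 0 for p in self.category_probs):
            raise ValueError("category_probs must be non-negative")


@dataclass
class GroundTruth:
    """What the generator planted, keyed the way extraction reports pairs.

    Pair keys are (meddra_code, meddra_level, icd_code, icd_version).
    """

    planted_umls_pairs: set[tuple[str, str, str, int]] = field(default_factory=set)
    planted_omop_direct: set[tuple[str, str, str, int]] = field(default_factory=set)
    planted_omop_indirect: set[tuple[str, str, str, int]] = field(default_factory=set)
    planted_exact_lexical_matches: set[tuple[str, str]] = field(default_factory=set)
    query_truth: dict[str, str] = field(default_factory=dict)  # PT string -> icd code
    rater1_labels: dict[str, str] = field(default_factory=dict)
    rater2_labels: dict[str, str] = field(default_factory=dict)
    stats: dict[str, int] = field(default_factory=dict)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ("structure", "lexical", "mrrel", "annotations")
    return {
        name: np.random.default_rng(child)
        for name, child in zip(names, root.spawn(len(names)))
    }


def _icd9_code(i: int) -> str:
    return f"{(i // 100) % 1000:03d}.{i % 100:02d}"


def _icd10_code(i: int) -> str:
    return f"{chr(65 + (i // 1000) % 26)}{(i // 10) % 100:02d}.{i % 10}"


def _perturb(
    string: str, rng: np.random.Generator, noise: float, force_modifier: bool = False
) -> str:
    """Lexical variant: token shuffle / substitution / modifier insertion.

    With ``noise == 0`` and no forced modifier the string is returned
    unchanged; the RNG is consumed identically either way so fixture
    content downstream of a call does not depend on the noise level.
    """
    tokens = string.split()
    subs = rng.random(len(tokens))
    sub_words = rng.choice(len(_LEXICON), size=len(tokens))
    do_shuffle = rng.random()
    perm = rng.permutation(len(tokens))
    do_insert = rng.random()
    modifier = _MODIFIERS[int(rng.integers(len(_MODIFIERS)))]
    position = int(rng.integers(len(tokens) + 1))

    tokens = [
        _LEXICON[sub_words[i]] if subs[i] < noise else t
        for i, t in enumerate(tokens)
    ]
    if do_shuffle < noise:
        tokens = [tokens[i] for i in perm]
    if force_modifier or do_insert < noise:
        tokens.insert(position, modifier)
    return " ".join(tokens)


def generate_fixture(config: SimConfig, output_dir: str | Path) -> GroundTruth:
    """Write one synthetic vocabulary release and return its ground truth.

    Emits ``MRCONSO.RRF``, ``MRREL.RRF``, ``CONCEPT.csv``,
    ``CONCEPT_RELATIONSHIP.csv``, ``llt.asc``, ``pt.asc`` and
    ``annotations.csv`` under ``output_dir``.  Identical configs produce
    byte-identical files.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    rng = _streams(config.seed)
    truth = GroundTruth()

    n_pt = config.n_soc * config.n_pt_per_soc
    n_extra_llt = config.n_llt_per_pt - 1

    # All stochastic structure drawn up front, unconditionally: raising a
    # planting fraction can only add pairs, never reshuffle the rest.
    st = rng["structure"]
    u_umls = st.random(n_pt)
    ver_draw = st.random(n_pt)
    u_direct = st.random(n_pt)
    direct_ver = st.random(n_pt)
    u_indirect = st.random(n_pt)
    indirect_ver = st.random(n_pt)
    u_multiaxial = st.random(n_pt)
    secondary_soc = st.integers(config.n_soc, size=n_pt)
    u_llt = st.random(n_pt * max(n_extra_llt, 1))

    lex = rng["lexical"]
    pt_strings: list[str] = []
    for p in range(n_pt):
        words = lex.choice(len(_LEXICON), size=3, replace=False)
        if config.disjoint_strings:
            pt_strings.append(f"term{p}a term{p}b")
        else:
            pt_strings.append(" ".join(_LEXICON[w] for w in words[:2]))

    hierarchy = MedDRAHierarchy()
    atoms: list[Atom] = []
    cui_counter = 0
    icd_counter = 0

    def next_cui() -> str:
        nonlocal cui_counter
        cui_counter += 1
        return f"C{cui_counter:07d}"

    def next_icd(version: int) -> str:
        nonlocal icd_counter
        icd_counter += 1
        return _icd9_code(icd_counter) if version == 9 else _icd10_code(icd_counter)

    def icd_synonyms(base: str, exact_first: bool) -> list[str]:
        strings = []
        for j in range(config.n_synonyms_per_icd):
            force = j > 0  # later synonyms always vary by a modifier
            noise = 0.0 if (j == 0 and exact_first) else config.lexical_noise
            strings.append(_perturb(base, lex, noise, force_modifier=force))
        return strings

    for p in range(n_pt):
        soc = SOC_NAMES[p // config.n_pt_per_soc]
        pt_code = str(10000000 + p)
        pt_string = pt_strings[p]
        hierarchy.pt_strings[pt_code] = pt_string
        socs = [(soc, True)]
        if u_multiaxial[p] < 0.2:
            other = SOC_NAMES[int(secondary_soc[p])]
            if other != soc:
                socs.append((other, False))
        hierarchy.pt_to_socs[pt_code] = socs
        # identical self-LLT, sharing the PT code
        hierarchy.llt_to_pt[pt_code] = pt_code
        hierarchy.llt_strings[pt_code] = pt_string
        hierarchy.llt_current[pt_code] = True

        umls_mapped = u_umls[p] < config.frac_umls_mapped
        pt_cui = next_cui()
        atoms.append(Atom(pt_cui, "ENG", "MDR", "PT", pt_code, pt_string))
        if umls_mapped:
            versions = (9,) if ver_draw[p] < 0.4 else (10,) if ver_draw[p] < 0.8 else (9, 10)
            for v in versions:
                icd_code = next_icd(v)
                sab = "ICD9CM" if v == 9 else "ICD10CM"
                for s in dict.fromkeys(icd_synonyms(pt_string, exact_first=False)):
                    atoms.append(Atom(pt_cui, "ENG", sab, "PT", icd_code, s))
                truth.planted_umls_pairs.add((pt_code, "PT", icd_code, v))
        else:
            # unmapped PT: plant an ICD-9-CM retrieval target under its own
            # CUI so the BM25 ranker has a recoverable answer
            icd_code = next_icd(9)
            icd_cui = next_cui()
            for s in dict.fromkeys(icd_synonyms(pt_string, exact_first=True)):
                atoms.append(Atom(icd_cui, "ENG", "ICD9CM", "PT", icd_code, s))
            truth.planted_exact_lexical_matches.add((pt_code, icd_code))
            truth.query_truth[pt_string] = icd_code

        for e in range(n_extra_llt):
            llt_idx = p * n_extra_llt + e
            llt_code = str(80000000 + llt_idx)
            llt_string = _perturb(pt_string, lex, config.lexical_noise, force_modifier=True)
            hierarchy.llt_to_pt[llt_code] = pt_code
            hierarchy.llt_strings[llt_code] = llt_string
            hierarchy.llt_current[llt_code] = True
            if u_llt[llt_idx] < config.frac_llt_mapped:
                llt_cui = next_cui()
                icd_code = next_icd(9)
                atoms.append(Atom(llt_cui, "ENG", "MDR", "LLT", llt_code, llt_string))
                atoms.append(Atom(llt_cui, "ENG", "ICD9CM", "PT", icd_code, llt_string))
                truth.planted_umls_pairs.add((llt_code, "LLT", icd_code, 9))

    # distractor ICD entries with lexicon strings and their own CUIs
    for _ in range(config.n_distractor_icd):
        words = lex.choice(len(_LEXICON), size=2, replace=False)
        s = " ".join(_LEXICON[w] for w in words)
        atoms.append(Atom(next_cui(), "ENG", "ICD9CM", "PT", next_icd(9), s))

    # ------------------------------------------------------------------ OMOP
    concepts: list[OMOPConcept] = []
    relationships: list[OMOPRelationship] = []
    cid = 0

    def next_cid() -> int:
        nonlocal cid
        cid += 1
        return cid

    med_cids: dict[str, int] = {}
    for p in range(n_pt):
        pt_code = str(10000000 + p)
        c = next_cid()
        med_cids[pt_code] = c
        concepts.append(OMOPConcept(c, pt_strings[p], "MedDRA", "PT", pt_code))
    for p in range(n_pt):
        pt_code = str(10000000 + p)
        if u_direct[p] < config.frac_omop_direct:
            v = 9 if direct_ver[p] < 0.5 else 10
            icd_code = next_icd(v)
            vocab = "ICD9CM" if v == 9 else "ICD10CM"
            icd_cid = next_cid()
            concepts.append(
                OMOPConcept(icd_cid, f"{pt_strings[p]} (icd)", vocab, "4-char billing code", icd_code)
            )
            relationships.append(
                OMOPRelationship(med_cids[pt_code], icd_cid, f"MedDRA - {vocab} eq")
            )
            truth.planted_omop_direct.add((pt_code, "PT", icd_code, v))
        if u_indirect[p] < config.frac_omop_indirect:
            v = 9 if indirect_ver[p] < 0.5 else 10
            icd_code = next_icd(v)
            vocab = "ICD9CM" if v == 9 else "ICD10CM"
            sno_cid = next_cid()
            concepts.append(
                OMOPConcept(sno_cid, f"{pt_strings[p]} (snomed)", "SNOMED",
                            "Clinical Finding", str(400000 + p))
            )
            icd_cid = next_cid()
            concepts.append(
                OMOPConcept(icd_cid, f"{pt_strings[p]} (icd)", vocab, "4-char billing code", icd_code)
            )
            relationships.append(
                OMOPRelationship(med_cids[pt_code], sno_cid, "MedDRA - SNOMED eq")
            )
            # OMOP convention: the non-standard ICD concept maps TO SNOMED
            relationships.append(OMOPRelationship(icd_cid, sno_cid, "Maps to"))
            truth.planted_omop_indirect.add((pt_code, "PT", icd_code, v))

    # ----------------------------------------------------------------- MRREL
    mrrel_rng = rng["mrrel"]
    mrrel: list[Relationship] = []
    all_cuis = [f"C{i:07d}" for i in range(1, cui_counter + 1)]
    for c in all_cuis:
        if mrrel_rng.random() < 0.3:
            mrrel.append(Relationship(c, c, "SY"))
    for i, c in enumerate(all_cuis[:-1]):
        r = mrrel_rng.random()
        if r < 0.1:
            mrrel.append(Relationship(c, c, "RQ"))
        elif r < 0.25:
            mrrel.append(Relationship(c, all_cuis[i + 1], "RQ", "classified_as"))

    # ----------------------------------------------------------- annotations
    items = sorted(f"{m}|{lvl}|{i}|{v}" for m, lvl, i, v in truth.planted_umls_pairs)
    if items:
        truth.rater1_labels, truth.rater2_labels = generate_annotations(items, config)

    truth.stats = {
        "n_pt": n_pt,
        "n_llt": len(hierarchy.llt_to_pt),
        "n_atoms": len(atoms),
        "n_icd_cuis": len({a.cui for a in atoms if a.sab in ("ICD9CM", "ICD10CM")}),
        "n_icd_synonym_strings": len(
            {(a.cui, a.string) for a in atoms if a.sab in ("ICD9CM", "ICD10CM")}
        ),
    }

    write_mrconso(atoms, output_dir / "MRCONSO.RRF")
    write_mrrel(mrrel, output_dir / "MRREL.RRF")
    write_omop_tables(
        concepts, relationships,
        output_dir / "CONCEPT.csv", output_dir / "CONCEPT_RELATIONSHIP.csv",
    )
    write_meddra_hierarchy(hierarchy, output_dir / "llt.asc", output_dir / "pt.asc")
    records = [
        AnnotationRecord(item, "rater1", truth.rater1_labels[item])
        for item in sorted(truth.rater1_labels)
    ] + [
        AnnotationRecord(item, "rater2", truth.rater2_labels[item])
        for item in sorted(truth.rater2_labels)
    ]
    write_annotations(records, output_dir / "annotations.csv")
    return truth


def generate_annotations(
    items: Sequence[str], config: SimConfig
) -> tuple[dict[str, str], dict[str, str]]:
    """Simulated two-rater labels over ``items``.

    Rater 1 draws from ``category_probs``; rater 2 copies rater 1's label
    with probability ``rater_agreement`` and otherwise draws independently
    from the same distribution.  Deterministic under ``config.seed``.
    """
    if not items:
        raise ValueError("cannot annotate an empty item list")
    rng = _streams(config.seed)["annotations"]
    probs = np.asarray(config.category_probs)
    cats = np.asarray(config.categories)
    r1 = rng.choice(cats, size=len(items), p=probs)
    copy = rng.random(len(items)) < config.rater_agreement
    independent = rng.choice(cats, size=len(items), p=probs)
    r2 = np.where(copy, r1, independent)
    return (
        {item: str(lab) for item, lab in zip(items, r1)},
        {item: str(lab) for item, lab in zip(items, r2)},
    )
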