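# Methods

## The crosswalk problem

MedDRA and ICD serve different masters: MedDRA's Preferred Terms (PTs) are
the reporting unit of pharmacovigilance systems, ICD-9-CM/ICD-10-CM the
billing and diagnosis codes of EHRs. A crosswalk between them lets a
safety signal detected in spontaneous reports be checked against
observational data. `medmap` constructs such a crosswalk from two public
mapping substrates and quantifies both its **coverage** (what fraction of
PTs gets any ICD link) and its **quality** (how often a link is a true
semantic equivalence rather than a broader/narrower or partial relation).

## Pair extraction

**UMLS CUI join.** In the Metathesaurus, every atom (one string from one
source vocabulary) carries a Concept Unique Identifier; atoms sharing a
CUI are asserted synonyms. For each CUI we emit the full cross product of
its MDR atoms (term types PT and LLT only — other MedDRA levels barely
occur in UMLS) with its ICD9CM and ICD10CM atoms, deduplicated on
(meddra_code, level, icd_code, version). The CUI is the *only* criterion:
MRREL relationship rows are deliberately not treated as mapping evidence.
`rel_cui_concordance` provides the supporting diagnostic — on a given
release it tabulates, per REL label, how many rows connect the same CUI
(so the row adds nothing beyond the join) and, among discordant rows, the
RELA distribution (dominated by classifies/classified-as, i.e.
hierarchical rather than synonymous links).

**OMOP direct and indirect.** CONCEPT_RELATIONSHIP rows whose
relationship_id names both MedDRA and ICD yield direct pairs. The
indirect route chains a MedDRA→SNOMED equivalence with a SNOMED↔ICD
"Maps to" edge. In OMOP releases "Maps to" points from the non-standard
ICD concept *to* the standard SNOMED concept, so both edge directions are
accepted on both legs; only the single SNOMED hop is traversed — no
transitive closure. Relationship-id sets are configurable because their
exact spelling varies across vocabulary releases.

**Cross-check.** Extracted pairs can be filtered against an official
MedDRA release by string (case-insensitive, whitespace-normalized at the
pair's own level); stale strings are dropped and divergent codes replaced
by the release's code.

## Coverage

Every PT has an identical self-LLT (same code), so LLT-level pairs
collapse losslessly onto their parent PT; coverage = unique mapped PTs /
all PTs in the release, with percentages rounded **half-up to two
decimals** (the convention of printed summary tables; Python's banker's
rounding would disagree on boundary values). Per-source cells count
distinct MedDRA *terms*, not pairs. Per-SOC summaries attribute each PT
once, to its primary SOC, so counts partition the PT set; an `all_socs`
mode counts multiaxially instead. Snapshot trends report two
denominators — all PTs in the release, and PTs present in that snapshot's
atoms — because a coverage decline over time can reflect either fewer
mappings or faster vocabulary growth.

## Candidate ranking

Unmapped PTs are queries against a CUI-grouped dictionary of ICD entries
(ICD-9-CM by default, ICD-10-CM addable), one document per synonym
string. Scoring is Okapi BM25 with the non-negative idf
`ln(1 + (N − df + 0.5)/(df + 0.5))`; k1 = 1.2 and b = 0.75 (the classical
Robertson/Lucene defaults, configurable); query-side term frequency is
ignored since clinical-term queries are short and rarely repeat tokens.
Document scores aggregate to code level by **max** over the code's
synonym documents — sum would reward synonym count rather than match
quality. Ties break on ascending ICD code for determinism; the list
truncates to the top 25. Tokenization is lowercase, split on
non-alphanumeric runs, no stemming or stopwords ("Buerger's disease" →
`buerger, s, disease`).

## Evaluation

The relation schema is Venn-diagram-based: EXACT_MATCH, PT_NARROWER,
PT_BROADER, PARTIAL_OVERLAP for crosswalk pairs, plus TOTALLY_IRRELEVANT,
NO_RESPONSE and OTHER for unmapped terms (NO_RESPONSE — the search
returned nothing — is a legitimate zero-count row in summaries).
Sampling: 10 % of mapped PT pairs (ceiling, uniform without replacement,
seeded) and up to 100 unmapped PTs per primary SOC (shortfall SOCs
contribute everything they have). Agreement is Cohen's kappa — chance
correction from each rater's *own* marginals, not pooled (Scott's pi) —
with the degenerate pe = 1 case flagged rather than divided through.
A calibration gate requires ≥ 80 % raw agreement (boundary inclusive)
before annotation proceeds; adjudicated consolidation requires an
explicit resolution for every disagreement.

## The synthetic generator

Licensed UMLS/MedDRA/OMOP files cannot ship, so fixtures are generated:
27 SOCs (the real SOC names), `n_pt_per_soc` = 10 PTs each, 3 LLTs per PT
(including the self-LLT), 8-digit MedDRA codes, "ddd.dd" ICD-9-CM and
letter-digit-digit-dot-suffix ICD-10-CM codes. Planting rates are the
study conditions: `frac_umls_mapped` = 0.10 per PT (of which 40 % map to
ICD-9 only, 40 % ICD-10 only, 20 % both), `frac_llt_mapped` = 0.06 per
non-self LLT, `frac_omop_direct` = 0.05, `frac_omop_indirect` = 0.04.
These compound, after LLT→PT collapse, to an expected PT-level coverage
of ≈ 27 % — the regime observed for the real MedDRA–ICD crosswalk. Every
unmapped PT gets an ICD-9-CM retrieval target under its own CUI whose
first synonym is the PT string perturbed at `lexical_noise` (token
shuffling, single-token substitution, modifier insertion; 0.10 by
default), with `n_synonyms_per_icd` = 3 variants, so the ranker has
recoverable answers of graded difficulty. Simulated raters draw from the
mapped-group relation frequencies (0.5144 / 0.0377 / 0.4213 / 0.0266)
with `rater_agreement` = 0.80 (rater 2 copies rater 1 with that
probability, else redraws), reproducing the observed-agreement/kappa
regime of real annotation rounds.

Two generator switches exist purely to make stated guarantees
constructible: `disjoint_strings` replaces lexicon-based term strings
with per-term unique tokens (the condition under which noise-free
recall@1 = 1 is provable), and `frac_llt_mapped` controls LLT-level
planting so the collapse step has work to do. All randomness flows from
`seed` through four named streams (structure, lexical, MRREL,
annotations); structure draws are taken up front and unconditionally, so
raising a planting fraction adds pairs monotonically without reshuffling
the rest, and identical configs produce byte-identical files.

**What the fixtures do not emulate:** real vocabulary scale (the
Metathesaurus has millions of atoms; fixtures have hundreds), clinical
string realism, skewed synonym-count distributions, suppressed or
non-current terms in volume, and one-to-many code structure within a CUI.
Passing tests therefore demonstrate the *correctness of the relational
logic* (extraction is provably exact against planted truth, scoring
matches the BM25 formula, kappa matches its definition) — not the
coverage or agreement numbers any particular licensed release would
yield.

## Numerical and design choices

- Percentages: half-up, two decimals, via `decimal.Decimal`.
- Pair identity excludes strings: same code, different strings → one pair;
  merged pairs keep the union of provenance tags.
- RRF dialect: UTF-8, pipe-delimited, trailing pipe, no header;
  suppressible atoms (O/E/Y) are kept by default with an exclusion flag;
  `english_only` defaults on. Non-current LLTs are surfaced
  (`llt_current`) but not filtered.
- MedDRA ASCII dialect: "$"-delimited; the PT file carries one row per
  (PT, SOC) with a Y/N primary flag — a single-file flattening of the
  distribution's pt/mdhier pair, chosen so one reader yields a complete
  multiaxial hierarchy.
- BM25 index documents are ordered by (CUI, string); empty queries and
  token-disjoint queries return empty candidate lists rather than errors.
- Problem sizes in tests and in `scripts/acceptance.py` (270-PT releases,
  20-seed recovery sweeps, 108-query retrieval corpora, 5000-item rater
  simulations) are chosen to estimate each rate to well under its
  tolerance while keeping the whole suite in seconds.

## Known limitations

- The OMOP extractors trust vocabulary_id strings ("MedDRA", "SNOMED",
  "ICD9CM", "ICD10CM"); nonstandard spellings need explicit
  relationship/vocabulary configuration.
- `crosscheck_with_meddra` matches whole strings only; it will not rescue
  pairs whose strings differ by more than case/whitespace.
- The ranker is purely lexical (BM25 over UMLS-provided synonyms): no
  embeddings, stemming or abbreviation expansion, so true synonyms with
  disjoint vocabulary ("thromboangiitis obliterans" vs "Buerger's
  disease") are out of reach by construction.
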