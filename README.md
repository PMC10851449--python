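# medmap

Tools for building and evaluating a **MedDRA ↔ ICD terminology crosswalk**.

Adverse drug events are reported at the MedDRA Preferred Term (PT) level
(FAERS and similar pharmacovigilance systems), while electronic health
records code diagnoses in ICD-9-CM / ICD-10-CM. Verifying a safety signal
against observational data therefore needs a reliable link between the two
terminologies. `medmap` implements that link-building pipeline end to end,
for medical informaticians and pharmacovigilance researchers:

1. **Pair extraction.** MedDRA–ICD mapped pairs are read out of the UMLS
   Metathesaurus by the CUI join — two atoms sharing a Concept Unique
   Identifier are asserted synonyms, so every (MDR, ICD9CM/ICD10CM) atom
   pair under one CUI is a mapped pair — and out of the OMOP standardized
   vocabulary via direct MedDRA–ICD relationship rows and the indirect
   chain MedDRA → SNOMED ("MedDRA - SNOMED eq") → ICD ("Maps to").
   `rel_cui_concordance` quantifies why the CUI is used as the only
   mapping criterion: relationship rows (REL = SY/RQ) are mostly
   CUI-concordant or dominated by classification rather than synonymy.
2. **Coverage analysis.** Because every PT is self-contained at the LLT
   level, LLT-level pairs collapse onto their parent PT; coverage is the
   fraction of all PTs carrying at least one ICD link, overall, per System
   Organ Class (primary-SOC attribution partitions the PT set), and across
   vocabulary snapshots for trend analysis.
3. **Candidate ranking.** For unmapped PT terms, ICD entries are grouped
   by CUI into a synonym dictionary, indexed one document per synonym
   string, and ranked against the PT query with Okapi BM25
   (`idf(t) = ln(1 + (N − df + 0.5)/(df + 0.5))`, defaults k1 = 1.2,
   b = 0.75, top 25 candidates, max-aggregation over a code's synonyms).
4. **Quality evaluation.** Sampled mapped pairs (10 % of the crosswalk)
   and unmapped PTs (100 per SOC) are labelled with a Venn-diagram relation
   schema — exact match, PT narrower/broader than ICD, partial overlap,
   plus totally-irrelevant / no-response / other for the unmapped group —
   by two raters whose reliability is measured with Cohen's kappa,
   κ = (p₀ − pₑ)/(1 − pₑ), behind an 80 % raw-agreement calibration gate.

UMLS, MedDRA and OMOP distributions are licensed, so the package ships a
**synthetic vocabulary generator** (`medmap.synthetic`) that writes a
self-consistent toy release — MRCONSO.RRF, MRREL.RRF, OMOP CONCEPT /
CONCEPT_RELATIONSHIP, "$"-delimited MedDRA hierarchy files — with the
mapping structure planted at configurable rates and returned as ground
truth, making every stage testable without licensed data.

## Worked example

```python
from medmap.synthetic import SimConfig, generate_fixture
from medmap import vocab_io as vio, extraction as ex, coverage as cov

truth = generate_fixture(SimConfig(seed=3), "release/")
atoms = vio.read_mrconso("release/MRCONSO.RRF")
concepts, rels = vio.read_omop_tables("release/CONCEPT.csv",
                                      "release/CONCEPT_RELATIONSHIP.csv")
hierarchy = vio.read_meddra_hierarchy("release/llt.asc", "release/pt.asc")

pairs = ex.merge_pair_sets([
    ex.extract_umls_pairs(atoms),
    ex.extract_omop_direct(concepts, rels),
    ex.extract_omop_indirect(concepts, rels),
])
report = cov.coverage_summary(cov.llt_pairs_to_pt(pairs, hierarchy),
                              hierarchy, all_pairs=pairs)
print(report.n_pt_mapped, "/", report.n_pt_total, "PTs mapped,",
      report.pct_pt_mapped, "%")
```

prints

```
62 / 270 PTs mapped, 22.96 %
```

i.e. of the 270 generated PT terms, 62 carry at least one ICD link through
UMLS or OMOP after LLT→PT aggregation — a 22.96 % coverage, matching the
roughly-one-in-four regime the generator's default planting rates emulate.
Extraction is exact on synthetic releases: the recovered pair set equals
the planted ground truth (`{p.key for p in ex.extract_umls_pairs(atoms)}
== truth.planted_umls_pairs`).

The same steps are available from a shell:

```bash
medmap simulate --seed 3 --out release/
medmap extract --mrconso release/MRCONSO.RRF \
    --omop-concept release/CONCEPT.csv --omop-rel release/CONCEPT_RELATIONSHIP.csv \
    --out pairs.csv
medmap coverage --pairs pairs.csv --meddra-llt release/llt.asc \
    --meddra-pt release/pt.asc --out report.json
medmap rank --mrconso release/MRCONSO.RRF --queries terms.txt --out candidates.csv
medmap evaluate --labels1 a.csv --labels2 b.csv --out summary.json
```

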