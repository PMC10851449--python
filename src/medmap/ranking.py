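"""Candidate ICD codes for unmapped MedDRA PT terms, via BM25 retrieval.

The searcher groups ICD atoms by CUI into a synonym dictionary, indexes one
document per synonym string, and scores documents against a PT-term query
with the Okapi BM25 weighting used by Lucene:

    score(q, d) = sum over distinct query tokens t of
                  idf(t) * tf(t,d) * (k1 + 1)
                  / (tf(t,d) + k1 * (1 - b + b * |d| / avgdl))

    idf(t) = ln(1 + (N - df(t) + 0.5) / (df(t) + 0.5))

with N the document count, df the document frequency, |d| the document
token length and avgdl the mean document length.  The idf form is
non-negative, so scores are non-negative.  Query-side term frequency is
ignored (clinical-term queries are short); document scores aggregate to the
code level by maximum over the code's synonym documents, so a concept with
many synonyms gains recall but not an inflated score.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from medmap.vocab_io import Atom

_TOKEN_RE = re.compile(r"[0-9a-z]+")

ICD_VERSION_BY_SAB = {"ICD9CM": 9, "ICD10CM": 10}


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric runs; no stemming/stopwords."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class BM25Params:
    """k1 controls term-frequency saturation; b length normalization."""

    k1: float = 1.2
    b: float = 0.75
    top_k: int = 25

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError("k1 must be > 0")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must be in [0, 1]")
        if self.top_k <= 0:
            raise ValueError("top_k must be positive")


@dataclass
class SynonymDictionary:
    """CUI-grouped ICD entries: codes and all synonym strings per concept."""

    entries: dict[str, tuple[set[tuple[str, int]], set[str]]] = field(
        default_factory=dict
    )

    @property
    def n_docs(self) -> int:
        return sum(len(strings) for _, strings in self.entries.values())


@dataclass
class InvertedIndex:
    postings: dict[str, list[tuple[int, int]]]
    doc_lengths: dict[int, int]
    avg_doc_length: float
    doc_meta: dict[int, tuple[str, tuple[tuple[str, int], ...], str]]

    @property
    def n_docs(self) -> int:
        return len(self.doc_lengths)


@dataclass(frozen=True)
class RankedCandidate:
    query: str
    icd_code: str
    icd_version: int
    cui: str
    score: float
    rank: int


def build_dictionary(
    atoms: Iterable[Atom], sources: Iterable[str] = ("ICD9CM",)
) -> SynonymDictionary:
    """Group ICD atoms by CUI, collecting codes and synonym strings.

    Defaults to ICD-9-CM only; pass ``{"ICD9CM", "ICD10CM"}`` to index both
    code systems.
    """
    sources = set(sources)
    unknown = sources - set(ICD_VERSION_BY_SAB)
    if unknown:
        raise ValueError(f"unsupported dictionary sources: {sorted(unknown)}")
    d = SynonymDictionary()
    for a in atoms:
        if a.sab not in sources:
            continue
        codes, strings = d.entries.setdefault(a.cui, (set(), set()))
        codes.add((a.code, ICD_VERSION_BY_SAB[a.sab]))
        strings.add(a.string)
    return d


def build_index(dictionary: SynonymDictionary) -> InvertedIndex:
    """Index one document per synonym string.

    Documents are ordered by (CUI, string) so index construction is
    deterministic regardless of atom input order.
    """
    if not dictionary.entries:
        raise ValueError("cannot index an empty synonym dictionary")
    postings: dict[str, list[tuple[int, int]]] = {}
    doc_lengths: dict[int, int] = {}
    doc_meta: dict[int, tuple[str, tuple[tuple[str, int], ...], str]] = {}
    doc_id = 0
    for cui in sorted(dictionary.entries):
        codes, strings = dictionary.entries[cui]
        code_tuple = tuple(sorted(codes))
        for s in sorted(strings):
            tokens = tokenize(s)
            doc_lengths[doc_id] = len(tokens)
            doc_meta[doc_id] = (cui, code_tuple, s)
            tf: dict[str, int] = {}
            for t in tokens:
                tf[t] = tf.get(t, 0) + 1
            for t, n in tf.items():
                postings.setdefault(t, []).append((doc_id, n))
            doc_id += 1
    avg = sum(doc_lengths.values()) / len(doc_lengths)
    return InvertedIndex(
        postings=postings, doc_lengths=doc_lengths, avg_doc_length=avg,
        doc_meta=doc_meta,
    )


def idf(index: InvertedIndex, token: str) -> float:
    df = len(index.postings.get(token, ()))
    n = index.n_docs
    return math.log(1.0 + (n - df + 0.5) / (df + 0.5))


def bm25_score(
    index: InvertedIndex,
    query_tokens: Sequence[str],
    doc_id: int,
    params: BM25Params = BM25Params(),
) -> float:
    """BM25 score of one document against tokenized query terms.

    Repeated query tokens are counted once; tokens absent from the document
    contribute zero.
    """
    if doc_id not in index.doc_lengths:
        raise KeyError(f"unknown document id {doc_id}")
    length = index.doc_lengths[doc_id]
    norm = 1.0 - params.b + params.b * length / index.avg_doc_length
    score = 0.0
    for t in set(query_tokens):
        tf = 0
        for d, n in index.postings.get(t, ()):
            if d == doc_id:
                tf = n
                break
        if tf == 0:
            continue
        score += idf(index, t) * tf * (params.k1 + 1.0) / (tf + params.k1 * norm)
    return score


def rank_candidates(
    index: InvertedIndex, query: str, params: BM25Params = BM25Params()
) -> list[RankedCandidate]:
    """Top candidate ICD codes for a PT-term query.

    Every document sharing at least one token with the query is scored;
    scores aggregate to code level by maximum over the code's synonym
    documents, ties break on ascending ICD code, and the list is truncated
    to ``params.top_k`` with 1-based ranks.
    """
    query_tokens = tokenize(query)
    if not query_tokens:
        return []
    doc_ids: set[int] = set()
    for t in set(query_tokens):
        doc_ids.update(d for d, _ in index.postings.get(t, ()))
    best: dict[tuple[str, int], tuple[float, str]] = {}
    for d in doc_ids:
        s = bm25_score(index, query_tokens, d, params)
        cui, codes, _ = index.doc_meta[d]
        for code_version in codes:
            prev = best.get(code_version)
            if prev is None or s > prev[0]:
                best[code_version] = (s, cui)
    ordered = sorted(
        best.items(), key=lambda kv: (-kv[1][0], kv[0][0], kv[0][1])
    )[: params.top_k]
    return [
        RankedCandidate(
            query=query, icd_code=code, icd_version=version, cui=cui,
            score=score, rank=i + 1,
        )
        for i, ((code, version), (score, cui)) in enumerate(ordered)
    ]


def rank_quality(
    rankings: Mapping[str, Sequence[RankedCandidate]],
    truth: Mapping[str, str],
) -> tuple[dict[int, float], float]:
    """Recall@{1,5,25} and mean reciprocal rank over queries with known
    planted matches."""
    missing = set(truth) - set(rankings)
    if missing:
        raise KeyError(f"truth queries absent from rankings: {sorted(missing)}")
    ks = (1, 5, 25)
    hits = {k: 0 for k in ks}
    rr_sum = 0.0
    for q, true_code in truth.items():
        rank = next(
            (c.rank for c in rankings[q] if c.icd_code == true_code), None
        )
        if rank is not None:
            rr_sum += 1.0 / rank
            for k in ks:
                if rank <= k:
                    hits[k] += 1
    n = len(truth)
    recall = {k: hits[k] / n for k in ks}
    return recall, rr_sum / n
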