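"""Literature-based validation of candidate genes from abstract corpora.

A corpus of PubMed-style abstract records (PMID, title, year, abstract) is
cleaned (missing abstracts, duplicate PMIDs, pre-cutoff years dropped), then
passed through a pluggable target-extraction backend that emits evidence
records: (PMID, gene, evidence sentence, co-mentioned drugs).  Candidate risk
genes and PPI neighbors are "validated" when enough distinct articles supply
evidence for them.

The shipped backend is a deterministic lexicon extractor — whole-token,
case-sensitive matching of gene symbols inside segmented sentences.  Any
object implementing ``extract(record) -> [(gene, sentence, drugs), ...]`` can
stand in for it (e.g. a client for an external LLM service); records a
backend returns that violate the evidence invariants are rejected and logged.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbstractRecord",
    "EvidenceRecord",
    "ValidatedGeneSet",
    "TargetExtractor",
    "LexiconExtractor",
    "split_sentences",
    "clean_abstracts",
    "extract_targets",
    "validate_genes",
    "read_abstracts_jsonl",
    "fetch_pubmed_abstracts",
]

DEFAULT_MIN_YEAR = 2001  # "past 25 years", i.e. published after 2000


@dataclass(frozen=True)
class AbstractRecord:
    pmid: str
    title: str
    year: int
    abstract: str


@dataclass(frozen=True)
class EvidenceRecord:
    """One extracted gene mention with its supporting sentence.

    Invariants: the sentence is a verbatim substring of the source abstract,
    and the gene appears as a whole token within the sentence.
    """

    pmid: str
    gene: str
    evidence_sentence: str
    drugs: tuple = ()


@dataclass
class ValidatedGeneSet:
    genes: set
    support: dict  # gene -> sorted list of distinct supporting pmids
    min_articles: int = 1


class TargetExtractor(Protocol):
    def extract(self, record: AbstractRecord) -> list:  # [(gene, sentence, drugs)]
        ...


_ABBREVIATIONS = ("e.g.", "i.e.", "et al.", "vs.", "cf.", "Fig.", "approx.", "ca.")


def split_sentences(text: str) -> list[str]:
    """Segment text on sentence-final punctuation, guarding abbreviations.

    Every returned sentence is a verbatim substring of ``text`` (leading and
    trailing whitespace stripped), so evidence sentences round-trip exactly.
    """
    boundaries = [0]
    for m in re.finditer(r"(?<=[.!?])\s+", text):
        before = text[: m.start()]
        if any(before.endswith(abbr) for abbr in _ABBREVIATIONS):
            continue
        boundaries.append(m.end())
    boundaries.append(len(text))
    out = []
    for start, end in zip(boundaries, boundaries[1:]):
        sentence = text[start:end].strip()
        if sentence:
            out.append(sentence)
    return out


_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9_.-]*")


def _tokens(sentence: str) -> set:
    return set(_TOKEN_RE.findall(sentence))


class LexiconExtractor:
    """Deterministic whole-token gene-symbol matcher.

    Matches symbols from ``lexicon`` case-sensitively against the token set
    of each sentence (so "VEGFR" never matches a lexicon entry "EGFR").  If a
    ``drug_lexicon`` is supplied, drug names found in the same sentence
    (case-insensitive) are attached to the evidence record as annotation.
    """

    def __init__(self, lexicon: Iterable[str], drug_lexicon: Iterable[str] = ()):
        self.lexicon = set(lexicon)
        self.drug_lexicon = {d.lower(): d for d in drug_lexicon}

    def extract(self, record: AbstractRecord) -> list:
        out = []
        for sentence in split_sentences(record.abstract):
            toks = _tokens(sentence)
            genes = sorted(self.lexicon & toks)
            if not genes:
                continue
            drugs = tuple(
                sorted(
                    self.drug_lexicon[t]
                    for t in {tok.lower() for tok in toks}
                    if t in self.drug_lexicon
                )
            )
            for gene in genes:
                out.append((gene, sentence, drugs))
        return out


def clean_abstracts(
    records: Iterable, min_year: int = DEFAULT_MIN_YEAR
) -> tuple[list[AbstractRecord], Counter]:
    """Drop incomplete, outdated and duplicated abstract records.

    Removes records with a missing/empty abstract, a year before ``min_year``
    or unparseable, or a PMID already seen (first occurrence kept).  Returns
    the retained records and a Counter of drop reasons.
    """
    kept: list[AbstractRecord] = []
    seen: set = set()
    drops: Counter = Counter()
    for rec in records:
        if not isinstance(rec, AbstractRecord):
            rec = AbstractRecord(
                pmid=str(rec.get("pmid", "")),
                title=str(rec.get("title", "") or ""),
                year=rec.get("year"),
                abstract=str(rec.get("abstract", "") or ""),
            )
        if not rec.abstract or not rec.abstract.strip():
            drops["empty_abstract"] += 1
            continue
        try:
            year = int(rec.year)
        except (TypeError, ValueError):
            drops["bad_year"] += 1
            continue
        if year < min_year:
            drops["too_old"] += 1
            continue
        if rec.pmid in seen:
            drops["duplicate_pmid"] += 1
            continue
        seen.add(rec.pmid)
        kept.append(AbstractRecord(rec.pmid, rec.title, year, rec.abstract))
    return kept, drops


def extract_targets(
    records: Iterable[AbstractRecord],
    extractor: TargetExtractor,
    max_failure_fraction: float = 0.5,
) -> list[EvidenceRecord]:
    """Run the extraction backend over a cleaned corpus.

    Backend output violating the evidence invariants (sentence not found in
    the abstract, gene not a token of the sentence) is rejected and logged.
    A backend exception on one record skips that record; if more than
    ``max_failure_fraction`` of records fail, the run aborts.
    """
    records = list(records)
    evidence: list[EvidenceRecord] = []
    failures = 0
    rejected = 0
    for rec in records:
        try:
            hits = extractor.extract(rec)
        except Exception:  # backend failure on one record
            logger.exception("extractor failed on pmid %s", rec.pmid)
            failures += 1
            continue
        for gene, sentence, drugs in hits:
            if sentence not in rec.abstract or gene not in _tokens(sentence):
                rejected += 1
                continue
            evidence.append(EvidenceRecord(rec.pmid, gene, sentence, tuple(drugs)))
    if rejected:
        logger.warning("%d evidence records violated invariants and were dropped", rejected)
    if records and failures / len(records) > max_failure_fraction:
        raise RuntimeError(
            f"extractor failed on {failures}/{len(records)} records; aborting"
        )
    return evidence


def validate_genes(
    candidates: Iterable[str],
    evidence: Iterable[EvidenceRecord],
    min_articles: int = 1,
) -> ValidatedGeneSet:
    """Retain candidates supported by >= min_articles distinct articles."""
    candidates = set(candidates)
    support: dict = {}
    for ev in evidence:
        if ev.gene in candidates:
            support.setdefault(ev.gene, set()).add(ev.pmid)
    validated = {g for g, pmids in support.items() if len(pmids) >= min_articles}
    return ValidatedGeneSet(
        genes=validated,
        support={g: sorted(p) for g, p in support.items()},
        min_articles=min_articles,
    )


def read_abstracts_jsonl(path) -> list[dict]:
    """Read a JSONL abstract corpus (one object per line: pmid/title/year/abstract)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def evidence_to_frame(
    evidence: Iterable[EvidenceRecord], abstracts: Iterable[AbstractRecord] = ()
) -> pd.DataFrame:
    """Tabulate evidence with per-article metadata for manual review."""
    meta = {a.pmid: a for a in abstracts}
    rows = []
    for ev in evidence:
        a = meta.get(ev.pmid)
        rows.append(
            {
                "pmid": ev.pmid,
                "title": a.title if a else "",
                "year": a.year if a else "",
                "gene": ev.gene,
                "evidence_sentence": ev.evidence_sentence,
                "drugs": ";".join(ev.drugs),
            }
        )
    return pd.DataFrame(
        rows, columns=["pmid", "title", "year", "gene", "evidence_sentence", "drugs"]
    )


def fetch_pubmed_abstracts(
    query: str,
    email: str,
    api_key: str | None = None,
    retmax: int = 1000,
    batch_size: int = 200,
) -> list[dict]:
    """Thin NCBI E-utilities client for populating a corpus from PubMed.

    Requires network access and biopython; intended for real runs only (all
    shipped analyses and tests operate on local JSONL corpora).  Returns raw
    record dicts suitable for :func:`clean_abstracts`.
    """
    from Bio import Entrez, Medline  # lazy: optional dependency

    Entrez.email = email
    if api_key:
        Entrez.api_key = api_key
    with Entrez.esearch(db="pubmed", term=query, retmax=retmax) as handle:
        ids = Entrez.read(handle)["IdList"]
    records: list[dict] = []
    for start in range(0, len(ids), batch_size):
        chunk = ids[start : start + batch_size]
        with Entrez.efetch(
            db="pubmed", id=",".join(chunk), rettype="medline", retmode="text"
        ) as handle:
            for rec in Medline.parse(handle):
                year = (rec.get("DP", "") or "").split(" ")[0]
                records.append(
                    {
                        "pmid": rec.get("PMID", ""),
                        "title": rec.get("TI", ""),
                        "year": year,
                        "abstract": rec.get("AB", ""),
                    }
                )
    return records
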