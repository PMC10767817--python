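"""Raw sequence records and the record-level inclusion/exclusion filters.

Antibody sequence corpora are assembled from keyword queries over large
archives, so the first pipeline stage is defensive: keep entries whose text
mentions antibody vocabulary, drop single-domain (nanobody) entries that
cannot be told apart from unpaired humanised heavy chains, and drop entries
whose sequence length is implausible for one-to-a-few immunoglobulin
domains (shorter than 70 or longer than 1000 residues).

Records are read either from GenBank flat files (via Biopython) or from a
JSON-lines fixture format that mirrors :class:`RawRecord` field-for-field.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

VALID_SOURCE_TYPES = ("patent", "paper", "structure", "therapeutic")

#: Inclusion vocabulary used when harvesting antibody entries.
DEFAULT_INCLUDE_TERMS = ("antibody", "antibodies", "immunoglobulin", "scfv", "bcr")
#: Single-domain antibody vocabulary; such entries are excluded because a
#: humanised nanobody is indistinguishable from an unpaired human VH.
DEFAULT_EXCLUDE_TERMS = ("nanobody", "nanobodies")

MIN_LENGTH = 70
MAX_LENGTH = 1000

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class RawRecord:
    """One sequence entry with its metadata and source linkage.

    ``patent_sections``/``patent_paragraphs`` are only meaningful when
    ``source_type == "patent"``; ``seq_id`` is the explicit sequence-listing
    number (SEQ ID NO) when the source declares one.
    """

    record_id: str
    description: str
    sequence: str
    source_id: str
    source_type: str = "paper"
    source_title: str = ""
    organism: Optional[str] = None
    isolate: Optional[str] = None
    clone: Optional[str] = None
    patent_sections: Optional[dict[str, str]] = None
    patent_paragraphs: Optional[list[str]] = None
    seq_id: Optional[int] = None
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.source_type not in VALID_SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}")
        if self.source_type != "patent" and (
            self.patent_sections is not None or self.patent_paragraphs is not None
        ):
            raise ValueError("patent sections/paragraphs only allowed on patent records")

    def text_fields(self) -> list[str]:
        """All textual fields of the record, used by the keyword gates."""
        fields = [self.description, self.source_title]
        for opt in (self.organism, self.isolate, self.clone):
            if opt:
                fields.append(opt)
        if self.patent_sections:
            fields.extend(self.patent_sections.values())
        if self.patent_paragraphs:
            fields.extend(self.patent_paragraphs)
        return fields

    def has_valid_residues(self) -> bool:
        return bool(self.sequence) and set(self.sequence) <= _VALID_RESIDUES


@dataclass
class FilterReport:
    """Outcome of record-level filtering: a partition of the input set."""

    kept: list[RawRecord] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (record_id, reason)

    DROP_REASONS = ("too_long", "too_short", "nanobody_term", "no_keyword", "invalid_residues")

    @property
    def kept_ids(self) -> set[str]:
        return {r.record_id for r in self.kept}


class ParseError(Exception):
    """A single malformed entry; collected, not fatal for the whole file."""


def _tokens(text: str) -> set[str]:
    """Lowercased whole-word tokens: split on non-alphanumeric characters.

    'antibody-drug' therefore yields the token 'antibody', while
    'antibodylike' does not.
    """
    return set(re.split(r"[^a-z0-9]+", text.lower())) - {""}


def keyword_gate(
    record: RawRecord,
    include_terms: Iterable[str] = DEFAULT_INCLUDE_TERMS,
    exclude_terms: Iterable[str] = DEFAULT_EXCLUDE_TERMS,
) -> bool:
    """True iff some include term and no exclude term matches the record.

    Matching is case-insensitive whole-word over *all* text fields of the
    record (description, titles, patent sections and paragraphs), mirroring
    an any-field archive query.
    """
    include = {t.lower() for t in include_terms}
    exclude = {t.lower() for t in exclude_terms}
    if not include:
        raise ValueError("include_terms must be non-empty")
    toks: set[str] = set()
    for text in record.text_fields():
        toks |= _tokens(text)
    return bool(toks & include) and not (toks & exclude)


def length_filter(
    records: list[RawRecord], min_len: int = MIN_LENGTH, max_len: int = MAX_LENGTH
) -> FilterReport:
    """Drop records whose sequence is shorter than ``min_len`` or longer
    than ``max_len``; the boundary lengths themselves are kept."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    report = FilterReport()
    for rec in records:
        n = len(rec.sequence)
        if n < min_len:
            report.dropped.append((rec.record_id, "too_short"))
        elif n > max_len:
            report.dropped.append((rec.record_id, "too_long"))
        else:
            report.kept.append(rec)
    return report


def filter_records(
    records: list[RawRecord],
    include_terms: Iterable[str] = DEFAULT_INCLUDE_TERMS,
    exclude_terms: Iterable[str] = DEFAULT_EXCLUDE_TERMS,
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
) -> FilterReport:
    """Full record-level filter: residues, keyword/nanobody gates, length.

    Records failing the keyword gate are recorded with reason ``no_keyword``
    (or ``nanobody_term`` when an exclude term matched) rather than silently
    skipped, so the build log accounts for every input record.
    """
    report = FilterReport()
    exclude = {t.lower() for t in exclude_terms}
    for rec in records:
        if not rec.has_valid_residues():
            report.dropped.append((rec.record_id, "invalid_residues"))
            continue
        toks: set[str] = set()
        for text in rec.text_fields():
            toks |= _tokens(text)
        if toks & exclude:
            report.dropped.append((rec.record_id, "nanobody_term"))
            continue
        if not keyword_gate(rec, include_terms, exclude_terms):
            report.dropped.append((rec.record_id, "no_keyword"))
            continue
        n = len(rec.sequence)
        if n < min_len:
            report.dropped.append((rec.record_id, "too_short"))
        elif n > max_len:
            report.dropped.append((rec.record_id, "too_long"))
        else:
            report.kept.append(rec)
    return report


# ---------------------------------------------------------------------------
# Readers


_OPTIONAL_FIELDS = (
    "organism",
    "isolate",
    "clone",
    "patent_sections",
    "patent_paragraphs",
    "seq_id",
    "year",
)


def _record_from_dict(d: dict) -> RawRecord:
    missing = {"record_id", "description", "sequence", "source_id"} - set(d)
    if missing:
        raise ParseError(f"missing fields: {sorted(missing)}")
    kwargs = {
        "record_id": d["record_id"],
        "description": d["description"],
        "sequence": d["sequence"],
        "source_id": d["source_id"],
        "source_type": d.get("source_type", "paper"),
        "source_title": d.get("source_title", ""),
    }
    for f in _OPTIONAL_FIELDS:
        kwargs[f] = d.get(f)
    try:
        return RawRecord(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ParseError(str(exc)) from exc


def read_fixture(path: str | Path) -> tuple[list[RawRecord], list[str]]:
    """Read the JSON-lines fixture format (one RawRecord object per line).

    Returns (records, parse_errors); malformed lines are reported, the
    remaining entries are returned in file order.
    """
    records: list[RawRecord] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(_record_from_dict(json.loads(line)))
            except (json.JSONDecodeError, ParseError) as exc:
                errors.append(f"line {lineno}: {exc}")
    return records, errors


def write_fixture(records: list[RawRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            d = {k: v for k, v in rec.__dict__.items() if v is not None}
            fh.write(json.dumps(d, sort_keys=True) + "\n")


def read_genbank(path: str | Path) -> tuple[list[RawRecord], list[str]]:
    """Read a GenBank flat file of protein entries.

    Maps LOCUS/VERSION to ``record_id``, DEFINITION to ``description``, the
    first REFERENCE title to ``source_title`` and its journal (or the
    accession prefix) to ``source_id``, and the source-feature qualifiers
    ``organism``/``isolate``/``clone`` to the matching fields.
    """
    from Bio import SeqIO

    records: list[RawRecord] = []
    errors: list[str] = []
    for entry in SeqIO.parse(str(path), "genbank"):
        try:
            organism = entry.annotations.get("organism")
            isolate = clone = None
            for feat in entry.features:
                if feat.type == "source":
                    isolate = (feat.qualifiers.get("isolate") or [None])[0]
                    clone = (feat.qualifiers.get("clone") or [None])[0]
            title = ""
            source_id = entry.id.split(".")[0]
            refs = entry.annotations.get("references", [])
            if refs:
                title = refs[0].title or ""
                if refs[0].journal:
                    source_id = refs[0].journal
            year = None
            date = entry.annotations.get("date", "")
            m = re.search(r"(\d{4})", date)
            if m:
                year = int(m.group(1))
            records.append(
                RawRecord(
                    record_id=entry.id,
                    description=entry.description,
                    sequence=str(entry.seq).upper(),
                    source_id=source_id,
                    source_type="paper",
                    source_title=title,
                    organism=organism,
                    isolate=isolate,
                    clone=clone,
                    year=year,
                )
            )
        except Exception as exc:  # per-entry, never fatal for the file
            errors.append(f"{entry.id}: {exc}")
    return records, errors


def read_records(path: str | Path, format: str = "fixture") -> list[RawRecord]:
    """Read records from ``path`` in the named format (genbank | fixture).

    Per-entry parse errors are collected and attached to the returned list
    as the ``parse_errors`` attribute of :func:`read_records_report`; this
    convenience wrapper discards them.
    """
    records, _ = read_records_report(path, format)
    return records


def read_records_report(path: str | Path, format: str = "fixture") -> tuple[list[RawRecord], list[str]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fixture":
        return read_fixture(path)
    if format == "genbank":
        return read_genbank(path)
    raise ValueError(f"unknown format {format!r}")


class FetchAdapter:
    """Contract for a live archive client: query string in, records out.

    The build pipeline only ever consumes the iterator; implementations may
    stream from a remote archive. No network client ships with the package
    and none is used in tests — this is the seam where one would plug in.
    """

    def fetch(self, query: str) -> Iterable[RawRecord]:  # pragma: no cover - contract
        raise NotImplementedError
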