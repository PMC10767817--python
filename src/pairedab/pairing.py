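"""VH-VL pairing from shared-source metadata.

Single-chain antibody depositions rarely say outright which heavy chain
goes with which light chain, but their metadata usually does. Within each
literature/patent source, six heuristics are applied in a fixed cascade;
a domain consumed by an earlier heuristic is invisible to later ones:

1. ``same_entry``    — one VH and one VL inside a single record (scFv or a
   two-domain deposition) are paired.
2. ``unique_word``   — a corpus-wide uncommon word (present in the
   descriptions of fewer than ``rarity_threshold`` entries) that occurs in
   the description of exactly one VH and one VL pairs them.
3. ``unique_source`` — a unique VH and VL sharing an experimental-source
   tag (isolate, then clone) are paired.
4. ``patent_text``   — a patent paragraph citing one VH and one VL
   sequence ID pairs them; a paragraph citing equal numbers of VH and VL
   ids pairs them in mention order.
5. ``unique_chain``  — a lone remaining VH (or VL) in a source is paired
   with every remaining opposite-chain domain.
6. ``ordered_entries`` — equal remaining counts are paired in deposition
   order.

Methods 1-4 (and curated imports) are high-confidence; the two positional
fallbacks are not, and every pair carries its method flag so users can
filter on it.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from pairedab.numbering import (
    NumberedDomain,
    NumberingBackend,
    REGION_ORDER,
    assign_labels,
    cdr_completeness_filter,
    find_domains,
    needs_restoration,
)
from pairedab.records_io import RawRecord

logger = logging.getLogger(__name__)

PAIRING_METHODS = (
    "same_entry",
    "unique_word",
    "unique_source",
    "patent_text",
    "unique_chain",
    "ordered_entries",
    "imported_structure",
    "imported_therapeutic",
)

HIGH_CONFIDENCE_METHODS = frozenset(
    {"same_entry", "unique_word", "unique_source", "patent_text",
     "imported_structure", "imported_therapeutic"}
)

#: A word is "uncommon" when it appears in the descriptions of fewer than
#: this many entries of the unpaired corpus.
DEFAULT_RARITY_THRESHOLD = 20

#: Tokens too generic to ever identify a clone: shared by essentially every
#: antibody description.
STOP_WORDS = frozenset(
    {"chain", "heavy", "light", "variable", "region", "antibody", "immunoglobulin"}
)


def description_tokens(text: str) -> set[str]:
    """Tokens eligible for unique-word pairing: lowercase, split on
    non-alphanumerics, minus stop words and bare single digits."""
    raw = set(re.split(r"[^a-z0-9]+", text.lower())) - {""}
    return {t for t in raw if t not in STOP_WORDS and not (t.isdigit() and len(t) < 2)}


def word_document_frequency(records: Iterable[RawRecord]) -> Counter:
    """Entry-level document frequency of description tokens over the
    unpaired corpus (each record counts a token at most once)."""
    freq: Counter = Counter()
    for rec in records:
        freq.update(description_tokens(rec.description))
    return freq


@dataclass
class PairedEntry:
    """A VH-VL pair with its pairing provenance and annotations."""

    pair_id: str
    heavy: NumberedDomain
    light: NumberedDomain
    pairing_method: str
    source_id: str
    source_title: str = ""
    source_type: str = "paper"
    description: str = ""
    organism: Optional[str] = None
    year: Optional[int] = None
    targets_mentioned: list[str] = field(default_factory=list)
    restoration_needed_h: bool = False
    restoration_needed_l: bool = False

    def __post_init__(self) -> None:
        if self.pairing_method not in PAIRING_METHODS:
            raise ValueError(f"unknown pairing method {self.pairing_method!r}")
        if self.heavy.chain_type != "H" or self.light.chain_type != "L":
            raise ValueError("heavy/light chain types are swapped or invalid")

    @property
    def high_confidence(self) -> bool:
        return self.pairing_method in HIGH_CONFIDENCE_METHODS

    @property
    def sequence_pair(self) -> tuple[str, str]:
        return (self.heavy.sequence, self.light.sequence)


@dataclass
class PairingCandidatePool:
    """Unpaired domains of one source, plus the records they came from."""

    source_id: str
    heavies: list[NumberedDomain] = field(default_factory=list)
    lights: list[NumberedDomain] = field(default_factory=list)
    record_meta: dict[str, RawRecord] = field(default_factory=dict)

    def record_order(self, record_id: str) -> int:
        return list(self.record_meta).index(record_id)

    def domain_key(self, dom: NumberedDomain) -> tuple[int, int]:
        return (self.record_order(dom.parent_record_id), dom.domain_index)

    def remove(self, *domains: NumberedDomain) -> None:
        for dom in domains:
            if dom.chain_type == "H":
                self.heavies.remove(dom)
            else:
                self.lights.remove(dom)


def build_pools(
    records: list[RawRecord],
    backend: NumberingBackend,
    log: Optional[list[str]] = None,
) -> dict[str, PairingCandidatePool]:
    """Detect and annotate domains in filtered records, drop CDR-incomplete
    domains, and group the survivors into per-source candidate pools."""
    pools: dict[str, PairingCandidatePool] = {}
    for rec in records:
        domains = find_domains(rec, backend)
        kept, dropped = cdr_completeness_filter(domains)
        if log is not None:
            for rid in dropped:
                log.append(f"domain dropped (incomplete CDR): record {rid}")
        if not kept:
            continue
        pool = pools.setdefault(rec.source_id, PairingCandidatePool(source_id=rec.source_id))
        pool.record_meta[rec.record_id] = rec
        for dom in kept:
            (pool.heavies if dom.chain_type == "H" else pool.lights).append(dom)
    return pools


# ---------------------------------------------------------------------------
# Pair construction


def _make_entry(
    pool: PairingCandidatePool,
    heavy: NumberedDomain,
    light: NumberedDomain,
    method: str,
) -> PairedEntry:
    h_rec = pool.record_meta[heavy.parent_record_id]
    l_rec = pool.record_meta[light.parent_record_id]
    descs = [h_rec.description]
    if l_rec.record_id != h_rec.record_id:
        descs.append(l_rec.description)
    pair_id = (
        f"{pool.source_id}|{heavy.parent_record_id}.{heavy.domain_index}"
        f"|{light.parent_record_id}.{light.domain_index}"
    )
    return PairedEntry(
        pair_id=pair_id,
        heavy=heavy,
        light=light,
        pairing_method=method,
        source_id=pool.source_id,
        source_title=h_rec.source_title or l_rec.source_title,
        source_type=h_rec.source_type,
        description=" / ".join(descs),
        organism=h_rec.organism or l_rec.organism,
        year=h_rec.year or l_rec.year,
        restoration_needed_h=needs_restoration(heavy),
        restoration_needed_l=needs_restoration(light),
    )


# ---------------------------------------------------------------------------
# Heuristics 1-6. Each consumes the domains it pairs.


def pair_same_entry(pool: PairingCandidatePool) -> list[PairedEntry]:
    """Heuristic 1: a record holding exactly one VH and one VL pairs them."""
    pairs = []
    for record_id in list(pool.record_meta):
        hs = [d for d in pool.heavies if d.parent_record_id == record_id]
        ls = [d for d in pool.lights if d.parent_record_id == record_id]
        if len(hs) == 1 and len(ls) == 1:
            pairs.append(_make_entry(pool, hs[0], ls[0], "same_entry"))
            pool.remove(hs[0], ls[0])
    return pairs


def _resolve_proposals(
    pool: PairingCandidatePool,
    proposals: list[tuple[NumberedDomain, NumberedDomain]],
    method: str,
) -> list[PairedEntry]:
    """Discard conflicting proposals (a domain proposed two different
    partners is untrustworthy evidence), emit the rest deterministically."""
    partner: dict[tuple, set[tuple]] = {}
    for h, l in proposals:
        partner.setdefault(("H",) + pool.domain_key(h), set()).add(pool.domain_key(l))
        partner.setdefault(("L",) + pool.domain_key(l), set()).add(pool.domain_key(h))
    conflicted = {k for k, v in partner.items() if len(v) > 1}
    unique = {}
    for h, l in proposals:
        if ("H",) + pool.domain_key(h) in conflicted or ("L",) + pool.domain_key(l) in conflicted:
            continue
        unique[(pool.domain_key(h), pool.domain_key(l))] = (h, l)
    pairs = []
    for _, (h, l) in sorted(unique.items()):
        pairs.append(_make_entry(pool, h, l, method))
        pool.remove(h, l)
    return pairs


def pair_unique_word(
    pool: PairingCandidatePool,
    word_freq: Counter,
    rarity_threshold: int = DEFAULT_RARITY_THRESHOLD,
) -> list[PairedEntry]:
    """Heuristic 2: an uncommon description word shared by exactly one VH
    and one VL pairs them. Rarity is judged corpus-wide (``word_freq``)."""
    tokens_of = {
        rid: description_tokens(rec.description) for rid, rec in pool.record_meta.items()
    }
    candidate_words: set[str] = set()
    for dom in pool.heavies + pool.lights:
        candidate_words |= {
            w for w in tokens_of[dom.parent_record_id] if word_freq[w] < rarity_threshold
        }
    proposals = []
    for word in sorted(candidate_words):
        hs = [d for d in pool.heavies if word in tokens_of[d.parent_record_id]]
        ls = [d for d in pool.lights if word in tokens_of[d.parent_record_id]]
        if len(hs) == 1 and len(ls) == 1:
            proposals.append((hs[0], ls[0]))
    return _resolve_proposals(pool, proposals, "unique_word")


def pair_unique_source(pool: PairingCandidatePool) -> list[PairedEntry]:
    """Heuristic 3: a unique VH and VL sharing an isolate (then clone)
    value are paired; ambiguous shared values pair nothing."""
    pairs = []
    for attr in ("isolate", "clone"):
        value_of = {}
        for rid, rec in pool.record_meta.items():
            val = getattr(rec, attr)
            if val and val.strip():
                value_of[rid] = val.strip()
        proposals = []
        for value in sorted(set(value_of.values())):
            hs = [d for d in pool.heavies if value_of.get(d.parent_record_id) == value]
            ls = [d for d in pool.lights if value_of.get(d.parent_record_id) == value]
            if len(hs) == 1 and len(ls) == 1:
                proposals.append((hs[0], ls[0]))
        pairs.extend(_resolve_proposals(pool, proposals, "unique_source"))
    return pairs


_SEQ_ID_REF = re.compile(r"SEQ\s+ID\s+NOs?\s*[.:]?\s*(\d+)", re.IGNORECASE)
_SEQ_ID_ANY = re.compile(r"SEQ\s+ID\s+NO", re.IGNORECASE)


def _paragraph_seq_ids(paragraph: str) -> Optional[list[int]]:
    """Sequence-listing numbers cited in a paragraph, in mention order
    (first mention wins); None when a citation is unparseable."""
    well_formed = list(_SEQ_ID_REF.finditer(paragraph))
    if len(list(_SEQ_ID_ANY.finditer(paragraph))) != len(well_formed):
        return None
    ids = []
    for m in well_formed:
        n = int(m.group(1))
        if n not in ids:
            ids.append(n)
    return ids


def pair_patent_text(pool: PairingCandidatePool) -> list[PairedEntry]:
    """Heuristic 4: pair sequences cited together in a patent paragraph.

    A paragraph citing exactly one remaining VH and one remaining VL pairs
    them; a paragraph citing equal numbers of each pairs them in mention
    order. Paragraphs with unparseable citations are skipped and logged.
    Records are addressed by their explicit SEQ ID NO when present, else by
    their 1-based deposition index within the source.
    """
    records = list(pool.record_meta.values())
    if not records or records[0].source_type != "patent":
        return []
    paragraphs: list[str] = []
    for rec in records:
        if rec.patent_paragraphs:
            paragraphs = rec.patent_paragraphs
            break
    seq_id_to_record = {}
    for idx, rec in enumerate(records, start=1):
        seq_id_to_record[rec.seq_id if rec.seq_id is not None else idx] = rec.record_id
    pairs = []
    for paragraph in paragraphs:
        ids = _paragraph_seq_ids(paragraph)
        if ids is None:
            logger.warning(
                "patent %s: unparseable sequence-ID reference, paragraph skipped", pool.source_id
            )
            continue
        cited = [seq_id_to_record[i] for i in ids if i in seq_id_to_record]
        hs = [d for rid in cited for d in pool.heavies if d.parent_record_id == rid]
        ls = [d for rid in cited for d in pool.lights if d.parent_record_id == rid]
        if len(hs) == len(ls) and hs:
            for h, l in zip(hs, ls):
                pairs.append(_make_entry(pool, h, l, "patent_text"))
                pool.remove(h, l)
    return pairs


def pair_unique_chain(pool: PairingCandidatePool) -> list[PairedEntry]:
    """Heuristic 5 (low confidence): a lone remaining VH (or VL) is paired
    with every remaining opposite-chain domain of the source."""
    pairs = []
    if len(pool.heavies) == 1 and pool.lights:
        h = pool.heavies[0]
        for l in sorted(pool.lights, key=pool.domain_key):
            pairs.append(_make_entry(pool, h, l, "unique_chain"))
        pool.heavies.clear()
        pool.lights.clear()
    elif len(pool.lights) == 1 and pool.heavies:
        l = pool.lights[0]
        for h in sorted(pool.heavies, key=pool.domain_key):
            pairs.append(_make_entry(pool, h, l, "unique_chain"))
        pool.heavies.clear()
        pool.lights.clear()
    return pairs


def pair_ordered(pool: PairingCandidatePool) -> list[PairedEntry]:
    """Heuristic 6 (low confidence): equal remaining VH and VL counts are
    paired in deposition order."""
    if not pool.heavies or len(pool.heavies) != len(pool.lights):
        return []
    hs = sorted(pool.heavies, key=pool.domain_key)
    ls = sorted(pool.lights, key=pool.domain_key)
    pairs = [_make_entry(pool, h, l, "ordered_entries") for h, l in zip(hs, ls)]
    pool.heavies.clear()
    pool.lights.clear()
    return pairs


def run_pairing_cascade(
    pools: dict[str, PairingCandidatePool],
    rarity_threshold: int = DEFAULT_RARITY_THRESHOLD,
    word_freq: Optional[Counter] = None,
) -> tuple[list[PairedEntry], list[tuple[str, int]]]:
    """Apply heuristics 1-6 in order to every source pool.

    Returns (pairs, unpaired domain identifiers). ``word_freq`` defaults to
    the document frequency over all records present in the pools — i.e.
    rarity is judged against the whole unpaired corpus, not per source.
    """
    if word_freq is None:
        all_records = [rec for pool in pools.values() for rec in pool.record_meta.values()]
        word_freq = word_document_frequency(all_records)
    pairs: list[PairedEntry] = []
    unpaired: list[tuple[str, int]] = []
    for source_id in sorted(pools):
        pool = pools[source_id]
        pairs.extend(pair_same_entry(pool))
        pairs.extend(pair_unique_word(pool, word_freq, rarity_threshold))
        pairs.extend(pair_unique_source(pool))
        pairs.extend(pair_patent_text(pool))
        pairs.extend(pair_unique_chain(pool))
        pairs.extend(pair_ordered(pool))
        for dom in pool.heavies + pool.lights:
            unpaired.append((dom.parent_record_id, dom.domain_index))
    return pairs, unpaired


# ---------------------------------------------------------------------------
# Tabular round-trip (shared with the database module)


ENTRY_COLUMNS = (
    ["pair_id", "pairing_method", "high_confidence", "source_id", "source_type",
     "source_title", "description", "organism", "year", "targets_mentioned",
     "restoration_needed_h", "restoration_needed_l",
     "n_term_missing_h", "n_term_missing_l", "light_class",
     "heavy_sequence", "light_sequence"]
    + [f"heavy_{r.lower()}" for r in REGION_ORDER]
    + [f"light_{r.lower()}" for r in REGION_ORDER]
)


def entry_to_row(entry: PairedEntry) -> dict:
    row = {
        "pair_id": entry.pair_id,
        "pairing_method": entry.pairing_method,
        "high_confidence": entry.high_confidence,
        "source_id": entry.source_id,
        "source_type": entry.source_type,
        "source_title": entry.source_title,
        "description": entry.description,
        "organism": entry.organism or "",
        "year": entry.year if entry.year is not None else "",
        "targets_mentioned": ";".join(entry.targets_mentioned),
        "restoration_needed_h": entry.restoration_needed_h,
        "restoration_needed_l": entry.restoration_needed_l,
        "n_term_missing_h": entry.heavy.n_terminal_missing,
        "n_term_missing_l": entry.light.n_terminal_missing,
        "light_class": entry.light.light_class or "",
        "heavy_sequence": entry.heavy.sequence,
        "light_sequence": entry.light.sequence,
    }
    for region in REGION_ORDER:
        row[f"heavy_{region.lower()}"] = entry.heavy.region_sequence(region)
        row[f"light_{region.lower()}"] = entry.light.region_sequence(region)
    return row


def domain_from_regions(
    chain_type: str,
    region_seqs: dict[str, str],
    n_terminal_missing: int = 0,
    parent_record_id: str = "",
    light_class: Optional[str] = None,
) -> NumberedDomain:
    """Rebuild a numbered domain from per-region sequences; FR1 labels are
    shifted by the recorded N-terminal deficit."""
    positions = assign_labels(region_seqs)
    if n_terminal_missing:
        positions = [
            (lab + n_terminal_missing, aa) if lab <= 26 else (lab, aa) for lab, aa in positions
        ]
    return NumberedDomain(
        parent_record_id=parent_record_id,
        chain_type=chain_type,
        positions=positions,
        n_terminal_missing=n_terminal_missing,
        light_class=light_class,
    )


def entry_from_row(row: dict) -> PairedEntry:
    def _regions(prefix: str) -> dict[str, str]:
        return {r: str(row.get(f"{prefix}_{r.lower()}", "") or "") for r in REGION_ORDER}

    def _int(v, default=0):
        try:
            return int(v)
        except (TypeError, ValueError):
            return default

    heavy = domain_from_regions(
        "H", _regions("heavy"), _int(row.get("n_term_missing_h")), row["pair_id"] + ":H"
    )
    light = domain_from_regions(
        "L",
        _regions("light"),
        _int(row.get("n_term_missing_l")),
        row["pair_id"] + ":L",
        light_class=str(row.get("light_class") or "") or None,
    )
    targets = [t for t in str(row.get("targets_mentioned", "") or "").split(";") if t]
    year_raw = row.get("year")
    year = _int(year_raw, None) if year_raw not in ("", None) else None

    def _bool(v) -> bool:
        return str(v).strip().lower() in ("true", "1")

    return PairedEntry(
        pair_id=row["pair_id"],
        heavy=heavy,
        light=light,
        pairing_method=row["pairing_method"],
        source_id=row["source_id"],
        source_title=str(row.get("source_title", "") or ""),
        source_type=str(row.get("source_type", "paper") or "paper"),
        description=str(row.get("description", "") or ""),
        organism=str(row.get("organism") or "") or None,
        year=year,
        targets_mentioned=targets,
        restoration_needed_h=_bool(row.get("restoration_needed_h")),
        restoration_needed_l=_bool(row.get("restoration_needed_l")),
    )


def import_external_pairs(path: str | Path, kind: str) -> list[PairedEntry]:
    """Import externally curated pairs from TSV.

    ``kind`` is ``structure`` or ``therapeutic``; entries get the matching
    ``imported_*`` method flag (high confidence). The TSV must carry
    ``pair_id``, ``source_id`` and the per-region heavy/light columns of
    :data:`ENTRY_COLUMNS`.
    """
    import pandas as pd

    if kind not in ("structure", "therapeutic"):
        raise ValueError("kind must be 'structure' or 'therapeutic'")
    method = f"imported_{kind}"
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = []
    for _, row in df.iterrows():
        d = row.to_dict()
        d["pairing_method"] = method
        d.setdefault("source_type", kind)
        if not d.get("source_type"):
            d["source_type"] = kind
        entries.append(entry_from_row(d))
    return entries
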