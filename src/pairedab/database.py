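"""The persistent paired-antibody database.

Storage is deliberately low-tech: one TSV row per paired entry (the column
set is :data:`pairedab.pairing.ENTRY_COLUMNS`) plus a JSON sidecar holding
the version string and the build log. The table is human-greppable and
diff-friendly, and rebuilding it from the same inputs is byte-identical.

Distinct entries may share the same (VH, VL) sequence pair — the same
antibody described by several sources — so the database keeps a unique
index from sequence pair to entry ids; downstream consumers (e.g. the
structural modelling step) use it to handle each unique antibody once.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from pairedab.pairing import ENTRY_COLUMNS, PairedEntry, entry_from_row, entry_to_row

SEARCHABLE_FIELDS = ("source_title", "description", "targets_mentioned")


@dataclass
class PairedDatabase:
    """All paired entries plus the unique (VH, VL) sequence index."""

    entries: list[PairedEntry] = field(default_factory=list)
    version: str = "0"
    build_log: list[str] = field(default_factory=list)

    @property
    def unique_index(self) -> dict[tuple[str, str], list[str]]:
        index: dict[tuple[str, str], list[str]] = {}
        for entry in self.entries:
            index.setdefault(entry.sequence_pair, []).append(entry.pair_id)
        return index

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def n_unique(self) -> int:
        return len(self.unique_index)

    def get(self, pair_id: str) -> Optional[PairedEntry]:
        for entry in self.entries:
            if entry.pair_id == pair_id:
                return entry
        return None

    def unique_entries(self) -> list[PairedEntry]:
        """One representative entry (lowest pair_id) per unique sequence pair."""
        best: dict[tuple[str, str], PairedEntry] = {}
        for entry in self.entries:
            cur = best.get(entry.sequence_pair)
            if cur is None or entry.pair_id < cur.pair_id:
                best[entry.sequence_pair] = entry
        return sorted(best.values(), key=lambda e: e.pair_id)


def upsert(db: PairedDatabase, new_entries: list[PairedEntry]) -> PairedDatabase:
    """Insert-or-replace entries by ``pair_id``; idempotent.

    A batch containing the same pair_id twice with different content is
    rejected outright (it cannot have a deterministic outcome).
    """
    by_id: dict[str, PairedEntry] = {}
    for entry in new_entries:
        prev = by_id.get(entry.pair_id)
        if prev is not None and entry_to_row(prev) != entry_to_row(entry):
            raise ValueError(
                f"batch contains conflicting duplicates of pair_id {entry.pair_id!r}"
            )
        by_id[entry.pair_id] = entry
    merged: dict[str, PairedEntry] = {e.pair_id: e for e in db.entries}
    merged.update(by_id)
    out = PairedDatabase(
        entries=sorted(merged.values(), key=lambda e: e.pair_id),
        version=db.version,
        build_log=list(db.build_log),
    )
    out.build_log.append(f"upsert: {len(by_id)} entries (database now {len(out.entries)})")
    return out


def regex_search(db: PairedDatabase, field_name: str, pattern: str) -> list[PairedEntry]:
    """Case-insensitive regex search over one metadata field.

    ``field_name`` is one of ``source_title``, ``description`` or
    ``targets_mentioned`` (the last matched against each target name).
    Results are ordered by entry id.
    """
    if field_name not in SEARCHABLE_FIELDS:
        raise ValueError(f"field must be one of {SEARCHABLE_FIELDS}")
    try:
        rx = re.compile(pattern, re.IGNORECASE)
    except re.error as exc:
        raise ValueError(f"invalid regular expression {pattern!r}: {exc}") from exc
    hits = []
    for entry in db.entries:
        if field_name == "targets_mentioned":
            matched = any(rx.search(t) for t in entry.targets_mentioned)
        else:
            matched = rx.search(getattr(entry, field_name)) is not None
        if matched:
            hits.append(entry)
    return sorted(hits, key=lambda e: e.pair_id)


def summarize(db: PairedDatabase) -> dict:
    """Database summary statistics.

    Counts by source type, by species (organism merged case-insensitively,
    absent organisms bucketed as 'unannotated') and by year, plus the
    CDR-H3 length histogram (occupied heavy-chain CDR3 positions) and its
    mean.
    """
    by_source_type = Counter(e.source_type for e in db.entries)
    species: Counter = Counter()
    for e in db.entries:
        species[e.organism.strip().casefold() if e.organism else "unannotated"] += 1
    by_year = Counter(e.year for e in db.entries if e.year is not None)
    h3_lengths = [e.heavy.cdr_lengths()[2] for e in db.entries]
    histogram = Counter(h3_lengths)
    return {
        "n_entries": db.n_entries,
        "n_unique": db.n_unique,
        "by_source_type": dict(sorted(by_source_type.items())),
        "by_species": dict(sorted(species.items())),
        "by_year": dict(sorted(by_year.items())),
        "cdr_h3_length_histogram": dict(sorted(histogram.items())),
        "cdr_h3_length_mean": (sum(h3_lengths) / len(h3_lengths)) if h3_lengths else None,
    }


# ---------------------------------------------------------------------------
# Persistence


def to_frame(db: PairedDatabase) -> pd.DataFrame:
    rows = [entry_to_row(e) for e in sorted(db.entries, key=lambda e: e.pair_id)]
    return pd.DataFrame(rows, columns=ENTRY_COLUMNS)


def save(db: PairedDatabase, tsv_path: str | Path) -> None:
    """Write the TSV table and its JSON sidecar (<name>.meta.json)."""
    tsv_path = Path(tsv_path)
    to_frame(db).to_csv(tsv_path, sep="\t", index=False)
    sidecar = tsv_path.with_suffix(tsv_path.suffix + ".meta.json")
    with open(sidecar, "w") as fh:
        json.dump({"version": db.version, "build_log": db.build_log}, fh, indent=1)
        fh.write("\n")


def load(tsv_path: str | Path) -> PairedDatabase:
    tsv_path = Path(tsv_path)
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    entries = [entry_from_row(row.to_dict()) for _, row in df.iterrows()]
    version, build_log = "0", []
    sidecar = tsv_path.with_suffix(tsv_path.suffix + ".meta.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
        version = meta.get("version", "0")
        build_log = meta.get("build_log", [])
    return PairedDatabase(entries=entries, version=version, build_log=build_log)


def export_fasta(
    db: PairedDatabase, path: str | Path, chains: str = "both", unique: bool = False
) -> int:
    """Export sequences as FASTA; ``chains`` is H, L or both (concatenated
    VH then VL, '/'-separated header note). Returns the number of records
    written."""
    entries = db.unique_entries() if unique else sorted(db.entries, key=lambda e: e.pair_id)
    n = 0
    with open(path, "w") as fh:
        for entry in entries:
            if chains == "H":
                fh.write(f">{entry.pair_id}|VH\n{entry.heavy.sequence}\n")
            elif chains == "L":
                fh.write(f">{entry.pair_id}|VL\n{entry.light.sequence}\n")
            elif chains == "both":
                fh.write(f">{entry.pair_id}|VH/VL\n{entry.heavy.sequence}{entry.light.sequence}\n")
            else:
                raise ValueError("chains must be H, L or both")
            n += 1
    return n
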