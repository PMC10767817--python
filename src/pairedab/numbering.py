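"""Variable-domain detection, canonical numbering and region annotation.

A variable domain is annotated with an IMGT-like integer numbering in which
every position label falls in exactly one of the seven regions:

======  ===========  ========
region  label range  capacity
======  ===========  ========
FR1     1-26         26
CDR1    27-38        12
FR2     39-55        17
CDR2    56-65        10
FR3     66-104       39
CDR3    105-117      13
FR4     118-128      11
======  ===========  ========

Framework labels are assigned contiguously (FR1, FR2 and FR4 from the start
of their range, FR3 end-aligned so the conserved cysteine preceding CDR3
sits at 104); CDR labels are assigned from both ends of the range toward
the middle, so loops of different lengths stay aligned at their anchors.
Insertion codes are not supported: loops longer than a region's capacity
are rejected.

Numbering itself is delegated to a pluggable backend. The package ships a
deterministic lookup-table backend (:class:`FixtureNumberingBackend`) that
annotates sequences registered with it — including as substrings of longer
records, which is how multi-domain scFv entries are handled — plus a thin
adapter for an external HMM-based numbering tool when one is installed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from pairedab.records_io import RawRecord

logger = logging.getLogger(__name__)

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

REGION_BOUNDS = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),
}

CDR_REGIONS = ("CDR1", "CDR2", "CDR3")

#: Entries missing more than this many leading framework residues are
#: flagged as needing N-terminal restoration before structural modelling.
RESTORATION_DEFICIT_THRESHOLD = 8


def region_of(label: int) -> str:
    """Region name for an integer position label."""
    for region, (lo, hi) in REGION_BOUNDS.items():
        if lo <= label <= hi:
            return region
    raise ValueError(f"label {label} outside the numbering range 1-128")


def cdr_labels(region: str, length: int) -> list[int]:
    """Canonical label set for a CDR of the given length.

    Labels fill from both ends of the region range toward the middle
    (front-heavy for odd lengths), the convention that keeps the loop
    anchors aligned across lengths.
    """
    lo, hi = REGION_BOUNDS[region]
    capacity = hi - lo + 1
    if not 0 <= length <= capacity:
        raise ValueError(f"{region} length {length} exceeds capacity {capacity}")
    n_front = math.ceil(length / 2)
    n_back = length - n_front
    return list(range(lo, lo + n_front)) + list(range(hi - n_back + 1, hi + 1))


def framework_labels(region: str, length: int) -> list[int]:
    """Canonical label set for a framework segment of the given length."""
    lo, hi = REGION_BOUNDS[region]
    capacity = hi - lo + 1
    if not 0 <= length <= capacity:
        raise ValueError(f"{region} length {length} exceeds capacity {capacity}")
    if region == "FR3":  # end-aligned: conserved Cys at 104
        return list(range(hi - length + 1, hi + 1))
    return list(range(lo, lo + length))


def assign_labels(region_seqs: dict[str, str]) -> list[tuple[int, str]]:
    """Number a full domain given its per-region sequences."""
    positions: list[tuple[int, str]] = []
    for region in REGION_ORDER:
        seq = region_seqs.get(region, "")
        labels = (
            cdr_labels(region, len(seq)) if region in CDR_REGIONS else framework_labels(region, len(seq))
        )
        positions.extend(zip(labels, seq))
    return positions


@dataclass
class NumberedDomain:
    """A detected variable domain with per-position numbering.

    ``positions`` is the ordered list of (integer label, residue);
    ``chain_type`` is H or L (L covers both kappa and lambda — the fine
    light-chain class, when known, lives in ``light_class``).
    """

    parent_record_id: str
    chain_type: str
    positions: list[tuple[int, str]]
    scheme: str = "imgt-like"
    n_terminal_missing: int = 0
    light_class: Optional[str] = None
    domain_index: int = 0  # N->C index of this domain within its record

    def __post_init__(self) -> None:
        if self.chain_type not in ("H", "L"):
            raise ValueError("chain_type must be H or L")
        labels = [lab for lab, _ in self.positions]
        if labels != sorted(labels) or len(set(labels)) != len(labels):
            raise ValueError("position labels must be strictly increasing")

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.positions)

    @property
    def region_spans(self) -> dict[str, list[int]]:
        spans: dict[str, list[int]] = {r: [] for r in REGION_ORDER}
        for lab, _ in self.positions:
            spans[region_of(lab)].append(lab)
        return spans

    def region_sequence(self, region: str) -> str:
        return "".join(aa for lab, aa in self.positions if region_of(lab) == region)

    def residue_map(self) -> dict[int, str]:
        return dict(self.positions)

    def cdr_lengths(self) -> tuple[int, int, int]:
        spans = self.region_spans
        return tuple(len(spans[r]) for r in CDR_REGIONS)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Template domains
#
# Germline-like human VH (IGHV3-23/IGHJ4-like) and V-kappa (IGKV1-39/IGKJ1-
# like) scaffolds. Fixture corpora derive their domains from these by
# substitution and CDR3 replacement, so every synthetic sequence can be
# annotated offline by the lookup backend.

VH_TEMPLATE_REGIONS = {
    "FR1": "EVQLLESGGGLVQPGGSLRLSCAAS",
    "CDR1": "GFTFSSYA",
    "FR2": "MSWVRQAPGKGLEWVSA",
    "CDR2": "ISGSGGST",
    "FR3": "YYADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYC",
    "CDR3": "AKDRGYSSGYFDY",
    "FR4": "WGQGTLVTVSS",
}

VL_TEMPLATE_REGIONS = {
    "FR1": "DIQMTQSPSSLSASVGDRVTITCRAS",
    "CDR1": "QSISSY",
    "FR2": "LNWYQQKPGKAPKLLIY",
    "CDR2": "AAS",
    "FR3": "SLQSGVPSRFSGSGSGTDFTLTISSLQPEDFATYYC",
    "CDR3": "QQSYSTPPT",
    "FR4": "FGQGTKVEIK",
}


# ---------------------------------------------------------------------------
# Backends


class NumberingBackend:
    """Contract: deterministically locate and number variable domains.

    ``number(sequence)`` returns, in N->C order, tuples of
    (start offset in the parent sequence, chain type, positions,
    n_terminal_missing, light_class).
    """

    name = "abstract"
    scheme = "imgt-like"

    def number(
        self, sequence: str
    ) -> list[tuple[int, str, list[tuple[int, str]], int, Optional[str]]]:
        raise NotImplementedError


class FixtureNumberingBackend(NumberingBackend):
    """Lookup-table backend: annotates exactly the sequences registered
    with it, found as substrings of a record sequence.

    Registration is how synthetic corpora stay annotatable offline: the
    corpus generator registers every domain it plants. Matching prefers
    longer registered sequences and never overlaps matches; a sequence
    containing no registered domain yields an empty list.
    """

    name = "fixture"

    def __init__(self) -> None:
        self._table: dict[str, tuple[str, tuple[tuple[int, str], ...], int, Optional[str]]] = {}

    def register(
        self,
        chain_type: str,
        positions: Sequence[tuple[int, str]],
        n_terminal_missing: int = 0,
        light_class: Optional[str] = None,
    ) -> str:
        positions = tuple(positions)
        seq = "".join(aa for _, aa in positions)
        self._table[seq] = (chain_type, positions, n_terminal_missing, light_class)
        return seq

    def register_regions(
        self,
        chain_type: str,
        region_seqs: dict[str, str],
        truncate_n: int = 0,
        light_class: Optional[str] = None,
    ) -> str:
        """Register a domain given per-region sequences, optionally with its
        first ``truncate_n`` residues removed (an N-terminally incomplete
        deposition)."""
        positions = assign_labels(region_seqs)[truncate_n:]
        return self.register(chain_type, positions, truncate_n, light_class)

    def __len__(self) -> int:
        return len(self._table)

    def save(self, path: str | Path) -> None:
        """Persist the lookup table as JSON so a generated corpus can be
        re-numbered in a later process."""
        import json

        payload = {
            seq: {
                "chain_type": chain,
                "positions": [[lab, aa] for lab, aa in positions],
                "n_terminal_missing": n_missing,
                "light_class": light_class,
            }
            for seq, (chain, positions, n_missing, light_class) in sorted(self._table.items())
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=0, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "FixtureNumberingBackend":
        import json

        backend = cls()
        with open(path) as fh:
            payload = json.load(fh)
        for entry in payload.values():
            backend.register(
                entry["chain_type"],
                [(int(lab), aa) for lab, aa in entry["positions"]],
                entry.get("n_terminal_missing", 0),
                entry.get("light_class"),
            )
        return backend

    def number(self, sequence: str):
        hits: list[tuple[int, str]] = []  # (start, registered seq)
        taken: list[tuple[int, int]] = []
        for seq in sorted(self._table, key=len, reverse=True):
            start = 0
            while True:
                idx = sequence.find(seq, start)
                if idx < 0:
                    break
                span = (idx, idx + len(seq))
                if all(span[1] <= s or span[0] >= e for s, e in taken):
                    hits.append((idx, seq))
                    taken.append(span)
                start = idx + 1
        out = []
        for start, seq in sorted(hits):
            chain, positions, n_missing, light_class = self._table[seq]
            out.append((start, chain, list(positions), n_missing, light_class))
        return out


class AnarciBackend(NumberingBackend):  # pragma: no cover - needs external tool
    """Adapter to an external HMM-based antibody numbering tool.

    Only usable when the ``anarci`` package is installed; the pipeline and
    the test suite run entirely on the fixture backend.
    """

    name = "anarci"

    def __init__(self, scheme: str = "imgt"):
        import anarci  # noqa: F401 — deliberate import-time check

        self._anarci = anarci
        self.scheme = scheme

    def number(self, sequence: str):
        numbered, details, _ = self._anarci.anarci(
            [("query", sequence)], scheme=self.scheme, output=False
        )
        out = []
        if not numbered or numbered[0] is None:
            return out
        for dom, det in zip(numbered[0], details[0]):
            positions = [
                (pos, aa) for (pos, ins), aa in dom[0] if aa != "-" and ins == " "
            ]
            chain = det["chain_type"]
            light_class = None
            if chain in ("K", "L"):
                light_class = "kappa" if chain == "K" else "lambda"
                chain = "L"
            deficit = positions[0][0] - 1 if positions else 0
            out.append((det["query_start"], chain, positions, deficit, light_class))
        return out


# ---------------------------------------------------------------------------
# Operations


def find_domains(record: RawRecord, backend: NumberingBackend) -> list[NumberedDomain]:
    """Detect and annotate all variable domains in a record, N->C order.

    A backend failure contributes no domains for this record and is logged;
    a non-antibody sequence simply yields an empty list.
    """
    try:
        raw = backend.number(record.sequence)
    except Exception as exc:
        logger.warning("numbering backend %s failed on %s: %s", backend.name, record.record_id, exc)
        return []
    domains = []
    for idx, (_, chain, positions, n_missing, light_class) in enumerate(raw):
        domains.append(
            NumberedDomain(
                parent_record_id=record.record_id,
                chain_type=chain,
                positions=positions,
                scheme=backend.scheme,
                n_terminal_missing=n_missing,
                light_class=light_class,
                domain_index=idx,
            )
        )
    return domains


def cdr_complete(domain: NumberedDomain) -> bool:
    """True iff all three CDR spans are non-empty and internally complete.

    A CDR is complete when its observed labels are exactly the canonical
    label set for its own length — natural length variation passes, but an
    interior deletion leaves a label set no loop length could produce.
    """
    spans = domain.region_spans
    for region in CDR_REGIONS:
        labels = spans[region]
        if not labels:
            return False
        if labels != cdr_labels(region, len(labels)):
            return False
    return True


def cdr_completeness_filter(
    domains: list[NumberedDomain],
) -> tuple[list[NumberedDomain], list[str]]:
    """Split domains into (kept, dropped parent-record ids) on CDR
    completeness; incompletely sequenced CDRs disqualify a domain."""
    kept, dropped = [], []
    for dom in domains:
        if cdr_complete(dom):
            kept.append(dom)
        else:
            dropped.append(dom.parent_record_id)
    return kept, dropped


def n_terminal_deficit(domain: NumberedDomain) -> int:
    """Number of expected leading framework positions absent before the
    first observed residue (0 for a complete FR1)."""
    if not domain.positions:
        return 0
    return domain.positions[0][0] - 1


def needs_restoration(domain: NumberedDomain) -> bool:
    """True when the domain is missing more than eight residues at the
    start and should be flagged for N-terminal restoration downstream."""
    return n_terminal_deficit(domain) > RESTORATION_DEFICIT_THRESHOLD


# ---------------------------------------------------------------------------
# Writers


def write_domains_fasta(domains: list[NumberedDomain], path: str | Path) -> None:
    with open(path, "w") as fh:
        for dom in domains:
            fh.write(f">{dom.parent_record_id}|{dom.chain_type}|{dom.domain_index}\n")
            fh.write(dom.sequence + "\n")


def write_domains_tsv(domains: list[NumberedDomain], path: str | Path) -> None:
    """One row per domain: parent id, chain type, region sequences."""
    cols = ["parent_record_id", "chain_type", "n_terminal_missing"] + list(REGION_ORDER)
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for dom in domains:
            row = [dom.parent_record_id, dom.chain_type, str(dom.n_terminal_missing)]
            row += [dom.region_sequence(r) for r in REGION_ORDER]
            fh.write("\t".join(row) + "\n")
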