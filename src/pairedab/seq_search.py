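"""Exhaustive region-restricted sequence-identity search.

Because every domain is numbered under the same scheme, two sequences are
already aligned position-by-position: identity over any region is simply
the fraction of matching residues at the selected labels, with no pairwise
alignment step. The searchable regions are the full variable domain, all
six CDRs, CDR-H3 alone, or an arbitrary user-defined set of (chain,
label) positions.

Identity convention: the denominator is the number of selected positions
occupied in *either* sequence, so a position present in only one of the
two counts as a mismatch — length differences penalise identity.

The search itself is an exhaustive scan of the database: every entry is
scored, making the hit set trivially equal to its definition
``{e : identity(q, e) > t}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from pairedab.database import PairedDatabase
from pairedab.numbering import CDR_REGIONS, NumberedDomain, region_of
from pairedab.pairing import PairedEntry

REGION_NAMES = ("full_variable", "all_cdrs", "cdr_h3", "user_defined")


@dataclass(frozen=True)
class RegionSelector:
    """Which numbered positions identity is computed over."""

    name: str = "full_variable"
    custom_positions: Optional[tuple[tuple[str, int], ...]] = None

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise ValueError(f"unknown region {self.name!r}")
        if (self.name == "user_defined") != (self.custom_positions is not None):
            raise ValueError("custom_positions required iff name == 'user_defined'")

    def selects(self, chain: str, label: int) -> bool:
        if self.name == "full_variable":
            return True
        if self.name == "all_cdrs":
            return region_of(label) in CDR_REGIONS
        if self.name == "cdr_h3":
            return chain == "H" and region_of(label) == "CDR3"
        return (chain, label) in self.custom_positions  # type: ignore[operator]


FULL_VARIABLE = RegionSelector("full_variable")
ALL_CDRS = RegionSelector("all_cdrs")
CDR_H3 = RegionSelector("cdr_h3")


@dataclass(frozen=True)
class SeqHit:
    entry_id: str
    identity: float
    region: RegionSelector
    chains_used: str  # H, L or both

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must lie in [0, 1]")


def _chain_identity(
    query: NumberedDomain, target: NumberedDomain, region: RegionSelector, chain: str
) -> tuple[int, int]:
    """(matches, occupied-in-either) over selected positions of one chain."""
    q = {lab: aa for lab, aa in query.positions if region.selects(chain, lab)}
    t = {lab: aa for lab, aa in target.positions if region.selects(chain, lab)}
    union = set(q) | set(t)
    matches = sum(1 for lab in q if t.get(lab) == q[lab])
    return matches, len(union)


def region_identity(
    query: dict[str, NumberedDomain],
    target: dict[str, NumberedDomain],
    region: RegionSelector = FULL_VARIABLE,
    chains_used: str = "H",
) -> float:
    """Fraction of selected numbered positions with identical residues.

    ``query``/``target`` map chain type (H/L) to a numbered domain; for
    ``chains_used='both'`` the identity is computed over the union of the
    selected positions of both chains.
    """
    chains = ("H", "L") if chains_used == "both" else (chains_used,)
    matches = occupied = 0
    for chain in chains:
        if chain not in query or chain not in target:
            continue
        m, n = _chain_identity(query[chain], target[chain], region, chain)
        matches += m
        occupied += n
    if occupied == 0:
        raise ValueError("selected region is empty in both sequences")
    return matches / occupied


def _entry_chains(entry: PairedEntry) -> dict[str, NumberedDomain]:
    return {"H": entry.heavy, "L": entry.light}


def search_by_identity(
    db: PairedDatabase,
    query: dict[str, NumberedDomain],
    region: RegionSelector = FULL_VARIABLE,
    threshold: float = 0.9,
    chains_used: str = "H",
    strict: bool = True,
    unique: bool = False,
) -> list[SeqHit]:
    """Exhaustive identity search over the database.

    For ``chains_used='both'``, each chain must individually exceed the
    threshold and the reported identity is the smaller (limiting) one.
    ``strict`` selects > vs >= at the threshold. ``unique`` collapses to
    one representative hit per unique (VH, VL) sequence pair.

    Hits are sorted by identity descending, ties broken by entry id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    entries = db.unique_entries() if unique else db.entries
    hits = []
    for entry in entries:
        target = _entry_chains(entry)
        if chains_used == "both":
            per_chain = [
                region_identity(query, target, region, chains_used=c) for c in ("H", "L")
            ]
            score = min(per_chain)
            passed = all(
                (i > threshold) if strict else (i >= threshold) for i in per_chain
            )
        else:
            score = region_identity(query, target, region, chains_used=chains_used)
            passed = (score > threshold) if strict else (score >= threshold)
        if passed:
            hits.append(SeqHit(entry.pair_id, score, region, chains_used))
    return sorted(hits, key=lambda h: (-h.identity, h.entry_id))
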