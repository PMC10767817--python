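"""Probable-antigen labelling from source text.

Every paired entry carries a ``targets_mentioned`` list: antigen names
found in the text of its source. For patents the title, abstract and
claims sections are searched; for any other source only the title is.
Two kinds of mention are collected:

* whole-token, case-insensitive matches against a user-supplied lexicon of
  commonly recognised antigen names (with optional synonym mapping), and
* any token carrying the ``anti-`` prefix — an "anti-PD-1 antibody" is
  presumably directed against PD-1 — with the prefix stripped.

The label is a recall-oriented shortlist, not a binding assertion: it cuts
down the manual review needed to establish what an antibody actually binds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

PATENT_SECTIONS = ("title", "abstract", "claims")

_TRAILING_PUNCT = ".,;:!?)]}'\""
_ANTI_PREFIX = re.compile(r"(?<![A-Za-z0-9-])anti-(\S+)", re.IGNORECASE)


@dataclass
class AntigenLexicon:
    """Antigen-name lexicon: canonical names plus alias -> canonical map."""

    names: list[str] = field(default_factory=list)
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        folded = [n.casefold() for n in self.names]
        if len(set(folded)) != len(folded):
            raise ValueError("canonical names must be unique after case-folding")
        self._canon = {n.casefold(): n for n in self.names}
        self._canon.update({a.casefold(): c for a, c in self.synonyms.items()})

    def canonical(self, token: str) -> str:
        """Canonical form of a token: through the synonym map when known,
        otherwise verbatim."""
        return self._canon.get(token.casefold(), token)

    def all_aliases(self) -> list[str]:
        return self.names + list(self.synonyms)

    @classmethod
    def from_file(cls, path: str | Path) -> "AntigenLexicon":
        """Load a plain-text lexicon: one bare name, or one
        ``alias<TAB>canonical`` mapping, per line; '#' starts a comment."""
        names: list[str] = []
        synonyms: dict[str, str] = {}
        seen = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "\t" in line:
                    alias, canonical = line.split("\t", 1)
                    synonyms[alias.strip()] = canonical.strip()
                    if canonical.strip().casefold() not in seen:
                        names.append(canonical.strip())
                        seen.add(canonical.strip().casefold())
                elif line.casefold() not in seen:
                    names.append(line)
                    seen.add(line.casefold())
        return cls(names=names, synonyms=synonyms)


def _strip_trailing_punct(token: str) -> str:
    return token.rstrip(_TRAILING_PUNCT)


def _mentions_in_text(text: str, lexicon: AntigenLexicon) -> list[tuple[int, str]]:
    """(position, canonical name) of every antigen mention in ``text``."""
    found: list[tuple[int, str]] = []
    for alias in lexicon.all_aliases():
        pattern = re.compile(
            rf"(?<![A-Za-z0-9]){re.escape(alias)}(?![A-Za-z0-9])", re.IGNORECASE
        )
        for m in pattern.finditer(text):
            found.append((m.start(), lexicon.canonical(alias)))
    for m in _ANTI_PREFIX.finditer(text):
        token = _strip_trailing_punct(m.group(1))
        if token:
            found.append((m.start(), lexicon.canonical(token)))
    return found


def extract_targets(
    entry_text_fields: dict[str, str],
    source_type: str,
    lexicon: AntigenLexicon,
) -> list[str]:
    """Antigen names mentioned in an entry's source text.

    ``entry_text_fields`` maps section name to text. Patents are searched
    over title, abstract and claims (in that order); all other source
    types over the title alone. The result is deduplicated (case-folded)
    and ordered by first mention.
    """
    sections = PATENT_SECTIONS if source_type == "patent" else ("title",)
    mentions: list[tuple[int, int, str]] = []
    for sec_idx, section in enumerate(sections):
        text = entry_text_fields.get(section, "")
        if not text:
            continue
        for pos, name in _mentions_in_text(text, lexicon):
            mentions.append((sec_idx, pos, name))
    out: list[str] = []
    seen: set[str] = set()
    for _, _, name in sorted(mentions, key=lambda t: (t[0], t[1])):
        if name.casefold() not in seen:
            out.append(name)
            seen.add(name.casefold())
    return out


def label_entries(entries, lexicon: AntigenLexicon, records_by_source=None) -> None:
    """Fill ``targets_mentioned`` on paired entries in place.

    Patent entries are labelled from their source record's patent sections
    (``records_by_source`` maps source_id -> a record carrying them);
    everything else from the source title.
    """
    for entry in entries:
        fields = {"title": entry.source_title}
        if entry.source_type == "patent" and records_by_source:
            rec = records_by_source.get(entry.source_id)
            if rec is not None and rec.patent_sections:
                fields = dict(rec.patent_sections)
                fields.setdefault("title", entry.source_title)
        entry.targets_mentioned = extract_targets(fields, entry.source_type, lexicon)
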