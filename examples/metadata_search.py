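"""Regex search over database metadata.

Every entry links back to its source title, description and antigen
labels; all three are searchable with case-insensitive regular
expressions, the way one compiles an antigen-specific subset.
"""

from pairedab.database import regex_search
from pairedab.pipeline import build_database
from pairedab.synth_fixtures import CorpusSpec, generate_corpus
from pairedab.targets import AntigenLexicon

corpus = generate_corpus(CorpusSpec(seed=1))
lexicon = AntigenLexicon(names=["TNF", "HER2", "PD-1", "CD3e", "EGFR", "RSV", "IL-6", "CD20"])
db = build_database(corpus.records, corpus.backend, lexicon=lexicon).database

for field, pattern in [
    ("source_title", "anti-pd-1|pd-1"),
    ("source_title", "her2"),
    ("targets_mentioned", "^tnf$"),
]:
    hits = regex_search(db, field, pattern)
    print(f"{field:17s} ~ /{pattern}/ -> {len(hits)} entries")
    for e in hits[:2]:
        print(f"   {e.pair_id.split('|')[0]:10s} {e.source_title[:60]}")
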