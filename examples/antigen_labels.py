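"""Antigen labelling from source text.

Patent entries are labelled from title + abstract + claims; every other
source type from the title alone. Mentions come from a lexicon of known
antigen names and from the 'anti-' prefix rule.
"""

from pairedab.targets import AntigenLexicon, extract_targets

lexicon = AntigenLexicon(
    names=["CD3e", "TNF", "HER2"],
    synonyms={"tumor necrosis factor": "TNF", "ERBB2": "HER2"},
)

cases = [
    ({"title": "Anti-PD-1 antibodies and methods of use thereof."}, "patent"),
    ({"title": "Bispecific CD3e x anti-TNF constructs"}, "paper"),
    ({"title": "An antibody survey", "abstract": "binders of HER2"}, "paper"),
    ({"title": "An antibody survey", "abstract": "binders of HER2"}, "patent"),
]

for fields, source_type in cases:
    out = extract_targets(fields, source_type, lexicon)
    print(f"{source_type:6s} {fields['title'][:45]:47s} -> {out}")

# Note the last two lines: the same text yields a label only for the
# patent, because non-patent entries are labelled from the title alone.
# Labels are a recall-oriented shortlist, not a binding assertion.
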