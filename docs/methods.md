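# Methods

This note records the models, conventions and design choices behind
`pairedab`, in the order the pipeline applies them.

## Record-level filtering

Records are kept when any text field (description, titles, patent
sections/paragraphs, organism/isolate/clone) contains at least one of the
inclusion terms `antibody`, `antibodies`, `immunoglobulin`, `scfv`, `bcr`
and none of the exclusion terms `nanobody`, `nanobodies`, matched
case-insensitively as whole words after splitting on non-alphanumerics
(so `antibody-drug` matches, `antibodylike` does not). Nanobodies are
excluded because a humanised single-domain antibody cannot be reliably
told apart from an unpaired human VH. The length window is inclusive:
sequences of exactly 70 or 1000 residues are kept; only strictly shorter
or longer ones are dropped. Records failing any gate are logged with a
reason (`too_short`, `too_long`, `nanobody_term`, `no_keyword`,
`invalid_residues`) rather than silently skipped, so the input partition
is auditable. The window is applied to the raw record, before any
multi-domain entry is split into domains.

## Numbering and regions

Domains carry an IMGT-like integer numbering with fixed region ranges
(FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3 66–104, CDR3 105–117,
FR4 118–128). Framework labels are contiguous (FR3 end-aligned so the
conserved cysteine preceding CDR3 sits at 104); CDR labels fill from both
ends of their range toward the middle, keeping loop anchors aligned
across lengths. Insertion codes are not supported, which caps CDR-H3 at
13 residues — adequate for the synthetic corpora here, a known limitation
for real repertoires whose CDR-H3 lengths often exceed it.

Numbering is a backend contract. The default `FixtureNumberingBackend` is
a deterministic lookup table: it annotates exactly the sequences
registered with it, located as substrings of a record (which is how scFv
records yield an H and an L domain in N→C order). The synthetic-corpus
generator registers every domain it plants, so no external tool runs in
the build or test path; an adapter for an external HMM-based numberer
exists behind the same interface for real data.

Two independent per-domain checks follow:

* **CDR completeness** — a domain is dropped iff any CDR span is empty or
  its observed labels differ from the canonical label set for its own
  length. Natural length polymorphism therefore passes; an interior (or
  edge) deletion leaves a label pattern no loop length could produce and
  is treated as incomplete sequencing.
* **N-terminal deficit** — the number of leading framework positions
  absent before the first observed residue. A deficit greater than eight
  flags the entry `restoration_needed`; restoration itself is a no-op
  hook in this build (it would be an external learned sequence model) and
  flagged entries keep their flag through storage.

## Pairing cascade

Within each source, six heuristics run in a fixed order; a domain
consumed by an earlier heuristic is invisible to later ones. The order is
the natural precedence: the specific, evidence-backed methods first, the
positional fallbacks (`unique_chain`, `ordered_entries`, the only
low-confidence methods) last.

Conventions the cascade fixes where the idea itself leaves latitude:

* **Word rarity** (`unique_word`) is computed once over the whole
  unpaired corpus, counting the number of *entries* whose description
  contains the token; a token is uncommon below 20 entries. Tokens are
  lowercased, split on non-alphanumerics; bare single digits and a small
  stop list (`chain, heavy, light, variable, region, antibody,
  immunoglobulin`) never count.
* **Conflicting evidence** within one heuristic (e.g. two rare words
  proposing different partners for the same domain) discards all
  conflicting proposals; the domains fall through to later heuristics.
* **`unique_source`** checks isolate before clone and requires exact
  string equality after trimming; no fuzzy matching.
* **Patent citations** match `SEQ ID NO[.:]? <integer>` (also `NOs`)
  case-insensitively; a record's number is its explicit `seq_id` when
  present, else its 1-based deposition index within the source. A
  paragraph whose citations do not all parse is skipped and logged.
  Paragraphs are processed in order and consume domains immediately.
  Equal VH/VL citation counts pair i-th with i-th in mention order.
* Ties everywhere break deterministically by (record id, domain index),
  so a rebuild is byte-identical and the pair set is invariant to source
  ordering.

High confidence ⇔ method ∈ {same_entry, unique_word, unique_source,
patent_text} or a curated import (`imported_structure`,
`imported_therapeutic`).

## Antigen labels

`targets_mentioned` is a recall-oriented shortlist, not a binding
assertion. Lexicon names match as whole tokens (boundaries = any
non-alphanumeric neighbour, so hyphenated names like `PD-1` work);
`anti-` captures the maximal following token up to whitespace, strips
trailing punctuation, keeps internal hyphens/digits, and canonicalises
through the synonym map when possible. Patents are searched over
title + abstract + claims, everything else over the title alone; results
are deduplicated case-insensitively in first-mention order. The lexicon
is a user input (plain text, bare name or `alias<TAB>canonical` per
line).

## Database

Storage is one TSV row per entry (full and per-region sequences, method
flag, confidence, source linkage, labels) plus a JSON sidecar with
version and build log — human-greppable and diff-friendly. Entries are
keyed by `pair_id`; `upsert` is idempotent, replaces by id, and rejects a
batch containing conflicting duplicates. Several entries may share one
(VH, VL) sequence pair; the unique index maps each distinct pair to its
entry ids, and downstream modelling is invoked once per unique pair.
CDR-H3 length is the count of occupied heavy CDR3 positions. Species
summaries merge the organism field case-insensitively and bucket absent
values as `unannotated`; per-year counts use the optional deposition
year.

## Sequence search

Because all domains share one numbering, identity needs no pairwise
alignment: over the selected positions (full variable domain, all six
CDRs, CDR-H3, or a user-defined set), identity = matching residues /
positions occupied in **either** sequence. The union denominator makes
length differences count against identity; it is symmetric and
monotone-friendly. Thresholds are strict (`> 0.9` for "over 90%"); the
CLI exposes `>=` as an option. A two-chain search requires each chain to
exceed the threshold individually, and the reported score is the smaller
(limiting) chain identity. The scan is exhaustive by design — at
desk-scale database sizes there is nothing to index.

## Structure search

Candidates are restricted to models with the query's exact six CDR loop
lengths (the strict reading: all of H1, H2, H3, L1, L2, L3), which gives
a one-to-one correspondence at the numbered positions. The shared
occupied framework positions of both chains jointly are superposed by the
Kabsch algorithm (SVD-based least squares; a proper rotation is enforced
via the determinant correction; fewer than three or collinear points are
a degeneracy error). The C\_alpha RMSD over all CDR positions is then
computed in that frame with **no re-fit on the loops**, preserving the
loop-orientation signal relative to the conserved scaffold. The measure
is symmetric to machine precision and invariant under rigid motion of
either model. Default thresholds: RMSD < 1.25 Å, optional CDR sequence
identity > 0.8, both strict.

Models come from a backend contract. The bundled `ScaffoldModelBackend`
places C-alphas on an idealised helical trace that is a pure function of
(chain, position label), with CDR positions additionally displaced by a
pure function of the residue identity — so identical loops superpose
exactly and divergent loops drift apart by up to a few Å. It rejects
non-standard residues, and any backend failure yields a `FAILED` model
(skipped by search) rather than an exception. A real structure predictor
would slot in behind the same contract, including the no-refinement flag
for query-side speed; the scaffold backend accepts and ignores it.

## Synthetic corpora and toy models

The generator plants, per intended pair, exactly the evidence its
heuristic needs and nothing more: every multi-record source shares one
description word multiset (so no background token can single out a VH/VL
pair), deposition order is crossed against the intended pairing wherever
a positional fallback could coincide with it, and decoy sources combine
ambiguous evidence with unequal chain counts so they fall through all six
heuristics. Filter decoys cover each drop reason. Domain sequences derive
from two germline-like templates (human VH3/JH4-like and V-kappa-1/JK1-
like) by 1–3 framework substitutions and CDR3 replacement (heavy 8–13,
light 8–10 residues); generation is a pure function of the spec and seed.
The reference sizing (`benchmark_spec`) is ~560 records and 300 planted
pairs with ≥ 20 per heuristic — small enough to rebuild in a fraction of
a second, large enough that corpus-wide word frequencies behave like a
real corpus's common/rare split.

Toy structural models perturb an idealised scaffold with isotropic
Gaussian CDR noise (default studies use σ = 0.5–0.6 Å) followed by a
random rigid transform; since frameworks stay noise-free, framework
superposition recovers exactly the planted RMS displacement
(E[RMSD²] = 3σ², which the tests check against the χ² sampling error).

What passing on these fixtures shows — and does not. The fixtures
exercise the metadata logic, the numbering-driven identity conventions
and the rigid-body geometry exactly; they do not emulate germline
diversity, somatic hypermutation, sequencing noise in descriptions, or
real patent prose. Perfect recovery here validates the machinery, not the
real-world accuracy of any heuristic, which depends on how clean actual
metadata is.

## Numerical and degenerate-input choices

* Kabsch: rank check (tolerance 1e-8) rejects collinear/coincident point
  sets; reflection is corrected to keep det(R) = +1.
* Identity with an empty selected region in both sequences is an error
  (undefined), not 0 or 1.
* Empty corpora build valid empty databases with a warning; re-running a
  build or an upsert is idempotent and byte-identical.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; no global RNG state is touched.

## Known limitations

* No insertion codes, hence CDR-H3 capped at 13 residues.
* The lookup-table numbering backend only annotates registered sequences;
  real data requires the external-numberer adapter.
* Scaffold model geometry encodes loop sequence, not physics; structural
  hits on real antibodies require a real predictor behind the backend.
* Antigen labelling is lexical; its precision on real text is bounded by
  the lexicon and the `anti-` convention.
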