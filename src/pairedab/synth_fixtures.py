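"""Seeded synthetic corpora with planted ground truth, and toy models.

The generator emits record corpora that exercise every pairing heuristic
unambiguously, together with the ground truth of intended pairs, so the
whole pipeline can be scored offline. Domain sequences derive from the
bundled germline-like VH/VL templates by framework substitution and CDR3
replacement, and every generated domain is registered with a
:class:`~pairedab.numbering.FixtureNumberingBackend` so that numbering
needs no external tool.

Construction rules that keep the plants unambiguous:

* every multi-record source shares one description word multiset, so no
  background word can single out one VH and one VL within a source;
* rare tokens, clone tags and patent citations are planted per intended
  pair, and deposition order is crossed against the intended pairing
  wherever a later positional heuristic could otherwise coincide with it;
* decoy sources carry ambiguous evidence plus unequal chain counts, so
  they fall through all six heuristics and stay unpaired.

Fixtures are metadata/geometry exercises only — they make no attempt at
biological realism (germline usage, somatic hypermutation, repertoire
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from pairedab.numbering import (
    FixtureNumberingBackend,
    VH_TEMPLATE_REGIONS,
    VL_TEMPLATE_REGIONS,
    assign_labels,
    cdr_labels,
)
from pairedab.records_io import RawRecord
from pairedab.struct_search import AntibodyModel, scaffold_coordinate

AA20 = "ACDEFGHIKLMNPQRSTVWY"

LINKER = "GGGGSGGGGSGGGGS"

COMMON_WORDS = (
    "engineered", "recombinant", "neutralizing", "affinity", "matured",
    "humanized", "murine", "monoclonal", "specific", "therapeutic",
    "candidate", "fragment",
)

ANTIGEN_POOL = ("PD-1", "TNF", "HER2", "CD3e", "EGFR", "RSV", "IL-6", "CD20")

ORGANISM_POOL = ("Homo sapiens", "Mus musculus", "Macaca mulatta", None, None)


@dataclass
class CorpusSpec:
    """Sizing of a synthetic corpus. All counts are >= 0; generation is a
    pure function of the spec (same spec -> byte-identical corpus)."""

    seed: int = 0
    n_same_entry: int = 5  # scFv-like records; 1 pair each
    n_unique_word_sources: int = 2  # 2 rare-word pairs each
    n_unique_source_sources: int = 2  # 2 clone/isolate pairs each
    n_patent_sources: int = 2  # 3 pairs each (1 one-to-one + 2 ordered)
    n_unique_chain_sources: int = 1  # 1 VH + 3 VL -> 3 pairs each
    n_ordered_sources: int = 2  # 2 in-order pairs each
    n_truncated_flagged: int = 1  # scFv records with VH missing 10 leading aa
    n_truncated_unflagged: int = 1  # scFv records with VH missing 5 leading aa
    n_ambiguous_word_decoys: int = 1  # sources defeating heuristic 2
    n_shared_clone_decoys: int = 1  # sources defeating heuristic 3
    n_unequal_patent_decoys: int = 1  # patents defeating heuristic 4
    n_light_only_sources: int = 1
    n_filter_decoys: int = 1  # sets of records dropped by record filters

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if name != "seed" and value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator planted: pairs the cascade should recover (with
    their method), domain-bearing records it should leave unpaired, and
    records the record filters should drop."""

    intended_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    intended_unpaired: list[str] = field(default_factory=list)
    intended_dropped_records: list[tuple[str, str]] = field(default_factory=list)
    restoration_flagged_records: list[str] = field(default_factory=list)

    def pairs_by_method(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, method in self.intended_pairs:
            counts[method] = counts.get(method, 0) + 1
        return counts


@dataclass
class SyntheticCorpus:
    records: list[RawRecord]
    truth: GroundTruth
    backend: FixtureNumberingBackend


class _Generator:
    def __init__(self, spec: CorpusSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.backend = FixtureNumberingBackend()
        self.truth = GroundTruth()
        self.blocks: list[list[RawRecord]] = []
        self._seen_sequences: set[str] = set()
        self._rec_counter = 0
        self._src_counter = 0
        self._rare_counter = 0

    # -- low-level helpers -------------------------------------------------

    def _record_id(self) -> str:
        self._rec_counter += 1
        return f"R{self._rec_counter:05d}"

    def _source_id(self, kind: str) -> str:
        self._src_counter += 1
        return f"{kind}-{self._src_counter:04d}"

    def _rare_token(self) -> str:
        self._rare_counter += 1
        return f"zq{self._rare_counter}x"

    def _random_cdr3(self, chain: str) -> str:
        if chain == "H":
            length = int(self.rng.integers(8, 14))  # CDR3 capacity is 13
            core = "".join(self.rng.choice(list(AA20), size=length - 2))
            return "AR" + core
        length = int(self.rng.integers(8, 11))
        return "QQ" + "".join(self.rng.choice(list(AA20), size=length - 2))

    def make_domain(self, chain: str, truncate_n: int = 0) -> str:
        """A fresh unique domain sequence, registered with the backend."""
        template = VH_TEMPLATE_REGIONS if chain == "H" else VL_TEMPLATE_REGIONS
        for _ in range(200):
            regions = dict(template)
            regions["CDR3"] = self._random_cdr3(chain)
            fr3 = list(regions["FR3"])
            # a couple of framework substitutions, away from the final Cys
            for _ in range(int(self.rng.integers(1, 4))):
                pos = int(self.rng.integers(0, len(fr3) - 1))
                fr3[pos] = str(self.rng.choice(list(AA20)))
            regions["FR3"] = "".join(fr3)
            seq = "".join(aa for _, aa in assign_labels(regions))[truncate_n:]
            if seq not in self._seen_sequences:
                self._seen_sequences.add(seq)
                light_class = None if chain == "H" else "kappa"
                self.backend.register_regions(chain, regions, truncate_n, light_class)
                return seq
        raise RuntimeError("could not generate a unique domain sequence")

    def _description(self, words: list[str], chain_note: str) -> str:
        return " ".join(words + ["antibody", chain_note])

    def _common_words(self, k: int = 2) -> list[str]:
        return [str(w) for w in self.rng.choice(COMMON_WORDS, size=k, replace=False)]

    def _meta(self) -> dict:
        organism = self.rng.choice(ORGANISM_POOL)
        return {
            "organism": None if organism is None else str(organism),
            "year": int(self.rng.integers(2004, 2024)),
        }

    def _record(self, source_id: str, description: str, sequence: str, **kw) -> RawRecord:
        meta = self._meta()
        meta.update(kw)
        title = meta.pop("source_title", "")
        return RawRecord(
            record_id=self._record_id(),
            description=description,
            sequence=sequence,
            source_id=source_id,
            source_title=title,
            **meta,
        )

    def _title(self, words: list[str]) -> str:
        antigen = str(self.rng.choice(ANTIGEN_POOL))
        return f"Characterization of {' '.join(words)} antibodies against {antigen}"

    # -- source builders ---------------------------------------------------

    def add_same_entry(self, truncate_n: int = 0) -> None:
        source = self._source_id("PUB")
        words = self._common_words()
        h = self.make_domain("H", truncate_n=truncate_n)
        l = self.make_domain("L")
        rec = self._record(
            source,
            self._description(words, "single chain variable fragment scfv"),
            h + LINKER + l,
            source_title=self._title(words),
        )
        self.blocks.append([rec])
        self.truth.intended_pairs.append((rec.record_id, rec.record_id, "same_entry"))
        if truncate_n > 8:
            self.truth.restoration_flagged_records.append(rec.record_id)

    def add_unique_word_source(self) -> None:
        source = self._source_id("PUB")
        words = self._common_words()
        title = self._title(words)
        t1, t2 = self._rare_token(), self._rare_token()
        recs = []
        # crossed deposition order: VH1, VH2, VL2, VL1
        for token, chain, note in (
            (t1, "H", "heavy chain"), (t2, "H", "heavy chain"),
            (t2, "L", "light chain"), (t1, "L", "light chain"),
        ):
            seq = self.make_domain(chain)
            recs.append(
                self._record(
                    source,
                    self._description(words + [f"mab {token}"], note),
                    seq,
                    source_title=title,
                )
            )
        self.blocks.append(recs)
        self.truth.intended_pairs.append((recs[0].record_id, recs[3].record_id, "unique_word"))
        self.truth.intended_pairs.append((recs[1].record_id, recs[2].record_id, "unique_word"))

    def add_unique_source_source(self, attr: str) -> None:
        source = self._source_id("PUB")
        words = self._common_words()
        title = self._title(words)
        tag1 = f"cl{self._src_counter}a"
        tag2 = f"cl{self._src_counter}b"
        recs = []
        # crossed deposition order: VH1, VH2, VL2, VL1
        for tag, chain, note in (
            (tag1, "H", "heavy chain"), (tag2, "H", "heavy chain"),
            (tag2, "L", "light chain"), (tag1, "L", "light chain"),
        ):
            seq = self.make_domain(chain)
            recs.append(
                self._record(
                    source,
                    self._description(words, note),
                    seq,
                    source_title=title,
                    **{attr: tag},
                )
            )
        self.blocks.append(recs)
        self.truth.intended_pairs.append((recs[0].record_id, recs[3].record_id, "unique_source"))
        self.truth.intended_pairs.append((recs[1].record_id, recs[2].record_id, "unique_source"))

    def add_patent_source(self, explicit_seq_ids: bool) -> None:
        source = self._source_id("PAT")
        words = self._common_words()
        antigen = str(self.rng.choice(ANTIGEN_POOL))
        title = f"Anti-{antigen} antibodies and methods of use thereof."
        chains = ["H", "L", "H", "H", "L", "L"]  # deposition order
        seqs = [self.make_domain(c) for c in chains]
        offset = 100 if explicit_seq_ids else 0
        ids = list(range(1 + offset, 7 + offset))
        paragraphs = [
            f"The antibody comprises a heavy chain of SEQ ID NO: {ids[0]} and a "
            f"light chain of SEQ ID NO: {ids[1]}.",
            # mention order crosses deposition order: VH3, VH4 then VL6, VL5
            f"Further antibodies pair SEQ ID NO: {ids[2]} and SEQ ID NO: {ids[3]} "
            f"with SEQ ID NO: {ids[5]} and SEQ ID NO: {ids[4]} respectively.",
            "Reference is also made to SEQ ID NO: n/a of the parent application.",
        ]
        sections = {
            "title": title,
            "abstract": f"Antibodies binding {antigen} and uses thereof.",
            "claims": f"An isolated antibody that binds {antigen}.",
        }
        recs = []
        for i, (chain, seq) in enumerate(zip(chains, seqs)):
            note = "heavy chain" if chain == "H" else "light chain"
            recs.append(
                self._record(
                    source,
                    self._description(words, note),
                    seq,
                    source_title=title,
                    source_type="patent",
                    seq_id=ids[i] if explicit_seq_ids else None,
                    patent_sections=sections if i == 0 else None,
                    patent_paragraphs=paragraphs if i == 0 else None,
                )
            )
        self.blocks.append(recs)
        self.truth.intended_pairs.append((recs[0].record_id, recs[1].record_id, "patent_text"))
        self.truth.intended_pairs.append((recs[2].record_id, recs[5].record_id, "patent_text"))
        self.truth.intended_pairs.append((recs[3].record_id, recs[4].record_id, "patent_text"))

    def add_unique_chain_source(self) -> None:
        source = self._source_id("PUB")
        words = self._common_words()
        title = self._title(words)
        recs = [
            self._record(
                source, self._description(words, "heavy chain"), self.make_domain("H"),
                source_title=title,
            )
        ]
        for _ in range(3):
            recs.append(
                self._record(
                    source, self._description(words, "light chain"), self.make_domain("L"),
                    source_title=title,
                )
            )
        self.blocks.append(recs)
        for lrec in recs[1:]:
            self.truth.intended_pairs.append((recs[0].record_id, lrec.record_id, "unique_chain"))

    def add_ordered_source(self) -> None:
        source = self._source_id("PUB")
        words = self._common_words()
        title = self._title(words)
        recs = []
        for chain, note in (("H", "heavy chain"), ("H", "heavy chain"),
                            ("L", "light chain"), ("L", "light chain")):
            recs.append(
                self._record(
                    source, self._description(words, note), self.make_domain(chain),
                    source_title=title,
                )
            )
        self.blocks.append(recs)
        self.truth.intended_pairs.append((recs[0].record_id, recs[2].record_id, "ordered_entries"))
        self.truth.intended_pairs.append((recs[1].record_id, recs[3].record_id, "ordered_entries"))

    # -- decoys ------------------------------------------------------------

    def add_ambiguous_word_decoy(self) -> None:
        # rare token in two VH descriptions: uniqueness violated, and 3 VH +
        # 2 VL defeats both positional fallbacks
        source = self._source_id("PUB")
        words = self._common_words()
        title = self._title(words)
        token = self._rare_token()
        plan = [("H", [f"mab {token}"]), ("H", [f"mab {token}"]), ("H", []),
                ("L", [f"mab {token}"]), ("L", [])]
        recs = []
        for chain, extra in plan:
            note = "heavy chain" if chain == "H" else "light chain"
            recs.append(
                self._record(
                    source, self._description(words + extra, note), self.make_domain(chain),
                    source_title=title,
                )
            )
        self.blocks.append(recs)
        self.truth.intended_unpaired.extend(r.record_id for r in recs)

    def add_shared_clone_decoy(self) -> None:
        source = self._source_id("PUB")
        words = self._common_words()
        title = self._title(words)
        tag = f"sh{self._src_counter}"
        plan = [("H", tag), ("H", tag), ("H", None), ("L", tag), ("L", None)]
        recs = []
        for chain, clone in plan:
            note = "heavy chain" if chain == "H" else "light chain"
            recs.append(
                self._record(
                    source, self._description(words, note), self.make_domain(chain),
                    source_title=title, clone=clone,
                )
            )
        self.blocks.append(recs)
        self.truth.intended_unpaired.extend(r.record_id for r in recs)

    def add_unequal_patent_decoy(self) -> None:
        source = self._source_id("PAT")
        words = self._common_words()
        title = "Antibody compositions and formulations."
        chains = ["H", "H", "L", "L", "L"]
        seqs = [self.make_domain(c) for c in chains]
        paragraphs = [
            "The invention provides SEQ ID NO: 1, SEQ ID NO: 2, SEQ ID NO: 3, "
            "SEQ ID NO: 4 and SEQ ID NO: 5."
        ]
        recs = []
        for i, (chain, seq) in enumerate(zip(chains, seqs)):
            note = "heavy chain" if chain == "H" else "light chain"
            recs.append(
                self._record(
                    source, self._description(words, note), seq,
                    source_title=title, source_type="patent",
                    patent_paragraphs=paragraphs if i == 0 else None,
                )
            )
        self.blocks.append(recs)
        self.truth.intended_unpaired.extend(r.record_id for r in recs)

    def add_light_only_source(self) -> None:
        source = self._source_id("PUB")
        words = self._common_words()
        title = self._title(words)
        recs = [
            self._record(
                source, self._description(words, "light chain"), self.make_domain("L"),
                source_title=title,
            )
            for _ in range(2)
        ]
        self.blocks.append(recs)
        self.truth.intended_unpaired.extend(r.record_id for r in recs)

    def add_filter_decoys(self) -> None:
        source = self._source_id("PUB")
        words = self._common_words()
        title = self._title(words)
        plan = [
            ("humanised nanobody against TNF", self.make_domain("H"), "nanobody_term"),
            (self._description(words, "heavy chain"), "AR" + "A" * 58, "too_short"),
            (self._description(words, "heavy chain"), "M" * 1001, "too_long"),
            ("a kinase inhibitor", self.make_domain("H"), "no_keyword"),
            (self._description(words, "heavy chain"), "ARB" + "A" * 97, "invalid_residues"),
        ]
        recs = []
        for desc, seq, reason in plan:
            # no_keyword must not inherit antibody vocabulary via the title
            rec = self._record(source, desc, seq,
                               source_title="" if reason == "no_keyword" else title)
            recs.append(rec)
            self.truth.intended_dropped_records.append((rec.record_id, reason))
        # passes the record filters but contains no variable domain
        recs.append(
            self._record(source, self._description(words, "construct"), "G" * 100,
                         source_title=title)
        )
        self.blocks.append(recs)

    # -- assembly ----------------------------------------------------------

    def run(self) -> SyntheticCorpus:
        s = self.spec
        for i in range(s.n_same_entry):
            self.add_same_entry()
        for i in range(s.n_truncated_flagged):
            self.add_same_entry(truncate_n=10)
        for i in range(s.n_truncated_unflagged):
            self.add_same_entry(truncate_n=5)
        for _ in range(s.n_unique_word_sources):
            self.add_unique_word_source()
        for i in range(s.n_unique_source_sources):
            self.add_unique_source_source("isolate" if i % 2 == 0 else "clone")
        for i in range(s.n_patent_sources):
            self.add_patent_source(explicit_seq_ids=i % 2 == 1)
        for _ in range(s.n_unique_chain_sources):
            self.add_unique_chain_source()
        for _ in range(s.n_ordered_sources):
            self.add_ordered_source()
        for _ in range(s.n_ambiguous_word_decoys):
            self.add_ambiguous_word_decoy()
        for _ in range(s.n_shared_clone_decoys):
            self.add_shared_clone_decoy()
        for _ in range(s.n_unequal_patent_decoys):
            self.add_unequal_patent_decoy()
        for _ in range(s.n_light_only_sources):
            self.add_light_only_source()
        for _ in range(s.n_filter_decoys):
            self.add_filter_decoys()
        order = self.rng.permutation(len(self.blocks))
        records = [rec for idx in order for rec in self.blocks[idx]]
        return SyntheticCorpus(records=records, truth=self.truth, backend=self.backend)


def benchmark_spec(seed: int = 0) -> CorpusSpec:
    """The reference corpus sizing: ~560 records and 300 planted pairs,
    with every pairing heuristic exercised at least twenty times and every
    decoy/filter path represented."""
    return CorpusSpec(
        seed=seed,
        n_same_entry=76,
        n_truncated_flagged=2,
        n_truncated_unflagged=2,
        n_unique_word_sources=22,
        n_unique_source_sources=22,
        n_patent_sources=14,
        n_unique_chain_sources=14,
        n_ordered_sources=24,
        n_ambiguous_word_decoys=3,
        n_shared_clone_decoys=3,
        n_unequal_patent_decoys=3,
        n_light_only_sources=4,
        n_filter_decoys=3,
    )


def generate_corpus(spec: CorpusSpec) -> SyntheticCorpus:
    """Generate a synthetic corpus with planted ground truth.

    Returns records (source blocks in seeded shuffled order, deposition
    order preserved within each source), the ground truth, and the fixture
    numbering backend that can annotate every planted domain.
    """
    return _Generator(spec).run()


# ---------------------------------------------------------------------------
# Toy structural models


#: Framework lengths shared by every toy model (the template lengths).
TOY_FRAMEWORK_LENGTHS = {
    "H": {"FR1": 25, "FR2": 17, "FR3": 38, "FR4": 11},
    "L": {"FR1": 26, "FR2": 17, "FR3": 36, "FR4": 10},
}


@dataclass
class ToyModelSet:
    models: list[AntibodyModel]
    true_rmsds: list[float]
    parents: dict[tuple[int, ...], AntibodyModel]


def _scaffold_keys(cdr_lengths: tuple[int, ...]) -> list[tuple[str, int]]:
    from pairedab.numbering import framework_labels

    keys: list[tuple[str, int]] = []
    per_chain = {"H": cdr_lengths[:3], "L": cdr_lengths[3:]}
    for chain in ("H", "L"):
        h1, h2, h3 = per_chain[chain]
        for region, length in TOY_FRAMEWORK_LENGTHS[chain].items():
            keys += [(chain, lab) for lab in framework_labels(region, length)]
        for region, length in (("CDR1", h1), ("CDR2", h2), ("CDR3", h3)):
            keys += [(chain, lab) for lab in cdr_labels(region, length)]
    return sorted(keys)


def _parent_model(cdr_lengths: tuple[int, ...], rng: np.random.Generator) -> AntibodyModel:
    keys = _scaffold_keys(cdr_lengths)
    coords = {k: scaffold_coordinate(*k) for k in keys}
    residues = {k: str(rng.choice(list(AA20))) for k in keys}
    name = "parent_" + "_".join(map(str, cdr_lengths))
    return AntibodyModel(entry_id=name, ca_coords=coords, residues=residues)


def generate_toy_models(
    n: int,
    cdr_length_tuples: list[tuple[int, ...]],
    perturbation_scale: float,
    seed: int = 0,
) -> ToyModelSet:
    """Rigid-body-perturbed toy antibody models.

    Each model is its parent scaffold (one per CDR-length tuple, assigned
    round-robin) with isotropic Gaussian noise of the given scale (in A)
    added to the CDR C-alphas, then a random rigid transform of the whole
    model. The recorded true RMSD is the root-mean-square of the CDR
    displacements — exactly what framework superposition should recover,
    since the framework itself is noise-free.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not cdr_length_tuples:
        raise ValueError("at least one CDR length tuple is required")
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    parents = {tuple(t): _parent_model(tuple(t), rng) for t in cdr_length_tuples}
    models: list[AntibodyModel] = []
    true_rmsds: list[float] = []
    for i in range(n):
        tup = tuple(cdr_length_tuples[i % len(cdr_length_tuples)])
        parent = parents[tup]
        keys = sorted(parent.ca_coords)
        cdr_keys = parent.cdr_keys()
        coords = {k: parent.ca_coords[k].copy() for k in keys}
        displacements = []
        for k in keys:
            if k in cdr_keys:
                d = rng.normal(0.0, perturbation_scale, size=3)
                coords[k] = coords[k] + d
                displacements.append(d)
        rmsd = float(np.sqrt(np.mean(np.sum(np.square(displacements), axis=1))))
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20.0, 20.0, size=3)
        coords = {k: R @ v + t for k, v in coords.items()}
        # CDR residues mutate with the geometry so identity filters have signal
        residues = dict(parent.residues)
        for k in parent.cdr_keys():
            if rng.random() < 0.3:
                residues[k] = str(rng.choice(list(AA20)))
        models.append(
            AntibodyModel(entry_id=f"toy{i:04d}", ca_coords=coords, residues=residues)
        )
        true_rmsds.append(rmsd)
    return ToyModelSet(models=models, true_rmsds=true_rmsds, parents=parents)
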