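"""The six VH-VL pairing heuristics and the cascade."""

import pytest

from conftest import make_domain
from pairedab.pairing import (
    HIGH_CONFIDENCE_METHODS,
    PairingCandidatePool,
    description_tokens,
    import_external_pairs,
    entry_to_row,
    pair_ordered,
    pair_patent_text,
    pair_same_entry,
    pair_unique_chain,
    pair_unique_source,
    pair_unique_word,
    run_pairing_cascade,
    word_document_frequency,
)
from pairedab.records_io import RawRecord
from pairedab.synth_fixtures import CorpusSpec, generate_corpus
from pairedab.pipeline import build_database


def _rec(record_id, description="monoclonal antibody", source_id="S1", **kw):
    return RawRecord(record_id=record_id, description=description,
                     sequence="A" * 100, source_id=source_id, **kw)


def _pool(*items, source_id="S1"):
    """items: (record, chain or list of chains). Domains get distinct CDR3s
    so sequence pairs are unique."""
    pool = PairingCandidatePool(source_id=source_id)
    counter = 0
    for record, chains in items:
        pool.record_meta[record.record_id] = record
        if isinstance(chains, str):
            chains = [chains]
        for idx, chain in enumerate(chains):
            counter += 1
            cdr3 = ("AR" if chain == "H" else "QQ") + "ACDEFGHIKL"[counter % 8] * 6
            dom = make_domain(chain, record_id=record.record_id, cdr3=cdr3,
                              domain_index=idx)
            (pool.heavies if chain == "H" else pool.lights).append(dom)
    return pool


class TestSameEntry:
    def test_single_vh_vl_record_paired(self):
        pool = _pool((_rec("r1"), ["H", "L"]))
        (pair,) = pair_same_entry(pool)
        assert pair.pairing_method == "same_entry"
        assert pair.high_confidence
        assert pool.heavies == [] and pool.lights == []

    def test_two_vh_one_vl_not_paired(self):
        pool = _pool((_rec("r1"), ["H", "H", "L"]))
        assert pair_same_entry(pool) == []
        assert len(pool.heavies) == 2


class TestUniqueWord:
    def test_rare_token_pairs_heavy_and_light(self):
        pool = _pool(
            (_rec("r1", "mAb X17-heavy"), "H"),
            (_rec("r2", "mAb X17-light"), "L"),
        )
        freq = word_document_frequency(pool.record_meta.values())
        (pair,) = pair_unique_word(pool, freq)
        assert pair.pairing_method == "unique_word"
        assert pair.heavy.parent_record_id == "r1"

    def test_tokenisation_of_alphanumeric_clone_codes(self):
        assert "x17" in description_tokens("mAb X17-heavy")
        assert "heavy" not in description_tokens("mAb X17-heavy")  # stop word

    def test_token_in_two_heavies_is_ambiguous(self):
        pool = _pool(
            (_rec("r1", "clone qq9z alpha"), "H"),
            (_rec("r2", "clone qq9z beta"), "H"),
            (_rec("r3", "clone qq9z gamma"), "L"),
        )
        freq = word_document_frequency(pool.record_meta.values())
        assert pair_unique_word(pool, freq) == []

    def test_conflicting_rare_words_discard_all_proposals(self):
        # token "aa1" proposes r1-r2; token "bb2" proposes r1-r3: conflicting
        # partners for r1's heavy, so nothing is paired by this heuristic
        pool = _pool(
            (_rec("r1", "aa1 bb2 candidate"), "H"),
            (_rec("r2", "aa1 candidate"), "L"),
            (_rec("r3", "bb2 candidate"), "L"),
        )
        freq = word_document_frequency(pool.record_meta.values())
        assert pair_unique_word(pool, freq) == []
        assert len(pool.heavies) == 1 and len(pool.lights) == 2

    def test_common_words_never_pair(self):
        records = [_rec(f"x{i}", "shared candidate phrase", source_id="OTHER")
                   for i in range(25)]
        pool = _pool(
            (_rec("r1", "shared candidate phrase"), "H"),
            (_rec("r2", "shared candidate phrase"), "L"),
        )
        freq = word_document_frequency(records + list(pool.record_meta.values()))
        assert pair_unique_word(pool, freq) == []


class TestUniqueSource:
    def test_unique_clone_pairs(self):
        pool = _pool(
            (_rec("r1", clone="B12-7"), "H"),
            (_rec("r2", clone="B12-7"), "L"),
            (_rec("r3", clone="other"), "H"),
        )
        (pair,) = pair_unique_source(pool)
        assert pair.pairing_method == "unique_source"
        assert {pair.heavy.parent_record_id, pair.light.parent_record_id} == {"r1", "r2"}

    def test_shared_clone_among_three_domains_pairs_nothing(self):
        pool = _pool(
            (_rec("r1", clone="A1"), "H"),
            (_rec("r2", clone="A1"), "H"),
            (_rec("r3", clone="A1"), "L"),
        )
        assert pair_unique_source(pool) == []

    def test_isolate_checked_before_clone(self):
        pool = _pool(
            (_rec("r1", isolate="iso9"), "H"),
            (_rec("r2", isolate="iso9", clone="c1"), "L"),
            (_rec("r3", clone="c1"), "L"),
        )
        pairs = pair_unique_source(pool)
        assert len(pairs) == 1
        assert pairs[0].light.parent_record_id == "r2"


class TestPatentText:
    def _patent_pool(self, paragraphs, plan):
        recs = []
        for i, chain in enumerate(plan):
            recs.append(
                (
                    _rec(
                        f"p{i+1}",
                        source_id="PAT1",
                        source_type="patent",
                        patent_paragraphs=paragraphs if i == 0 else None,
                    ),
                    chain,
                )
            )
        return _pool(*recs, source_id="PAT1")

    def test_one_to_one_citation(self):
        pool = self._patent_pool(
            ["The antibody has SEQ ID NO:1 (VH) and SEQ ID NO:2 (VL)."], ["H", "L"]
        )
        (pair,) = pair_patent_text(pool)
        assert pair.pairing_method == "patent_text"
        assert (pair.heavy.parent_record_id, pair.light.parent_record_id) == ("p1", "p2")

    def test_equal_counts_pair_in_mention_order(self):
        # deposition: p1=VH, p2=VL, p3=VH, p4=VL; mentions VH p1, p3 then VL p2, p4
        pool = self._patent_pool(
            ["Heavy chains SEQ ID NO: 1 and SEQ ID NO: 3 pair with light chains "
             "SEQ ID NO: 2 and SEQ ID NO: 4."],
            ["H", "L", "H", "L"],
        )
        pairs = pair_patent_text(pool)
        assert [(p.heavy.parent_record_id, p.light.parent_record_id) for p in pairs] == [
            ("p1", "p2"), ("p3", "p4")
        ]

    def test_unequal_counts_pair_nothing(self):
        pool = self._patent_pool(
            ["SEQ ID NO: 1 and SEQ ID NO: 2 with SEQ ID NO: 3, SEQ ID NO: 4, "
             "SEQ ID NO: 5."],
            ["H", "H", "L", "L", "L"],
        )
        assert pair_patent_text(pool) == []

    def test_unparseable_reference_skips_paragraph(self, caplog):
        pool = self._patent_pool(
            ["See SEQ ID NO: n/a for details.",
             "The pair is SEQ ID NO: 1 and SEQ ID NO: 2."],
            ["H", "L"],
        )
        with caplog.at_level("WARNING"):
            pairs = pair_patent_text(pool)
        assert len(pairs) == 1
        assert "unparseable" in caplog.text

    def test_explicit_seq_ids_override_deposition_index(self):
        recs = [
            (_rec("p1", source_id="PAT1", source_type="patent", seq_id=101,
                  patent_paragraphs=["SEQ ID NO: 101 and SEQ ID NO: 102."]), "H"),
            (_rec("p2", source_id="PAT1", source_type="patent", seq_id=102), "L"),
        ]
        pool = _pool(*recs, source_id="PAT1")
        (pair,) = pair_patent_text(pool)
        assert pair.heavy.parent_record_id == "p1"


class TestPositionalFallbacks:
    def test_single_vh_pairs_with_all_lights(self):
        pool = _pool((_rec("r1"), "H"), (_rec("r2"), "L"), (_rec("r3"), "L"),
                     (_rec("r4"), "L"))
        pairs = pair_unique_chain(pool)
        assert len(pairs) == 3
        assert all(p.pairing_method == "unique_chain" for p in pairs)
        assert not any(p.high_confidence for p in pairs)

    def test_two_and_two_not_unique_chain(self):
        pool = _pool((_rec("r1"), "H"), (_rec("r2"), "H"), (_rec("r3"), "L"),
                     (_rec("r4"), "L"))
        assert pair_unique_chain(pool) == []

    def test_degenerate_one_one(self):
        pool = _pool((_rec("r1"), "H"), (_rec("r2"), "L"))
        assert len(pair_unique_chain(pool)) == 1

    def test_ordered_pairs_in_deposition_order(self):
        pool = _pool((_rec("a"), "H"), (_rec("b"), "H"), (_rec("c"), "L"),
                     (_rec("d"), "L"))
        pairs = pair_ordered(pool)
        assert [(p.heavy.parent_record_id, p.light.parent_record_id) for p in pairs] == [
            ("a", "c"), ("b", "d")
        ]
        assert all(p.pairing_method == "ordered_entries" for p in pairs)

    def test_ordered_requires_equal_counts(self):
        pool = _pool((_rec("a"), "H"), (_rec("c"), "L"), (_rec("d"), "L"))
        assert pair_ordered(pool) == []


class TestCascade:
    def test_recovers_planted_ground_truth_with_method_flags(self):
        corpus = generate_corpus(CorpusSpec(seed=3))
        result = build_database(corpus.records, corpus.backend)
        recovered = {
            (e.heavy.parent_record_id, e.light.parent_record_id, e.pairing_method)
            for e in result.database.entries
        }
        assert recovered == set(map(tuple, corpus.truth.intended_pairs))
        assert sorted({r for r, _ in result.unpaired}) == sorted(
            set(corpus.truth.intended_unpaired)
        )

    def test_light_only_corpus_pairs_nothing(self):
        pool = _pool((_rec("r1"), "L"), (_rec("r2"), "L"))
        pairs, unpaired = run_pairing_cascade({"S1": pool})
        assert pairs == []
        assert len(unpaired) == 2

    def test_idempotent_on_leftovers(self):
        pool = _pool((_rec("r1"), "H"), (_rec("r2"), "H"), (_rec("r3"), "H"),
                     (_rec("r4"), "L"), (_rec("r5"), "L"))
        pairs, unpaired = run_pairing_cascade({"S1": pool})
        assert pairs == []  # 3 VH + 2 VL falls through every heuristic
        again, still_unpaired = run_pairing_cascade({"S1": pool})
        assert again == [] and still_unpaired == unpaired

    def test_confidence_flags_match_method_class(self, small_db):
        for entry in small_db.entries:
            assert entry.high_confidence == (
                entry.pairing_method in HIGH_CONFIDENCE_METHODS
            )

    def test_source_order_invariance(self):
        corpus = generate_corpus(CorpusSpec(seed=11))
        result_fwd = build_database(corpus.records, corpus.backend)
        corpus2 = generate_corpus(CorpusSpec(seed=11))
        # reverse source-block order but keep intra-source deposition order
        by_source: dict[str, list] = {}
        for rec in corpus2.records:
            by_source.setdefault(rec.source_id, []).append(rec)
        reversed_records = [r for sid in reversed(list(by_source)) for r in by_source[sid]]
        result_rev = build_database(reversed_records, corpus2.backend)
        key = lambda e: (e.heavy.parent_record_id, e.light.parent_record_id, e.pairing_method)
        assert sorted(map(key, result_fwd.database.entries)) == sorted(
            map(key, result_rev.database.entries)
        )

    def test_no_domain_in_two_pairs_outside_unique_chain(self, small_db):
        seen = set()
        for e in small_db.entries:
            if e.pairing_method == "unique_chain":
                continue
            for key in (("H", e.heavy.parent_record_id, e.heavy.domain_index),
                        ("L", e.light.parent_record_id, e.light.domain_index)):
                assert key not in seen
                seen.add(key)


class TestExternalImport:
    def test_tsv_import_maps_to_imported_method(self, tmp_path, small_db):
        import pandas as pd

        rows = [entry_to_row(e) for e in small_db.entries[:2]]
        for i, row in enumerate(rows):
            row["pair_id"] = f"ext{i}"
            row["source_type"] = ""
        path = tmp_path / "external.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        entries = import_external_pairs(path, "structure")
        assert [e.pairing_method for e in entries] == ["imported_structure"] * 2
        assert all(e.high_confidence for e in entries)
        assert entries[0].heavy.sequence == small_db.entries[0].heavy.sequence

    def test_unknown_kind_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            import_external_pairs(tmp_path / "x.tsv", "webserver")
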