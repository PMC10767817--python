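"""Shared fixtures: template-derived domains and a small synthetic corpus."""

from __future__ import annotations

import numpy as np
import pytest

from pairedab.numbering import (
    NumberedDomain,
    VH_TEMPLATE_REGIONS,
    VL_TEMPLATE_REGIONS,
    assign_labels,
)
from pairedab.pipeline import build_database
from pairedab.synth_fixtures import CorpusSpec, generate_corpus
from pairedab.targets import AntigenLexicon


def make_domain(
    chain: str,
    record_id: str = "rec",
    cdr3: str | None = None,
    mutations: dict[int, str] | None = None,
    truncate_n: int = 0,
    domain_index: int = 0,
) -> NumberedDomain:
    """A numbered domain derived from the bundled template: optional CDR3
    replacement, position-label substitutions, N-terminal truncation."""
    template = dict(VH_TEMPLATE_REGIONS if chain == "H" else VL_TEMPLATE_REGIONS)
    if cdr3 is not None:
        template["CDR3"] = cdr3
    positions = assign_labels(template)
    if mutations:
        positions = [(lab, mutations.get(lab, aa)) for lab, aa in positions]
    return NumberedDomain(
        parent_record_id=record_id,
        chain_type=chain,
        positions=positions[truncate_n:],
        n_terminal_missing=truncate_n,
        domain_index=domain_index,
    )


@pytest.fixture(scope="session")
def small_corpus():
    return generate_corpus(CorpusSpec(seed=7))


@pytest.fixture(scope="session")
def small_build(small_corpus):
    lexicon = AntigenLexicon(names=["TNF", "HER2", "CD3e", "EGFR", "IL-6", "CD20"])
    return build_database(small_corpus.records, small_corpus.backend, lexicon=lexicon)


@pytest.fixture(scope="session")
def small_db(small_build):
    return small_build.database


@pytest.fixture
def rng():
    return np.random.default_rng(42)


# -- independent oracles (deliberately naive re-implementations) -----------


def oracle_identity(query, target, selector, chains_used):
    """Brute-force position-by-position identity; union denominator."""
    chains = ("H", "L") if chains_used == "both" else (chains_used,)
    matches = occupied = 0
    for chain in chains:
        if chain not in query or chain not in target:
            continue
        q = {lab: aa for lab, aa in query[chain].positions if selector.selects(chain, lab)}
        t = {lab: aa for lab, aa in target[chain].positions if selector.selects(chain, lab)}
        for lab in set(q) | set(t):
            occupied += 1
            if lab in q and lab in t and q[lab] == t[lab]:
                matches += 1
    return matches / occupied


def oracle_cdr_rmsd(query, target):
    """Framework superposition + CDR RMSD using scipy's rotation fit."""
    from scipy.spatial.transform import Rotation

    fw = sorted(query.framework_keys() & target.framework_keys())
    q_fw = np.array([query.ca_coords[k] for k in fw])
    t_fw = np.array([target.ca_coords[k] for k in fw])
    q_mean, t_mean = q_fw.mean(axis=0), t_fw.mean(axis=0)
    rot, _ = Rotation.align_vectors(q_fw - q_mean, t_fw - t_mean)
    cdr = sorted(query.cdr_keys() & target.cdr_keys())
    q_cdr = np.array([query.ca_coords[k] for k in cdr])
    t_cdr = rot.apply(np.array([target.ca_coords[k] for k in cdr]) - t_mean) + q_mean
    return float(np.sqrt(np.mean(np.sum((t_cdr - q_cdr) ** 2, axis=1))))
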