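"""Shared fixtures and independent re-implementations of the locus criteria
used as oracles across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from tn7kit.loci import ComponentHit


def make_hit(
    gene_id: str,
    start: int,
    end: int,
    component_class: str = "TnsC",
    strand: str = "+",
    contig: str = "c1",
    score: float = 100.0,
    protein_length: int = 0,
) -> ComponentHit:
    return ComponentHit(
        contig_id=contig,
        gene_id=gene_id,
        start=start,
        end=end,
        strand=strand,
        component_class=component_class,
        score=score,
        protein_length=protein_length,
    )


def criteria_oracle(
    rows: list[dict],
    contig_length: int,
    edge_margin: int = 3000,
    operon_gap: int = 50,
) -> tuple[bool, bool, bool]:
    """Independent re-check of the three locus-selection criteria from plain
    hit rows (dicts with start/end/strand/component_class).

    Deliberately written from the rule definitions, not by calling the
    package: criterion i needs >=2 hit genes spanning >=2 distinct component
    classes (a TnsAB fusion evidences TnsA and TnsB); criterion ii needs two
    hit genes connected by a chain of codirectional neighbours each < 50 bp
    apart; criterion iii needs every hit gene >= edge_margin from both ends.
    """
    classes: set[str] = set()
    for r in rows:
        if r["component_class"] == "TnsAB":
            classes |= {"TnsA", "TnsB"}
        else:
            classes.add(r["component_class"])
    crit_i = len(rows) >= 2 and len(classes) >= 2

    ordered = sorted(rows, key=lambda r: (r["start"], r["end"]))
    crit_ii = False
    run = 1
    for a, b in zip(ordered, ordered[1:]):
        if b["strand"] == a["strand"] and b["start"] - a["end"] < operon_gap:
            run += 1
        else:
            run = 1
        if run >= 2:
            crit_ii = True
    crit_iii = all(
        r["start"] >= edge_margin and contig_length - r["end"] >= edge_margin
        for r in rows
    )
    return crit_i, crit_ii, crit_iii


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    from tn7kit.synthetic import GenomeSimConfig, gen_contigs_with_loci

    return gen_contigs_with_loci(GenomeSimConfig(seed=7))


@pytest.fixture(scope="session")
def genome_hits(small_genome):
    return [
        make_hit(
            r.gene_id,
            r.start,
            r.end,
            r.component_class,
            r.strand,
            contig=r.contig,
            score=r.score,
            protein_length=r.protein_length,
        )
        for r in small_genome.hits.itertuples(index=False)
    ]
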