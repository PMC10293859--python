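"""Locus aggregation, operon calling, filtering, and multiplicity accounting."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tn7kit.loci import (
    Locus,
    aggregate_loci,
    call_operons,
    filter_loci,
    histogram_accounting,
    load_hits,
    selector_multiplicity,
    write_hits,
)

from conftest import criteria_oracle, make_hit

# ---------------------------------------------------------------------------
# hit table I/O
# ---------------------------------------------------------------------------


class TestLoadHits:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert load_hits(p) == []

    def test_write_then_read_identity(self, tmp_path):
        hits = [
            make_hit("g1", 100, 1000, "TnsB", protein_length=300),
            make_hit("g2", 1200, 2100, "TnsC", "-", score=55.5),
            make_hit("g3", 2200, 3000, "TniQ_TnsD", protein_length=266),
        ]
        p = tmp_path / "hits.tsv"
        write_hits(hits, p)
        assert load_hits(p) == hits

    def test_inverted_coordinates_rejected_with_row_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "contig\tgene_id\tstart\tend\tstrand\tcomponent_class\tscore\n"
            "c1\tg1\t500\t100\t+\tTnsC\t10\n"
        )
        with pytest.raises(ValueError, match="row 1"):
            load_hits(p)

    def test_unknown_class_maps_to_other_with_warning(self, tmp_path):
        p = tmp_path / "odd.tsv"
        p.write_text(
            "contig\tgene_id\tstart\tend\tstrand\tcomponent_class\tscore\n"
            "c1\tg1\t100\t500\t+\tMysteryGene\t10\n"
        )
        with pytest.warns(UserWarning, match="MysteryGene"):
            (hit,) = load_hits(p)
        assert hit.component_class == "Other"

    def test_tblout_dialect(self, tmp_path):
        p = tmp_path / "hits.tblout"
        p.write_text(
            "# comment line\n"
            "c1|g1|100|1000|+ - TnsB - 1e-20 150.2 0.1\n"
            "c1|g2|1200|2100|- - TnsC - 1e-10 88.0 0.0\n"
        )
        hits = load_hits(p, dialect="tblout")
        assert [h.gene_id for h in hits] == ["g1", "g2"]
        assert hits[0].score == pytest.approx(150.2)
        assert hits[1].strand == "-"


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_oracle(hits, max_gap):
    """O(n^2) transitive closure on the 'interval gap <= max_gap' relation."""
    groups = []
    for h in hits:
        linked = [
            g
            for g in groups
            if any(
                a.contig_id == h.contig_id
                and max(a.start, h.start) - min(a.end, h.end) <= max_gap
                for a in g
            )
        ]
        merged = [h]
        for g in linked:
            merged.extend(g)
            groups.remove(g)
        groups.append(merged)
    return {
        frozenset(x.gene_id for x in g) for g in groups
    }


class TestAggregateLoci:
    def test_twenty_kb_gap_is_one_locus_one_more_bp_is_two(self):
        a = make_hit("a", 0, 1000)
        for gap, n in [(20_000, 1), (20_001, 2)]:
            b = make_hit("b", 1000 + gap, 2000 + gap)
            assert len(aggregate_loci([a, b])) == n

    def test_single_hit_is_a_single_locus(self):
        loci = aggregate_loci([make_hit("a", 10, 500)])
        assert len(loci) == 1 and loci[0].span == (10, 500)

    def test_matches_transitive_closure_oracle_on_random_hits(self, rng):
        for trial in range(10):
            hits = [
                make_hit(
                    f"g{i}",
                    s := int(rng.integers(0, 300_000)),
                    s + int(rng.integers(200, 3000)),
                    contig=f"c{rng.integers(1, 3)}",
                )
                for i in range(50)
            ]
            got = {
                frozenset(h.gene_id for h in lc.hits)
                for lc in aggregate_loci(hits, max_gap=15_000)
            }
            assert got == aggregate_oracle(hits, 15_000)

    def test_permutation_invariance_and_idempotence(self, rng):
        hits = [
            make_hit(f"g{i}", int(i * 7000), int(i * 7000 + 900)) for i in range(12)
        ]
        ref = [(lc.span, tuple(h.gene_id for h in lc.hits)) for lc in aggregate_loci(hits)]
        perm = list(hits)
        rng.shuffle(perm)
        got = [(lc.span, tuple(h.gene_id for h in lc.hits)) for lc in aggregate_loci(perm)]
        assert got == ref


# ---------------------------------------------------------------------------
# operons
# ---------------------------------------------------------------------------


def operon_oracle(genes, max_gap=50):
    """Brute-force maximal codirectional runs from the pairwise rule."""
    ordered = sorted(genes, key=lambda g: (g[1], g[2], g[0]))
    runs = []
    for g in ordered:
        if (
            runs
            and g[3] == runs[-1][-1][3]
            and g[1] - runs[-1][-1][2] < max_gap
        ):
            runs[-1].append(g)
        else:
            runs.append([g])
    return [tuple(x[0] for x in r) for r in runs]


class TestCallOperons:
    def test_forty_nine_bp_gap_operonized_fifty_is_not(self):
        for gap, n_ops in [(49, 1), (50, 2)]:
            ops = call_operons(
                [("a", 0, 1000, "+"), ("b", 1000 + gap, 2000 + gap, "+")]
            )
            assert len(ops) == n_ops

    def test_opposite_strands_never_operonized(self):
        ops = call_operons([("a", 0, 1000, "+"), ("b", 1000, 2000, "-")])
        assert len(ops) == 2

    def test_overlapping_codirectional_genes_are_operonized(self):
        (op,) = call_operons([("a", 0, 1000, "+"), ("b", 900, 1800, "+")])
        assert op.member_gene_ids == ("a", "b")
        assert op.max_internal_gap == -100

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 4000), st.integers(50, 800), st.booleans()),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_bruteforce_rule_on_arbitrary_arrangements(self, layout):
        genes = []
        cursor = 0
        for jump, length, fwd in layout:
            start = cursor + jump
            genes.append((f"g{len(genes)}", start, start + length, "+" if fwd else "-"))
            cursor = start + length
        got = [op.member_gene_ids for op in call_operons(genes)]
        assert got == operon_oracle(genes)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


class TestFilterLoci:
    def test_two_hits_of_one_class_fail_distinct_components(self):
        hits = [make_hit("a", 10_000, 11_000), make_hit("b", 11_020, 12_000)]
        (locus,) = filter_loci(aggregate_loci(hits), {"c1": 50_000})
        assert locus.distinct_components is False
        assert locus.operonized_pair is True
        assert not locus.accepted

    def test_operonized_distinct_pair_mid_contig_accepted(self):
        hits = [
            make_hit("a", 10_000, 11_000, "TnsB"),
            make_hit("b", 11_020, 12_000, "TnsC"),
        ]
        (locus,) = filter_loci(aggregate_loci(hits), {"c1": 50_000})
        assert locus.criteria_flags == (True, True, True) and locus.accepted

    def test_tnsab_fusion_counts_as_two_components(self):
        hits = [
            make_hit("a", 10_000, 11_000, "TnsAB"),
            make_hit("b", 11_020, 12_000, "TnsB"),
        ]
        (locus,) = filter_loci(aggregate_loci(hits), {"c1": 50_000})
        assert locus.distinct_components is True

    def test_edge_rule_polarity(self):
        hits = [
            make_hit("a", 200, 1200, "TnsB"),
            make_hit("b", 1220, 2200, "TnsC"),
        ]
        (far,) = filter_loci(aggregate_loci(hits), {"c1": 50_000})
        assert far.boundary_ok is False and not far.accepted
        (near,) = filter_loci(
            aggregate_loci(hits), {"c1": 50_000}, edge_rule="require_near"
        )
        assert near.boundary_ok is True and near.accepted

    def test_unknown_contig_raises(self):
        with pytest.raises(KeyError, match="unknown contig"):
            filter_loci(aggregate_loci([make_hit("a", 10, 500)]), {"other": 1000})

    def test_planted_genomes_recovered_exactly(self, small_genome, genome_hits):
        """On a noiseless synthetic genome, accepted loci = planted loci."""
        contig_lengths = {c: len(s) for c, s in small_genome.contigs.items()}
        gene_table = list(
            small_genome.genes[["contig", "gene_id", "start", "end", "strand"]]
            .itertuples(index=False, name=None)
        )
        loci = filter_loci(
            aggregate_loci(genome_hits), contig_lengths, gene_table=gene_table
        )
        accepted = {(lc.contig_id, lc.span) for lc in loci if lc.accepted}
        planted = {
            (t["contig"], tuple(t["span"])) for t in small_genome.truth["loci"]
        }
        assert accepted == planted

    def test_flags_agree_with_independent_criteria_oracle(self, small_genome, genome_hits):
        contig_lengths = {c: len(s) for c, s in small_genome.contigs.items()}
        loci = filter_loci(aggregate_loci(genome_hits), contig_lengths)
        for lc in loci:
            rows = [
                {
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                    "component_class": h.component_class,
                }
                for h in lc.hits
            ]
            assert lc.criteria_flags == criteria_oracle(
                rows, contig_lengths[lc.contig_id]
            )


# ---------------------------------------------------------------------------
# multiplicity accounting
# ---------------------------------------------------------------------------


class TestMultiplicity:
    def _accepted_locus(self, hits):
        lc = Locus("c1", (hits[0].start, hits[-1].end), list(hits))
        lc.distinct_components = lc.operonized_pair = lc.boundary_ok = True
        return lc

    def test_histogram_over_selector_counts(self):
        l1 = self._accepted_locus(
            [make_hit("a", 0, 900, "TnsC")]
            + [make_hit(f"q{i}", 1000 + i * 1000, 1900 + i * 1000, "TniQ_TnsD") for i in range(3)]
        )
        l2 = self._accepted_locus([make_hit("b", 0, 900, "TnsC")])
        assert selector_multiplicity([l1, l2]) == {0: 1, 3: 1}

    def test_accounting_closed_forms(self):
        assert histogram_accounting({}) == (0, 0)
        assert histogram_accounting({2: 50}) == (50, 100)

    def test_accounting_on_survey_histogram(self):
        """The published selector-multiplicity histogram implies 1,048 tandem
        loci and 5,072 selector genes in total."""
        hist = {1: 2905, 2: 998, 3: 33, 4: 14, 5: 2, 6: 1}
        tandem, total = histogram_accounting(hist)
        assert (tandem, total) == (1048, 5072)
        assert sum(n for m, n in hist.items() if m > 2) == 50
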