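"""Selector association, size classification, and neighborhood annotation."""

from __future__ import annotations

import itertools

import pytest

from conftest import make_hit
from tn7kit.loci import call_operons
from tn7kit.selectors import (
    RATIONALE_FALLBACK,
    RATIONALE_SOLE,
    annotate_neighborhood,
    associate_selectors,
    classify_selector,
    find_partner_candidates,
    interval_distance,
    pick_representative_selectors,
)


def _operons(*hits):
    return call_operons([(h.gene_id, h.start, h.end, h.strand) for h in hits])


class TestAssociateSelectors:
    def test_sole_tnsc_claims_all_vicinity_selectors(self):
        rep = make_hit("tnsC1", 10_000, 11_000, "TnsC")
        sels = [
            make_hit("q1", 12_000, 13_000, "TniQ_TnsD"),
            make_hit("q2", 14_000, 15_500, "TniQ_TnsD"),
        ]
        a = associate_selectors(rep, [rep], sels, [], [])
        assert a.associated == ["q1", "q2"]
        assert set(a.rationale.values()) == {RATIONALE_SOLE}

    def test_non_tnsc_representative_rejected(self):
        with pytest.raises(ValueError, match="not a TnsC"):
            associate_selectors(
                make_hit("q", 0, 900, "TniQ_TnsD"), [], [], [], []
            )

    def test_decision_table_over_all_configurations(self):
        """Enumerate (other tnsC present, other closer, other operonized with
        tnsB) and compare against the written association rule."""
        rep = make_hit("rep", 0, 1000, "TnsC")
        sel = make_hit("q1", 15_000, 16_000, "TniQ_TnsD")
        for present, closer, has_tnsb in itertools.product([0, 1], repeat=3):
            other_pos = 17_000 if closer else 45_000
            other = make_hit("other", other_pos, other_pos + 1000, "TnsC")
            tnsb = make_hit("b", other_pos + 1020, other_pos + 2000, "TnsB")
            all_tnsc = [rep, other] if present else [rep]
            tnsb_hits = [tnsb] if has_tnsb else []
            operons = _operons(rep, sel, *(([other] if present else []) + tnsb_hits))
            a = associate_selectors(rep, all_tnsc, [sel], tnsb_hits, operons)
            # independent decision table from the rule text
            if not present:
                expect = ("kept", RATIONALE_SOLE)
            elif closer and has_tnsb:
                expect = ("moved", None)
            else:
                expect = ("kept", RATIONALE_FALLBACK)
            if expect[0] == "kept":
                assert a.associated == ["q1"], (present, closer, has_tnsb)
                assert a.rationale["q1"] == expect[1]
            else:
                assert a.associated == [] and a.reassigned == {"q1": "other"}

    def test_distance_tie_favours_representative(self):
        rep = make_hit("rep", 0, 1000, "TnsC")
        other = make_hit("other", 30_000, 31_000, "TnsC")
        tnsb = make_hit("b", 31_020, 32_000, "TnsB")
        sel = make_hit("q1", 15_000, 16_000, "TniQ_TnsD")  # 14,000 bp to both
        a = associate_selectors(
            rep, [rep, other], [sel], [tnsb], _operons(rep, sel, other, tnsb)
        )
        assert a.associated == ["q1"]

    def test_partition_every_vicinity_selector_assigned_once(self, small_genome, genome_hits):
        by_contig: dict[str, list] = {}
        for h in genome_hits:
            by_contig.setdefault(h.contig_id, []).append(h)
        genes = small_genome.genes
        for contig, hits in by_contig.items():
            tnsc = [h for h in hits if h.component_class == "TnsC"]
            sels = [h for h in hits if h.component_class == "TniQ_TnsD"]
            tnsb = [h for h in hits if h.component_class in ("TnsB", "TnsAB")]
            # operon structure over the full gene table, so that non-hit
            # cargo genes can glue the transposase operon together
            sub = genes[genes.contig == contig]
            operons = call_operons(
                list(sub[["gene_id", "start", "end", "strand"]].itertuples(index=False, name=None))
            )
            claimed: list[str] = []
            for rep in tnsc:
                a = associate_selectors(rep, tnsc, sels, tnsb, operons)
                claimed += a.associated
            near_any = {
                s.gene_id
                for s in sels
                if any(interval_distance(s, t) <= 50_000 for t in tnsc)
            }
            # each selector near at least one tnsC is claimed by exactly one
            assert sorted(claimed) == sorted(set(claimed))
            assert set(claimed) == near_any

    def test_invariance_under_coordinate_translation_and_strand_flip(self):
        rep = make_hit("rep", 5_000, 6_000, "TnsC")
        other = make_hit("other", 20_000, 21_000, "TnsC")
        tnsb = make_hit("b", 21_050, 22_000, "TnsB")
        sel = make_hit("q1", 14_000, 15_000, "TniQ_TnsD")
        base = associate_selectors(
            rep, [rep, other], [sel], [tnsb], _operons(rep, sel, other, tnsb)
        )

        def translate(h, off):
            return make_hit(
                h.gene_id, h.start + off, h.end + off, h.component_class, h.strand
            )

        tr = {h.gene_id: translate(h, 100_000) for h in [rep, other, tnsb, sel]}
        shifted = associate_selectors(
            tr["rep"],
            [tr["rep"], tr["other"]],
            [tr["q1"]],
            [tr["b"]],
            _operons(*tr.values()),
        )

        total = 120_000

        def flip(h):
            return make_hit(
                h.gene_id,
                total - h.end,
                total - h.start,
                h.component_class,
                "-" if h.strand == "+" else "+",
            )

        fl = {h.gene_id: flip(h) for h in [rep, other, tnsb, sel]}
        flipped = associate_selectors(
            fl["rep"],
            [fl["rep"], fl["other"]],
            [fl["q1"]],
            [fl["b"]],
            _operons(*fl.values()),
        )
        for variant in (shifted, flipped):
            assert variant.associated == base.associated
            assert variant.reassigned == base.reassigned


class TestClassifySelector:
    @pytest.mark.parametrize(
        "length,expected",
        [(498, "TnsD_like"), (400, "TniQ_like"), (369, "TniQ_like"), (401, "TnsD_like")],
    )
    def test_length_threshold(self, length, expected):
        assert classify_selector("g", length).selector_class == expected

    def test_non_positive_length_rejected(self):
        with pytest.raises(ValueError):
            classify_selector("g", 0)


class TestPickRepresentativeSelectors:
    def test_single_selector_returned(self):
        (only,) = pick_representative_selectors(
            [make_hit("a", 0, 900, "TniQ_TnsD", protein_length=300)]
        )
        assert only == "a"

    def test_two_largest_selected(self):
        sels = [
            make_hit("a", 0, 900, "TniQ_TnsD", protein_length=300),
            make_hit("b", 2000, 3500, "TniQ_TnsD", protein_length=500),
            make_hit("c", 5000, 6350, "TniQ_TnsD", protein_length=450),
        ]
        assert pick_representative_selectors(sels) == ["b", "c"]

    def test_matches_sort_and_take_two_oracle(self, rng):
        for _ in range(20):
            lengths = rng.integers(100, 900, size=int(rng.integers(1, 8)))
            sels = [
                make_hit(f"s{i}", i * 2000, i * 2000 + 900, "TniQ_TnsD", protein_length=int(n))
                for i, n in enumerate(lengths)
            ]
            expect = [
                s.gene_id
                for s in sorted(sels, key=lambda s: (-s.protein_length, s.start))
            ][:2]
            assert pick_representative_selectors(sels) == expect


class TestAnnotateNeighborhood:
    def _setup(self):
        center = make_hit("tnsC1", 100_000, 101_000, "TnsC")
        genes = [
            ("c1", "tnsC1", 100_000, 101_000, "+"),
            ("c1", "cas_in", 130_000, 131_000, "+"),
            ("c1", "cas_weak", 60_000, 61_000, "+"),
            ("c1", "cas_out", 152_000, 153_000, "+"),
            ("c1", "plain", 99_000, 99_800, "+"),
        ]
        profile_hits = [
            make_hit("cas_in", 130_000, 131_000, "Cas_effector", score=80.0),
            make_hit("cas_weak", 60_000, 61_000, "Cas_effector", score=24.9),
            make_hit("cas_out", 152_000, 153_000, "Cas_effector", score=99.0),
        ]
        return center, genes, profile_hits

    def test_score_threshold_and_window(self):
        center, genes, hits = self._setup()
        ann = annotate_neighborhood(center, genes, hits)
        labels = dict((g, lab) for g, lab, _ in ann.annotated)
        assert labels["cas_in"] == "Cas_effector"
        assert labels["cas_weak"] == "other"  # score 24.9 < 25
        assert "cas_out" not in labels  # 51 kb away: outside the window
        assert labels["plain"] == "other"

    def test_boundary_score_exactly_25_is_cas(self):
        center, genes, _ = self._setup()
        hits = [make_hit("cas_in", 130_000, 131_000, "Cas6", score=25.0)]
        ann = annotate_neighborhood(center, genes, hits)
        assert dict((g, l) for g, l, _ in ann.annotated)["cas_in"] == "Cas6"


class TestFindPartnerCandidates:
    def test_tnsf_discovery_pattern(self):
        """An unknown gene operonized with a short TniQ is the partner
        candidate; core transposase genes are not."""
        operons = _operons(
            make_hit("tnsC", 0, 1000, "TnsC"),
            make_hit("tniQ", 1020, 2100, "TniQ_TnsD"),
            make_hit("unknown498aa", 2120, 3614, "Other"),
        )
        classes = {"tnsC": "TnsC", "tniQ": "TniQ_TnsD", "unknown498aa": "Other"}
        assert find_partner_candidates("tniQ", operons, classes) == ["unknown498aa"]

    def test_singleton_operon_gives_nothing(self):
        operons = _operons(make_hit("tniQ", 0, 900, "TniQ_TnsD"))
        assert find_partner_candidates("tniQ", operons, {"tniQ": "TniQ_TnsD"}) == []

    def test_matches_set_difference_oracle(self, rng):
        classes_pool = ["TnsA", "TnsB", "TnsC", "TniQ_TnsD", "TnsE", "Other", "Other"]
        for _ in range(20):
            n = int(rng.integers(2, 7))
            hits = []
            cursor = 0
            for i in range(n):
                cls = classes_pool[rng.integers(0, len(classes_pool))]
                start = cursor + int(rng.integers(0, 120))
                hits.append(make_hit(f"g{i}", start, start + 800, cls))
                cursor = start + 800
            classes = {h.gene_id: h.component_class for h in hits}
            operons = _operons(*hits)
            selectors = [h.gene_id for h in hits if h.component_class == "TniQ_TnsD"]
            for sel in selectors:
                got = find_partner_candidates(sel, operons, classes)
                (op,) = [o for o in operons if sel in o.member_gene_ids]
                expect = sorted(
                    g
                    for g in op.member_gene_ids
                    if g != sel
                    and classes[g] not in {"TnsA", "TnsAB", "TnsB", "TnsC", "TniQ_TnsD", "TnsE"}
                )
                assert got == expect
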