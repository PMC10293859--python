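"""Synthetic data generators with planted ground truth.

Every input the analysis stages consume can be generated here: contigs with
planted Tn7-like loci (component genes in operons, terminal repeat arrays,
target-site duplications, and decoy hit clusters each built to violate
exactly one locus-selection criterion), junction-spanning long reads with a
controlled simple/co-integrate mixture and substitution noise, TTISS read
pairs with toy alignments, and gene trees with paralog pairs planted under
in-situ-duplication, single-origin, or null scenarios.

All generators are fully determined by their config seed.  The error model
for reads is substitution-only: the downstream anchor filters count base
mismatches, which is a Hamming contract, so indel realism is out of scope.
Coordinates are 0-based half-open internally and converted to 1-based
inclusive only at GFF3 boundaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import pysam

from .ends import revcomp
from .insertions import (
    AJ_TN6022_CLASS_ANCHORS,
    TTISS_PRESETS,
    AnchorSpec,
    TtissRule,
)
from .loci import HIT_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Minimum separation between planted items so they never co-aggregate
#: under the 20-kb locus rule.
_ITEM_SEPARATION = 20_001

DECOY_KINDS = ("single_component", "no_operon", "edge")
_KIND_VIOLATES = {
    "single_component": "distinct_components",
    "no_operon": "operonized_pair",
    "edge": "boundary_ok",
}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    """Apply exactly n_sub substitutions at distinct positions."""
    if n_sub == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        alt = [b for b in "ACGT" if b != out[pos]]
        out[pos] = alt[rng.integers(0, 3)]
    return "".join(out)


# ===========================================================================
# Genome simulation
# ===========================================================================


@dataclass(frozen=True)
class GenomeSimConfig:
    """Conditions for planting Tn7-like loci and decoys on random contigs."""

    n_contigs: int = 5
    contig_length: int = 200_000
    n_true_loci: int = 5
    n_decoy_hits: int = 30
    component_set: tuple[str, ...] = ("TnsA", "TnsB", "TnsC", "TniQ_TnsD")
    intergenic_gap: tuple[int, int] = (5, 45)  # uniform, < 50 bp: operonized
    gene_length: tuple[int, int] = (900, 1800)
    end_repeat_unit: str = "ATGCCTACGTGA"
    end_repeat_copies: int = 3
    end_repeat_spacer: int = 8
    end_repeat_max_mismatches: int = 2
    tsd_length: int = 5
    edge_margin: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.end_repeat_unit) != 12:
            raise ValueError("end_repeat_unit must be 12 nt")
        if not 0 < self.tsd_length <= 12:
            raise ValueError("tsd_length must be in 1..12")


@dataclass
class SimulatedGenome:
    contigs: dict[str, str]
    genes: pd.DataFrame  # contig, gene_id, start, end, strand
    hits: pd.DataFrame  # HIT_COLUMNS (+ decoy_kind, violates for decoys)
    truth: dict


def _build_locus_item(
    rng: np.random.Generator, cfg: GenomeSimConfig, locus_id: str
) -> dict:
    """Lay out one transposon relative to its own origin (position 0 =
    left boundary).  Returns genes, overlay sequences, and truth fields."""
    unit, spacer = cfg.end_repeat_unit, cfg.end_repeat_spacer
    array_parts: list[str] = []
    for k in range(cfg.end_repeat_copies):
        n_mm = 0 if k == 0 else int(rng.integers(0, cfg.end_repeat_max_mismatches + 1))
        array_parts.append(_mutate(rng, unit, n_mm))
    left_array = (_random_seq(rng, spacer)).join(array_parts)
    array_parts = []
    for k in range(cfg.end_repeat_copies):
        n_mm = 0 if k == cfg.end_repeat_copies - 1 else int(
            rng.integers(0, cfg.end_repeat_max_mismatches + 1)
        )
        array_parts.append(_mutate(rng, unit, n_mm))
    right_array = (_random_seq(rng, spacer)).join(array_parts)

    # one operonized non-component cargo gene (a partner-selector candidate)
    # sits inside the run of component genes so the hit-gene span stays close
    # to both terminal repeat arrays
    plan: list[tuple[str, str | None, bool]] = []
    for i, cls in enumerate(cfg.component_set):
        plan.append((f"{locus_id}_g{i + 1}", cls, True))
    plan.insert(min(2, len(plan)), (f"{locus_id}_cargo", None, False))

    genes = []
    cursor = len(left_array) + 150
    for gene_id, cls, is_hit in plan:
        glen = int(rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1))
        genes.append(
            {
                "gene_id": gene_id,
                "start": cursor,
                "end": cursor + glen,
                "strand": "+",
                "component_class": cls,
                "is_hit": is_hit,
            }
        )
        cursor += glen + int(
            rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1)
        )
    cursor += 150
    total = cursor + len(right_array)
    tsd = _random_seq(rng, cfg.tsd_length)
    return {
        "genes": genes,
        "overlays": [(0, left_array), (cursor, right_array)],
        "length": total,
        "tsd": tsd,
        "locus_id": locus_id,
    }


def _build_decoy_item(
    rng: np.random.Generator, cfg: GenomeSimConfig, kind: str, decoy_id: str, index: int
) -> dict:
    lo, hi = cfg.gene_length
    g1 = int(rng.integers(lo, hi + 1))
    g2 = int(rng.integers(lo, hi + 1))
    if kind == "single_component":
        # two operonized genes, one component class: violates criterion i only
        classes, strands = ("TnsC", "TnsC"), ("+", "+")
        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
    elif kind == "no_operon":
        # distinct classes mid-contig but never operonized: criterion ii only;
        # alternate between a wide gap and an antisense arrangement
        classes = ("TnsB", "TnsC")
        if index % 2 == 0:
            strands, gap = ("+", "+"), int(rng.integers(60, 200))
        else:
            strands, gap = ("+", "-"), int(rng.integers(0, 40))
    elif kind == "edge":
        # a perfectly good operonized pair placed against the contig end:
        # criterion iii only
        classes, strands = ("TnsB", "TnsC"), ("+", "+")
        gap = int(rng.integers(cfg.intergenic_gap[0], cfg.intergenic_gap[1] + 1))
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    genes = [
        {
            "gene_id": f"{decoy_id}_g1",
            "start": 0,
            "end": g1,
            "strand": strands[0],
            "component_class": classes[0],
            "is_hit": True,
        },
        {
            "gene_id": f"{decoy_id}_g2",
            "start": g1 + gap,
            "end": g1 + gap + g2,
            "strand": strands[1],
            "component_class": classes[1],
            "is_hit": True,
        },
    ]
    return {
        "genes": genes,
        "overlays": [],
        "length": g1 + gap + g2,
        "kind": kind,
        "decoy_id": decoy_id,
    }


def gen_contigs_with_loci(config: GenomeSimConfig) -> SimulatedGenome:
    """Generate contigs with planted loci, decoys, and a full truth record.

    Planted loci and decoys are separated by more than 20 kb so each forms
    its own locus under aggregation.  Edge decoys are pinned against contig
    ends (at most two per contig); everything else is placed at least
    ``edge_margin`` from both ends.  Raises ``ValueError`` without partial
    output when the configured items cannot fit on the contigs.
    """
    rng = np.random.default_rng(config.seed)
    loci_items = [
        ("locus", _build_locus_item(rng, config, f"locus{i + 1}"))
        for i in range(config.n_true_loci)
    ]
    decoy_items = []
    for i in range(config.n_decoy_hits):
        kind = DECOY_KINDS[i % len(DECOY_KINDS)]
        decoy_items.append(
            ("decoy", _build_decoy_item(rng, config, kind, f"decoy{i + 1}", i))
        )

    # distribute: edge decoys to contig ends (capacity 2 per contig),
    # everything else round-robin into contig interiors
    edge_slots: list[list[dict]] = [[] for _ in range(config.n_contigs)]
    interior: list[list[tuple[str, dict]]] = [[] for _ in range(config.n_contigs)]
    c_int = c_edge = 0
    for tag, item in loci_items + decoy_items:
        if tag == "decoy" and item["kind"] == "edge":
            placed = False
            for off in range(config.n_contigs):
                ci = (c_edge + off) % config.n_contigs
                if len(edge_slots[ci]) < 2:
                    edge_slots[ci].append(item)
                    c_edge = ci + 1
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "config infeasible: more edge decoys than contig ends"
                )
        else:
            interior[c_int % config.n_contigs].append((tag, item))
            c_int += 1

    contigs: dict[str, str] = {}
    gene_rows: list[dict] = []
    hit_rows: list[dict] = []
    truth: dict = {"loci": [], "decoys": []}

    for ci in range(config.n_contigs):
        contig_id = f"contig{ci + 1}"
        seq = np.frombuffer(
            _random_seq(rng, config.contig_length).encode(), dtype=np.uint8
        ).copy()

        placements: list[tuple[int, str, dict]] = []  # (offset, tag, item)
        cursor = config.edge_margin + 500
        right_limit = config.contig_length - config.edge_margin - 500
        edge = edge_slots[ci]
        if len(edge) >= 1:
            placements.append((200, "edge_decoy", edge[0]))
            cursor = max(cursor, 200 + edge[0]["length"] + _ITEM_SEPARATION)
        if len(edge) >= 2:
            off = config.contig_length - 200 - edge[1]["length"]
            placements.append((off, "edge_decoy", edge[1]))
            right_limit = min(right_limit, off - _ITEM_SEPARATION)
        for tag, item in interior[ci]:
            offset = cursor + int(rng.integers(0, 1_000))
            if offset + item["length"] > right_limit:
                raise ValueError(
                    f"config infeasible: items do not fit on {contig_id} "
                    f"(needed past {offset + item['length']}, limit {right_limit})"
                )
            placements.append((offset, tag, item))
            cursor = offset + item["length"] + _ITEM_SEPARATION

        for offset, tag, item in placements:
            for pos, overlay in item["overlays"]:
                enc = np.frombuffer(overlay.encode(), dtype=np.uint8)
                seq[offset + pos : offset + pos + len(enc)] = enc
            if tag == "locus":
                tsd_enc = np.frombuffer(item["tsd"].encode(), dtype=np.uint8)
                t_end = offset + item["length"]
                seq[offset - len(tsd_enc) : offset] = tsd_enc
                seq[t_end : t_end + len(tsd_enc)] = tsd_enc
            for g in item["genes"]:
                start, end = offset + g["start"], offset + g["end"]
                gene_rows.append(
                    {
                        "contig": contig_id,
                        "gene_id": g["gene_id"],
                        "start": start,
                        "end": end,
                        "strand": g["strand"],
                    }
                )
                if g["is_hit"]:
                    hit_rows.append(
                        {
                            "contig": contig_id,
                            "gene_id": g["gene_id"],
                            "start": start,
                            "end": end,
                            "strand": g["strand"],
                            "component_class": g["component_class"],
                            "score": round(float(rng.uniform(50, 300)), 1),
                            "protein_length": (end - start) // 3,
                            "decoy_kind": item.get("kind"),
                            "violates": _KIND_VIOLATES.get(item.get("kind")),
                        }
                    )
            if tag == "locus":
                hit_genes = [g for g in item["genes"] if g["is_hit"]]
                truth["loci"].append(
                    {
                        "locus_id": item["locus_id"],
                        "contig": contig_id,
                        "span": [
                            offset + min(g["start"] for g in hit_genes),
                            offset + max(g["end"] for g in hit_genes),
                        ],
                        "left_end": offset,
                        "right_end": offset + item["length"],
                        "tsd": item["tsd"],
                        "gene_ids": [g["gene_id"] for g in hit_genes],
                        "component_classes": [
                            g["component_class"] for g in hit_genes
                        ],
                    }
                )
            else:
                truth["decoys"].append(
                    {
                        "decoy_id": item["decoy_id"],
                        "contig": contig_id,
                        "kind": item["kind"],
                        "violates": _KIND_VIOLATES[item["kind"]],
                        "gene_ids": [g["gene_id"] for g in item["genes"]],
                    }
                )
        contigs[contig_id] = seq.tobytes().decode()

    genes = pd.DataFrame(
        gene_rows, columns=["contig", "gene_id", "start", "end", "strand"]
    )
    hits = pd.DataFrame(hit_rows, columns=HIT_COLUMNS + ["decoy_kind", "violates"])
    return SimulatedGenome(contigs=contigs, genes=genes, hits=hits, truth=truth)


def gen_decoy_hits(config: GenomeSimConfig) -> pd.DataFrame:
    """Decoy hit rows only (no true loci), labeled with the criterion each
    decoy is built to violate (columns ``decoy_kind`` and ``violates``)."""
    sim = gen_contigs_with_loci(dataclasses.replace(config, n_true_loci=0))
    return sim.hits


# ===========================================================================
# Junction-read simulation
# ===========================================================================


@dataclass(frozen=True)
class ReadSimConfig:
    n_reads: int = 500
    frac_simple: float = 0.609
    per_base_error: float = 0.0
    read_length: tuple[int, int] = (3_000, 6_000)
    seed: int = 0
    frac_on_target: float | None = None  # TTISS planting; frac_simple if None

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_simple <= 1.0:
            raise ValueError("frac_simple must be in [0, 1]")
        if not 0.0 <= self.per_base_error < 1.0:
            raise ValueError("per_base_error must be in [0, 1)")


@dataclass(frozen=True)
class JunctionLayout:
    """The synthetic simple-insertion product and its anchors.

    The simple product reads target-upstream | LE | cargo | RE |
    target-downstream; the co-integrate-like product retains a stretch of
    donor backbone between the left end and the cargo, displacing the
    upstream-edge-to-cargo distance.
    """

    filter_anchors: tuple[AnchorSpec, AnchorSpec, AnchorSpec]
    class_anchors: tuple[AnchorSpec, AnchorSpec, AnchorSpec, AnchorSpec]
    simple_core: str
    cointegrate_core: str
    expected_spacing: int


def build_junction_layout(
    layout_seed: int = 0,
    class_anchor_seqs: Mapping[str, str] = AJ_TN6022_CLASS_ANCHORS,
    backbone_length: int = 2_000,
) -> JunctionLayout:
    """Construct the fixed plasmid-like templates the read simulator copies.

    The four classification anchors are placed at their natural positions;
    the three 25-bp filter anchors are cut from the target fragment, LE, and
    RE regions of the template.  ``layout_seed`` fixes the random sequence
    around the anchors (it is a property of the simulated construct, not of
    a read batch).
    """
    rng = np.random.default_rng(layout_seed)
    a = class_anchor_seqs
    comm_up = _random_seq(rng, 20) + a["comM_upstream_edge"]
    le = _random_seq(rng, 470)
    cargo = _random_seq(rng, 100) + a["cargo"] + _random_seq(rng, 1_370)
    re_ = _random_seq(rng, 440) + a["end2"]
    comm_down = a["comM_downstream_edge"] + _random_seq(rng, 20)
    backbone = _random_seq(rng, backbone_length)

    simple_core = comm_up + le + cargo + re_ + comm_down
    coint_core = comm_up + le + backbone + cargo + re_ + comm_down
    class_anchors = tuple(
        AnchorSpec(name, a[name])
        for name in ("comM_downstream_edge", "end2", "comM_upstream_edge", "cargo")
    )
    filter_anchors = (
        AnchorSpec("comM_25", comm_up[5:30]),
        AnchorSpec("LE_25", le[:25]),
        AnchorSpec("RE_25", re_[200:225]),
    )
    expected = simple_core.find(a["cargo"]) - simple_core.find(
        a["comM_upstream_edge"]
    )
    return JunctionLayout(
        filter_anchors=filter_anchors,
        class_anchors=class_anchors,
        simple_core=simple_core,
        cointegrate_core=coint_core,
        expected_spacing=expected,
    )


DEFAULT_JUNCTION_LAYOUT = build_junction_layout()


@dataclass
class SimulatedReads:
    reads: list[tuple[str, str, list[int]]]  # (id, sequence, qualities)
    truth: list[dict]
    layout: JunctionLayout

    @property
    def n_simple_true(self) -> int:
        return sum(1 for t in self.truth if t["label"] == "simple")


def gen_junction_reads(
    config: ReadSimConfig, layout: JunctionLayout | None = None
) -> SimulatedReads:
    """Simulate junction-spanning nanopore-like reads.

    Each read copies the simple or co-integrate template (Bernoulli with
    ``frac_simple``), is padded with random sequence to a length drawn from
    ``read_length`` (never truncated below the template),
    reverse-complemented with probability 1/2, and subjected
    to seeded substitution noise at ``per_base_error``.  Base qualities are
    constant Q12.  The realized per-read labels are returned as truth.
    """
    layout = layout or DEFAULT_JUNCTION_LAYOUT
    rng = np.random.default_rng(config.seed)
    longest_anchor = max(
        len(a.sequence)
        for a in layout.filter_anchors + layout.class_anchors
    )
    if config.read_length[1] < longest_anchor:
        raise ValueError("anchor longer than the configured read length")
    reads: list[tuple[str, str, list[int]]] = []
    truth: list[dict] = []
    for i in range(config.n_reads):
        simple = bool(rng.random() < config.frac_simple)
        core = layout.simple_core if simple else layout.cointegrate_core
        total = int(rng.integers(config.read_length[0], config.read_length[1] + 1))
        pad = max(0, total - len(core))
        left = int(rng.integers(0, pad + 1))
        seq = _random_seq(rng, left) + core + _random_seq(rng, pad - left)
        flipped = bool(rng.random() < 0.5)
        if flipped:
            seq = revcomp(seq)
        if config.per_base_error > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            mask = rng.random(arr.size) < config.per_base_error
            if mask.any():
                shift = rng.integers(1, 4, size=int(mask.sum()))
                code = {65: 0, 67: 1, 71: 2, 84: 3}
                vals = np.array([code[b] for b in arr[mask]])
                arr[mask] = _BASES[(vals + shift) % 4]
            seq = arr.tobytes().decode()
        rid = f"read{i + 1}"
        reads.append((rid, seq, [12] * len(seq)))
        truth.append(
            {
                "read_id": rid,
                "label": "simple" if simple else "cointegrate",
                "flipped": flipped,
            }
        )
    return SimulatedReads(reads=reads, truth=truth, layout=layout)


# ===========================================================================
# TTISS simulation
# ===========================================================================


@dataclass
class TtissReference:
    sequences: dict[str, str]
    on_target_sites: tuple[tuple[str, int, int], ...]


def default_ttiss_reference(layout_seed: int = 0) -> TtissReference:
    rng = np.random.default_rng(layout_seed)
    return TtissReference(
        sequences={
            "genome": _random_seq(rng, 12_000),
            "pTarget": _random_seq(rng, 3_000),
        },
        on_target_sites=(("genome", 6_000, 6_100), ("pTarget", 1_400, 1_500)),
    )


@dataclass
class SimulatedTtiss:
    read_pairs: list[tuple[str, str, str]]  # (id, r1, r2)
    truth: list[dict]
    sam_records: list[pysam.AlignedSegment]
    header: pysam.AlignmentHeader
    rule: TtissRule

    def write_sam(self, path: str | Path) -> None:
        with pysam.AlignmentFile(str(path), "wh", header=self.header) as fh:
            for rec in self.sam_records:
                fh.write(rec)


def gen_ttiss_pairs(
    config: ReadSimConfig,
    reference: TtissReference | None = None,
    rule: TtissRule | None = None,
    n_rejected: int = 0,
) -> SimulatedTtiss:
    """Simulate TTISS read pairs plus toy exact-mapper alignments.

    ``round(frac_on_target * n_reads)`` reads are planted inside on-target
    site intervals, the rest at uniformly random off-target positions; read
    order is then shuffled.  R1 begins with the rule's terminal end sequence
    followed by ``trimmed_length_required`` bases of the insertion site; the
    toy mapper emits one alignment record per pair at the planted position,
    flagged 99 (forward) or 147 (reverse), since with planted positions an
    exact aligner is exercised, not approximated.  ``n_rejected`` extra
    records are emitted that must be excluded (wrong flag, wrong trimmed
    length, or R1 lacking the terminal end).
    """
    reference = reference or default_ttiss_reference()
    if rule is None:
        rng0 = np.random.default_rng(1_234)
        rule = TtissRule(
            terminal_end_sequence=_random_seq(rng0, TTISS_PRESETS["AjTn6022"][0]),
            trimmed_length_required=TTISS_PRESETS["AjTn6022"][1],
            on_target_sites=reference.on_target_sites,
        )
    rng = np.random.default_rng(config.seed)
    frac_on = (
        config.frac_on_target
        if config.frac_on_target is not None
        else config.frac_simple
    )
    n_on = int(round(frac_on * config.n_reads))
    tlen = rule.trimmed_length_required
    ref_names = sorted(reference.sequences)

    def off_target_position() -> tuple[str, int]:
        while True:
            ref = ref_names[rng.integers(0, len(ref_names))]
            pos = int(rng.integers(0, len(reference.sequences[ref]) - tlen - 60))
            if not any(
                ref == r and lo - tlen <= pos < hi
                for r, lo, hi in reference.on_target_sites
            ):
                return ref, pos

    plan: list[tuple[str, int, bool]] = []
    for k in range(config.n_reads):
        if k < n_on:
            r, lo, hi = reference.on_target_sites[
                rng.integers(0, len(reference.on_target_sites))
            ]
            plan.append((r, int(rng.integers(lo, hi - tlen)), True))
        else:
            ref, pos = off_target_position()
            plan.append((ref, pos, False))
    order = rng.permutation(config.n_reads)

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": len(reference.sequences[name])}
                for name in ref_names
            ],
        }
    )
    pairs, truth, records = [], [], []
    for out_i, src in enumerate(order):
        ref, pos, on = plan[src]
        rid = f"ttiss{out_i + 1}"
        refseq = reference.sequences[ref]
        insert = refseq[pos : pos + tlen]
        reverse = bool(rng.random() < 0.5)
        r1 = rule.terminal_end_sequence + insert
        r2 = revcomp(refseq[pos + 20 : pos + 20 + 30])
        pairs.append((rid, r1, r2))
        truth.append({"read_id": rid, "reference": ref, "position": pos, "on_target": on})
        rec = pysam.AlignedSegment(header)
        rec.query_name = rid
        rec.query_sequence = revcomp(insert) if reverse else insert
        rec.flag = 147 if reverse else 99
        rec.reference_id = ref_names.index(ref)
        rec.reference_start = pos
        rec.mapping_quality = 60
        rec.cigarstring = f"{tlen}M"
        records.append(rec)

    for j in range(n_rejected):
        ref, pos = off_target_position()
        rec = pysam.AlignedSegment(header)
        rec.query_name = f"reject{j + 1}"
        mode = j % 3
        if mode == 0:  # improper-pair flag
            rec.query_sequence = reference.sequences[ref][pos : pos + tlen]
            rec.flag = 83
            rec.cigarstring = f"{tlen}M"
        elif mode == 1:  # wrong trimmed length
            rec.query_sequence = reference.sequences[ref][pos : pos + tlen + 4]
            rec.flag = 99
            rec.cigarstring = f"{tlen + 4}M"
        else:  # R1 lacked the terminal end: never aligned
            pairs.append((rec.query_name, _random_seq(rng, tlen + 10), ""))
            continue
        rec.reference_id = ref_names.index(ref)
        rec.reference_start = pos
        rec.mapping_quality = 60
        records.append(rec)
    return SimulatedTtiss(
        read_pairs=pairs, truth=truth, sam_records=records, header=header, rule=rule
    )


# ===========================================================================
# Tree simulation
# ===========================================================================


@dataclass(frozen=True)
class TreeSimConfig:
    n_leaves: int = 100
    n_pairs: int = 20
    scenario: str = "null_random"  # in_situ_duplication | single_origin | null_random
    pair_branch_scale: float = 0.05
    branch_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (
            "in_situ_duplication",
            "single_origin",
            "null_random",
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if 2 * self.n_pairs > self.n_leaves:
            raise ValueError("need 2*n_pairs <= n_leaves")
        if self.pair_branch_scale < 0 or self.branch_scale <= 0:
            raise ValueError("branch scales must be positive")


def _random_join_plan(rng: np.random.Generator, n: int) -> list[tuple[int, int]]:
    """Sequence of (i, j) index joins producing a random binary topology."""
    roots = list(range(n))
    plan = []
    nxt = n
    while len(roots) > 1:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False).tolist())
        plan.append((roots[i], roots[j]))
        roots[i] = nxt
        del roots[j]
        nxt += 1
    return plan


def _tree_from_plan(
    plan: list[tuple[int, int]],
    leaf_names: list[str],
    rng: np.random.Generator,
    scale: float,
) -> dendropy.Node:
    n = len(leaf_names)
    taxa = dendropy.TaxonNamespace()
    nodes: dict[int, dendropy.Node] = {}
    for i, name in enumerate(leaf_names):
        node = dendropy.Node()
        node.taxon = taxa.require_taxon(label=name)
        nodes[i] = node
    nxt = n
    for a, b in plan:
        parent = dendropy.Node()
        for child in (nodes.pop(a), nodes.pop(b)):
            child.edge.length = float(rng.exponential(scale))
            parent.add_child(child)
        nodes[nxt] = parent
        nxt += 1
    (root,) = nodes.values()
    return root


def _finish_tree(root: dendropy.Node) -> dendropy.Tree:
    tns = dendropy.TaxonNamespace()
    labels = sorted(leaf.taxon.label for leaf in root.leaf_iter())
    for label in labels:
        tns.require_taxon(label=label)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    for leaf in root.leaf_iter():
        leaf.taxon = tns.get_taxon(leaf.taxon.label)
    return tree


def gen_tree_with_pairs(config: TreeSimConfig) -> tuple[str, list[tuple[str, str]]]:
    """Generate a newick tree and labeled paralog pairs under a scenario.

    * ``in_situ_duplication`` — pair members are cherries attached where a
      single ancestral leaf stood, with within-pair branch lengths drawn at
      ``pair_branch_scale`` (mean), so within-pair distances shrink with the
      scale.
    * ``single_origin`` — all first members form one clade and all second
      members a mirror clade (one ancestral duplication).
    * ``null_random`` — pairs are uniformly random disjoint leaf couples on
      a plain random tree.
    """
    rng = np.random.default_rng(config.seed)
    n, npair = config.n_leaves, config.n_pairs

    if config.scenario == "in_situ_duplication":
        n_base = n - npair
        base_names = [f"L{i + 1}" for i in range(n_base)]
        plan = _random_join_plan(rng, n_base)
        root = _tree_from_plan(plan, base_names, rng, config.branch_scale)
        chosen = rng.choice(n_base, size=npair, replace=False)
        pairs = []
        leaves = {leaf.taxon.label: leaf for leaf in root.leaf_iter()}
        for k, idx in enumerate(sorted(chosen.tolist())):
            leaf = leaves[base_names[idx]]
            leaf.taxon = None
            a, b = f"P{k + 1}a", f"P{k + 1}b"
            taxa = dendropy.TaxonNamespace()
            for name in (a, b):
                child = dendropy.Node()
                child.taxon = taxa.require_taxon(label=name)
                child.edge.length = float(rng.exponential(config.pair_branch_scale))
                leaf.add_child(child)
            pairs.append((a, b))
        tree = _finish_tree(root)
    elif config.scenario == "single_origin":
        plan = _random_join_plan(rng, npair)
        root_a = _tree_from_plan(
            plan, [f"P{k + 1}a" for k in range(npair)], rng, config.branch_scale
        )
        root_b = _tree_from_plan(
            plan, [f"P{k + 1}b" for k in range(npair)], rng, config.branch_scale
        )
        root = dendropy.Node()
        for sub in (root_a, root_b):
            sub.edge.length = float(rng.exponential(config.branch_scale))
            root.add_child(sub)
        for i in range(n - 2 * npair):  # outgroup chain outside both clades
            new_root = dendropy.Node()
            root.edge.length = float(rng.exponential(config.branch_scale))
            out = dendropy.Node()
            out.taxon = dendropy.TaxonNamespace().require_taxon(label=f"L{i + 1}")
            out.edge.length = float(rng.exponential(config.branch_scale))
            new_root.add_child(root)
            new_root.add_child(out)
            root = new_root
        pairs = [(f"P{k + 1}a", f"P{k + 1}b") for k in range(npair)]
        tree = _finish_tree(root)
    else:  # null_random
        names = [f"L{i + 1}" for i in range(n)]
        plan = _random_join_plan(rng, n)
        root = _tree_from_plan(plan, names, rng, config.branch_scale)
        tree = _finish_tree(root)
        chosen = rng.choice(n, size=2 * npair, replace=False)
        pairs = [
            (names[chosen[2 * k]], names[chosen[2 * k + 1]]) for k in range(npair)
        ]

    newick = tree.as_string(schema="newick", suppress_rooting=True)
    return newick, pairs


# ===========================================================================
# File output
# ===========================================================================


def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()],
        str(path),
        "fasta",
    )


def write_fastq(
    reads: Iterable[tuple[str, str, Sequence[int]]], path: str | Path
) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for rid, seq, quals in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    from Bio import SeqIO

    return [
        (rec.id, str(rec.seq), rec.letter_annotations["phred_quality"])
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_gene_table_tsv(genes: pd.DataFrame, path: str | Path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def write_gene_table_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for row in genes.itertuples(index=False):
        lines.append(
            "\t".join(
                [
                    row.contig,
                    "tn7kit_sim",
                    "gene",
                    str(row.start + 1),
                    str(row.end),
                    ".",
                    row.strand,
                    ".",
                    f"ID={row.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read either the flat TSV dialect or GFF3 back to 0-based half-open."""
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if first.startswith("##gff"):
        rows = []
        for line in path.read_text().splitlines():
            if line.startswith("#") or not line.strip():
                continue
            f = line.split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            rows.append(
                {
                    "contig": f[0],
                    "gene_id": attrs.get("ID", f[8]),
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "strand": f[6],
                }
            )
        return pd.DataFrame(rows, columns=["contig", "gene_id", "start", "end", "strand"])
    return pd.read_csv(path, sep="\t").astype({"start": int, "end": int})


def write_genome(sim: SimulatedGenome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.contigs, outdir / "contigs.fasta")
    write_gene_table_tsv(sim.genes, outdir / "genes.tsv")
    write_gene_table_gff3(sim.genes, outdir / "genes.gff3")
    sim.hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(json.dumps(sim.truth, indent=2) + "\n")
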