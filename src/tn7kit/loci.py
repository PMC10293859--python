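"""Locus discovery for Tn7-like transposons.

Protein-profile hits (TnsA/TnsB/TnsC/TniQ-TnsD/TnsE/...) placed on genes of a
contig are aggregated into candidate loci by genomic proximity, operon
structure is called from intergenic distances, and each locus is screened
against three selection criteria:

  i.   at least two hit genes from at least two distinct transposon components,
  ii.  at least two hit genes share a putative operon (codirectional ORFs
       separated by less than 50 bp of non-coding sequence),
  iii. all hit genes lie at least ``edge_margin`` bp away from both contig
       ends, so that truncated elements on contig edges are removed.

All coordinates are 0-based half-open.  Intergenic gaps are measured from the
end of the upstream feature to the start of the downstream feature; overlapping
features have a negative gap.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Recognised transposon component classes.  ``TnsAB`` is a natural
#: TnsA-TnsB fusion gene; for criterion i it contributes both activities.
COMPONENT_CLASSES = frozenset(
    {
        "TnsA",
        "TnsAB",
        "TnsB",
        "TnsC",
        "TniQ_TnsD",
        "TnsE",
        "TnsF",
        "Cas_effector",
        "Cas6",
        "Other",
    }
)

#: Classes considered core Tn7 machinery when searching for non-Tn7 partner
#: genes in an operon with a target selector.
TN7_COMPONENT_CLASSES = frozenset(
    {"TnsA", "TnsAB", "TnsB", "TnsC", "TniQ_TnsD", "TnsE"}
)

DEFAULT_AGGREGATION_GAP = 20_000
DEFAULT_OPERON_GAP = 50
DEFAULT_EDGE_MARGIN = 3_000

HIT_COLUMNS = [
    "contig",
    "gene_id",
    "start",
    "end",
    "strand",
    "component_class",
    "score",
    "protein_length",
]


@dataclass(frozen=True)
class ComponentHit:
    """A protein-profile hit placed on a gene of a contig."""

    contig_id: str
    gene_id: str
    start: int
    end: int
    strand: str
    component_class: str
    score: float
    protein_length: int = 0

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"hit {self.gene_id}: start must be < end "
                f"(got {self.start}..{self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"hit {self.gene_id}: bad strand {self.strand!r}")
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValueError(f"hit {self.gene_id}: score must be finite")

    @property
    def component_classes(self) -> frozenset[str]:
        """Distinct component classes this gene evidences (fusions give two)."""
        if self.component_class == "TnsAB":
            return frozenset({"TnsA", "TnsB"})
        return frozenset({self.component_class})


@dataclass(frozen=True)
class Operon:
    """A maximal run of codirectional genes with short intergenic gaps."""

    member_gene_ids: tuple[str, ...]
    strand: str
    max_internal_gap: int


@dataclass
class Locus:
    """A maximal cluster of component hits on one contig."""

    contig_id: str
    span: tuple[int, int]
    hits: list[ComponentHit]
    operons: list[Operon] = field(default_factory=list)
    distinct_components: bool | None = None
    operonized_pair: bool | None = None
    boundary_ok: bool | None = None

    @property
    def criteria_flags(self) -> tuple[bool | None, bool | None, bool | None]:
        return (self.distinct_components, self.operonized_pair, self.boundary_ok)

    @property
    def accepted(self) -> bool:
        return bool(
            self.distinct_components and self.operonized_pair and self.boundary_ok
        )


# ---------------------------------------------------------------------------
# Hit table I/O
# ---------------------------------------------------------------------------


def _hit_from_row(row: Mapping, idx: int) -> ComponentHit:
    try:
        start, end = int(row["start"]), int(row["end"])
        cls = str(row["component_class"])
        if cls not in COMPONENT_CLASSES:
            import warnings

            warnings.warn(
                f"row {idx}: unknown component class {cls!r} mapped to 'Other'",
                stacklevel=3,
            )
            cls = "Other"
        return ComponentHit(
            contig_id=str(row["contig"]),
            gene_id=str(row["gene_id"]),
            start=start,
            end=end,
            strand=str(row["strand"]),
            component_class=cls,
            score=float(row["score"]),
            protein_length=int(row.get("protein_length", 0) or 0),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed hit row {idx}: {exc}") from exc


def load_hits(path: str | Path, dialect: str = "tsv") -> list[ComponentHit]:
    """Read a hit table.

    ``dialect="tsv"`` expects a header line with the columns
    ``contig  gene_id  start  end  strand  component_class  score``
    (``protein_length`` optional).  ``dialect="tblout"`` accepts an
    hmmsearch-tblout-like whitespace table whose first column encodes the gene
    placement as ``contig|gene_id|start|end|strand``, the third column the
    profile (component class) name and the sixth column the full-sequence
    score, with ``#`` comment lines ignored.
    """
    path = Path(path)
    if dialect == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            return []
        hits = [
            _hit_from_row(row, idx)
            for idx, row in enumerate(df.to_dict(orient="records"), start=1)
        ]
    elif dialect == "tblout":
        hits = []
        idx = 0
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            idx += 1
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"malformed hit row {idx}: expected >=6 fields")
            target = fields[0].split("|")
            if len(target) != 5:
                raise ValueError(
                    f"malformed hit row {idx}: target name must be "
                    "contig|gene_id|start|end|strand"
                )
            contig, gene_id, start, end, strand = target
            hits.append(
                _hit_from_row(
                    {
                        "contig": contig,
                        "gene_id": gene_id,
                        "start": start,
                        "end": end,
                        "strand": strand,
                        "component_class": fields[2],
                        "score": fields[5],
                    },
                    idx,
                )
            )
    else:
        raise ValueError(f"unknown hit-table dialect {dialect!r}")
    for i, h in enumerate(hits, start=1):
        if h.end - h.start <= 0:
            raise ValueError(f"row {i}: zero-length gene {h.gene_id}")
    return hits


def write_hits(hits: Iterable[ComponentHit], path: str | Path) -> None:
    """Write hits as the flat TSV dialect understood by :func:`load_hits`."""
    rows = [
        {
            "contig": h.contig_id,
            "gene_id": h.gene_id,
            "start": h.start,
            "end": h.end,
            "strand": h.strand,
            "component_class": h.component_class,
            "score": h.score,
            "protein_length": h.protein_length,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Aggregation and operon calling
# ---------------------------------------------------------------------------


def aggregate_loci(
    hits: Sequence[ComponentHit], max_gap: int = DEFAULT_AGGREGATION_GAP
) -> list[Locus]:
    """Cluster hits into loci by single-linkage on the inter-hit interval gap.

    Hits on the same contig whose interval gap (start of the downstream hit
    minus the running maximum end of the cluster) is no further than
    ``max_gap`` bp belong to one locus.  Loci are maximal and the result is
    independent of the input order of ``hits``.
    """
    loci: list[Locus] = []
    by_contig: dict[str, list[ComponentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    for contig_id in sorted(by_contig):
        chits = sorted(by_contig[contig_id], key=lambda h: (h.start, h.end, h.gene_id))
        cluster: list[ComponentHit] = []
        cluster_end = None
        for h in chits:
            if cluster and h.start - cluster_end > max_gap:
                loci.append(_make_locus(contig_id, cluster))
                cluster = []
                cluster_end = None
            cluster.append(h)
            cluster_end = h.end if cluster_end is None else max(cluster_end, h.end)
        if cluster:
            loci.append(_make_locus(contig_id, cluster))
    return loci


def _make_locus(contig_id: str, cluster: list[ComponentHit]) -> Locus:
    return Locus(
        contig_id=contig_id,
        span=(min(h.start for h in cluster), max(h.end for h in cluster)),
        hits=list(cluster),
    )


def call_operons(
    genes: Sequence[tuple[str, int, int, str]], max_gap: int = DEFAULT_OPERON_GAP
) -> list[Operon]:
    """Call operons as maximal runs of codirectional genes with gaps < max_gap.

    ``genes`` are ``(gene_id, start, end, strand)`` tuples; they are sorted by
    start internally.  The gap between adjacent genes is
    ``next.start - prev.end``; overlapping codirectional genes (negative gap)
    are operonized.  A strand switch or a gap of ``max_gap`` or more breaks the
    run.  Singleton runs are reported as single-member operons.
    """
    ordered = sorted(genes, key=lambda g: (g[1], g[2], g[0]))
    operons: list[Operon] = []
    run: list[tuple[str, int, int, str]] = []
    gaps: list[int] = []
    for g in ordered:
        if run:
            prev = run[-1]
            gap = g[1] - prev[2]
            if g[3] == prev[3] and gap < max_gap:
                run.append(g)
                gaps.append(gap)
                continue
            operons.append(
                Operon(tuple(x[0] for x in run), run[0][3], max(gaps, default=0))
            )
        run = [g]
        gaps = []
    if run:
        operons.append(Operon(tuple(x[0] for x in run), run[0][3], max(gaps, default=0)))
    return operons


# ---------------------------------------------------------------------------
# Locus filtering
# ---------------------------------------------------------------------------


def filter_loci(
    loci: Iterable[Locus],
    contig_lengths: Mapping[str, int],
    edge_margin: int = DEFAULT_EDGE_MARGIN,
    operon_gap: int = DEFAULT_OPERON_GAP,
    gene_table: Sequence[tuple[str, str, int, int, str]] | None = None,
    edge_rule: str = "require_far",
) -> list[Locus]:
    """Set the three criteria flags on each locus and return them.

    Operons are called on the locus hit genes, or — when ``gene_table`` rows
    ``(contig, gene_id, start, end, strand)`` are supplied — on every annotated
    gene overlapping the locus span, so that non-hit genes can glue or break
    an operon.  ``edge_rule="require_far"`` (default) accepts a locus only if
    all hit genes are at least ``edge_margin`` bp from both contig ends;
    ``"require_near"`` applies the opposite (literal) polarity.
    """
    if edge_rule not in ("require_far", "require_near"):
        raise ValueError(f"unknown edge_rule {edge_rule!r}")
    out = []
    for locus in loci:
        if locus.contig_id not in contig_lengths:
            raise KeyError(f"locus references unknown contig {locus.contig_id!r}")
        clen = contig_lengths[locus.contig_id]
        locus.hits.sort(key=lambda h: (h.start, h.end, h.gene_id))

        classes: set[str] = set()
        for h in locus.hits:
            classes |= h.component_classes
        locus.distinct_components = len(locus.hits) >= 2 and len(classes) >= 2

        if gene_table is not None:
            lo, hi = locus.span
            genes = [
                (gid, s, e, st)
                for (ctg, gid, s, e, st) in gene_table
                if ctg == locus.contig_id and s < hi and e > lo
            ]
        else:
            genes = [(h.gene_id, h.start, h.end, h.strand) for h in locus.hits]
        locus.operons = call_operons(genes, max_gap=operon_gap)
        hit_ids = {h.gene_id for h in locus.hits}
        locus.operonized_pair = any(
            sum(1 for gid in op.member_gene_ids if gid in hit_ids) >= 2
            for op in locus.operons
        )

        far = all(
            h.start >= edge_margin and clen - h.end >= edge_margin
            for h in locus.hits
        )
        locus.boundary_ok = far if edge_rule == "require_far" else not far
        out.append(locus)
    return out


# ---------------------------------------------------------------------------
# Selector multiplicity accounting
# ---------------------------------------------------------------------------


def selector_multiplicity(loci: Iterable[Locus]) -> dict[int, int]:
    """Histogram of TniQ/TnsD gene count per accepted locus."""
    counts = Counter()
    for locus in loci:
        if not locus.accepted:
            continue
        m = sum(1 for h in locus.hits if h.component_class == "TniQ_TnsD")
        counts[m] += 1
    return dict(sorted(counts.items()))


def histogram_accounting(hist: Mapping[int, int]) -> tuple[int, int]:
    """Tandem-locus count (multiplicity >= 2) and total selector gene count."""
    tandem = sum(n for m, n in hist.items() if m >= 2)
    total = sum(m * n for m, n in hist.items())
    return tandem, total


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------


def write_loci_bed(loci: Iterable[Locus], path: str | Path) -> None:
    """BED-like TSV: contig, start, end, accepted, three criterion flags."""
    rows = []
    for lc in loci:
        rows.append(
            {
                "contig": lc.contig_id,
                "start": lc.span[0],
                "end": lc.span[1],
                "accepted": int(lc.accepted),
                "distinct_components": int(bool(lc.distinct_components)),
                "operonized_pair": int(bool(lc.operonized_pair)),
                "boundary_ok": int(bool(lc.boundary_ok)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_loci_json(loci: Iterable[Locus], path: str | Path) -> None:
    detail = []
    for lc in loci:
        detail.append(
            {
                "contig": lc.contig_id,
                "span": list(lc.span),
                "accepted": lc.accepted,
                "criteria": {
                    "distinct_components": lc.distinct_components,
                    "operonized_pair": lc.operonized_pair,
                    "boundary_ok": lc.boundary_ok,
                },
                "hits": [
                    {
                        "gene_id": h.gene_id,
                        "start": h.start,
                        "end": h.end,
                        "strand": h.strand,
                        "component_class": h.component_class,
                        "score": h.score,
                    }
                    for h in lc.hits
                ],
                "operons": [
                    {
                        "members": list(op.member_gene_ids),
                        "strand": op.strand,
                        "max_internal_gap": op.max_internal_gap,
                    }
                    for op in lc.operons
                ],
            }
        )
    Path(path).write_text(json.dumps(detail, indent=2) + "\n")
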