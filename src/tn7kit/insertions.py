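"""Insertion-junction read classification and transposition-frequency
arithmetic.

Three read-level analyses determine what a transposition reaction produced:

* **Nanopore structure counting** — long reads spanning the insertion
  junction are first screened with three 25-bp anchors (a target-gene
  fragment, the transposon left end, and the right end; up to 2 mismatches
  each) to discard low-quality and contaminating reads, then classified with
  four 30-bp anchors: reads carrying the downstream target edge and the
  distal transposon end are candidates, and the distance between the
  upstream target edge and the cargo anchor decides simple insertion versus
  co-integrate (donor backbone retained).
* **TTISS specificity** — paired-end reads whose R1 begins with the terminal
  transposon end are trimmed and aligned; alignments with the exact expected
  trimmed length and SAM flags 99/147 (proper-pair orientation) are tallied
  per insertion site as on- or off-target.
* **ddPCR frequency** — insertion frequency is inserts per template x 100.

Anchor matching is approximate string search under the Hamming metric
(substitutions only); positions are 0-based in read coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .ends import revcomp

DEFAULT_ANCHOR_MAX_MISMATCHES = 2
DEFAULT_SPACING_TOLERANCE = 50
DEFAULT_MIN_READ_LENGTH = 2_500
DEFAULT_MIN_QSCORE = 7.0

#: The four 30-bp classification anchors of the AjTn6022 nanopore insertion
#: counter: (1) downstream edge of the cloned comM 100-bp fragment, (2) the
#: end2/RE-side sequence, (3) upstream edge of the cloned comM fragment,
#: (4) cargo.
AJ_TN6022_CLASS_ANCHORS: dict[str, str] = {
    "comM_downstream_edge": "AGCGGGCCGGGAACTCGGCGCGGCGGGCTG",
    "end2": "GGACTGGGATTCTCCAATATTCCTTAGCGC",
    "comM_upstream_edge": "CACGGCTTCGACCGCAGCACTGGTCGGTGG",
    "cargo": "GTCGGGGGGATCCACTAGTGAGCTCATGCA",
}

#: TTISS trim/length presets: AjTn6022 trims 29 bp of RE leaving 16-bp R1;
#: ZooTsy trims 36 bp of end1 leaving 39-bp R1.
TTISS_PRESETS: dict[str, tuple[int, int]] = {
    "AjTn6022": (29, 16),
    "ZooTsy": (36, 39),
}


@dataclass(frozen=True)
class AnchorSpec:
    name: str
    sequence: str
    max_mismatches: int = DEFAULT_ANCHOR_MAX_MISMATCHES
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"anchor {self.name}: empty sequence")
        if self.max_mismatches < 0:
            raise ValueError(f"anchor {self.name}: negative mismatch budget")


@dataclass(frozen=True)
class ReadQC:
    min_length: int = DEFAULT_MIN_READ_LENGTH
    min_qscore: float = DEFAULT_MIN_QSCORE

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_qscore < 0:
            raise ValueError("QC thresholds must be >= 0")


@dataclass
class InsertionCall:
    read_id: str
    call: str  # 'simple' | 'non_simple' | 'unclassified'
    anchor_positions: dict[str, int] = field(default_factory=dict)
    observed_spacing: int | None = None


@dataclass(frozen=True)
class TtissRule:
    terminal_end_sequence: str
    trimmed_length_required: int
    accepted_flags: frozenset[int] = frozenset({99, 147})
    on_target_sites: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.trimmed_length_required <= 0:
            raise ValueError("trimmed_length_required must be > 0")


@dataclass
class TtissTally:
    on_target_reads: int = 0
    off_target_reads: int = 0
    site_reads: dict[str, int] = field(default_factory=dict)
    site_unique_positions: dict[str, int] = field(default_factory=dict)

    @property
    def on_target_fraction(self) -> float | None:
        total = self.on_target_reads + self.off_target_reads
        return self.on_target_reads / total if total else None


# ---------------------------------------------------------------------------
# Anchor search
# ---------------------------------------------------------------------------


def hamming_find(read: str, anchor: AnchorSpec) -> list[tuple[int, str, int]]:
    """All windows of ``read`` within the anchor's Hamming budget.

    Returns ``(position, strand, mismatches)`` triples, 0-based positions in
    read coordinates, '+' for the anchor as given and '-' for its reverse
    complement (searched when ``search_both_strands``).  Sorted by position,
    '+' before '-' at equal positions.
    """
    read = read.upper()
    a = anchor.sequence.upper()
    if len(a) > len(read):
        raise ValueError(
            f"anchor {anchor.name} ({len(a)} nt) longer than read ({len(read)} nt)"
        )
    hits: list[tuple[int, str, int]] = []
    renc = np.frombuffer(read.encode(), dtype=np.uint8)
    n_win = len(read) - len(a) + 1
    idx = np.arange(n_win)[:, None] + np.arange(len(a))[None, :]
    windows = renc[idx]
    queries = [("+", a)]
    if anchor.search_both_strands:
        queries.append(("-", revcomp(a)))
    for strand, q in queries:
        qenc = np.frombuffer(q.encode(), dtype=np.uint8)
        dist = (windows != qenc[None, :]).sum(axis=1)
        for pos in np.flatnonzero(dist <= anchor.max_mismatches):
            hits.append((int(pos), strand, int(dist[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


# ---------------------------------------------------------------------------
# Read QC
# ---------------------------------------------------------------------------


def mean_qscore(qualities: Sequence[int]) -> float:
    """Mean Phred score over the read (arithmetic mean of per-base Q)."""
    if len(qualities) == 0:
        return 0.0
    return float(np.mean(qualities))


def qc_filter(
    reads: Iterable[tuple[str, str, Sequence[int]]], qc: ReadQC = ReadQC()
) -> list[tuple[str, str, Sequence[int]]]:
    """Retain reads strictly longer than ``min_length`` with mean QScore
    strictly above ``min_qscore``.  Reads are (id, sequence, qualities)."""
    return [
        r
        for r in reads
        if len(r[1]) > qc.min_length and mean_qscore(r[2]) > qc.min_qscore
    ]


# ---------------------------------------------------------------------------
# Nanopore insertion-structure classification
# ---------------------------------------------------------------------------


def classify_read(
    read_id: str,
    sequence: str,
    filter_anchors: Sequence[AnchorSpec],
    class_anchors: Sequence[AnchorSpec],
    expected_spacing: int,
    tolerance: int = DEFAULT_SPACING_TOLERANCE,
) -> InsertionCall:
    """Classify one junction-spanning read.

    The read must carry all three ``filter_anchors`` (else ``unclassified``).
    ``class_anchors`` are, in order: (1) downstream target edge, (2) distal
    transposon end, (3) upstream target edge, (4) cargo.  Reads with (1)+(2)
    are insertion candidates; candidates missing (3) or (4) are
    ``non_simple``; otherwise the spacing between the (3) and (4) anchor
    positions decides: within ``tolerance`` of ``expected_spacing`` is a
    simple insertion, anything else (extra sequence between target edge and
    cargo) is ``non_simple``.  Reads passing the filter but lacking (1) or
    (2) do not span the junction and stay ``unclassified``.
    """
    if len(filter_anchors) != 3 or len(class_anchors) != 4:
        raise ValueError("need exactly 3 filter anchors and 4 class anchors")
    for anchor in filter_anchors:
        if not hamming_find(sequence, anchor):
            return InsertionCall(read_id, "unclassified")
    positions: dict[str, int] = {}
    found: dict[int, list[tuple[int, str, int]]] = {}
    for k, anchor in enumerate(class_anchors):
        hits = hamming_find(sequence, anchor)
        found[k] = hits
        if hits:
            positions[anchor.name] = hits[0][0]
    if not (found[0] and found[1]):
        return InsertionCall(read_id, "unclassified", positions)
    if not (found[2] and found[3]):
        return InsertionCall(read_id, "non_simple", positions)
    spacing = abs(found[3][0][0] - found[2][0][0])
    call = "simple" if abs(spacing - expected_spacing) <= tolerance else "non_simple"
    return InsertionCall(read_id, call, positions, observed_spacing=spacing)


def count_insertions(calls: Iterable[InsertionCall]) -> dict:
    """Tally classified reads; the simple fraction excludes unclassified."""
    n_simple = n_non = n_un = 0
    for c in calls:
        if c.call == "simple":
            n_simple += 1
        elif c.call == "non_simple":
            n_non += 1
        else:
            n_un += 1
    denom = n_simple + n_non
    return {
        "n_simple": n_simple,
        "n_non_simple": n_non,
        "n_unclassified": n_un,
        "fraction_simple": (n_simple / denom) if denom else None,
    }


# ---------------------------------------------------------------------------
# TTISS specificity
# ---------------------------------------------------------------------------


def ttiss_filter_trim(
    r1_reads: Iterable[tuple[str, str]], terminal_end_sequence: str
) -> list[tuple[str, str]]:
    """Keep R1 reads beginning with the terminal transposon end and trim it."""
    end = terminal_end_sequence.upper()
    out = []
    for rid, seq in r1_reads:
        s = seq.upper()
        if s.startswith(end):
            out.append((rid, s[len(end) :]))
    return out


def ttiss_classify(
    sam: str | Path | Iterable[pysam.AlignedSegment],
    rule: TtissRule,
) -> TtissTally:
    """Tally on/off-target insertions from trimmed-R1 alignments.

    Records are kept when the aligned read length equals
    ``trimmed_length_required`` and the SAM flag is one of
    ``accepted_flags`` (99/147: both mates mapped in proper-pair
    orientation).  A kept record is on-target iff its mapped position falls
    inside one of the ``on_target_sites`` intervals (0-based half-open).
    Per-site tallies report both read counts and unique (position, strand)
    insertion positions.
    """
    if isinstance(sam, (str, Path)):
        with pysam.AlignmentFile(str(sam), "r", check_sq=False) as fh:
            try:
                records = list(fh)
            except (ValueError, OSError) as exc:
                raise ValueError(f"malformed SAM: {exc}") from exc
    else:
        records = list(sam)

    tally = TtissTally()
    seen_positions: dict[str, set[tuple[int, bool]]] = {}
    for i, rec in enumerate(records):
        if rec.is_unmapped:
            continue
        if rec.flag not in rule.accepted_flags:
            continue
        if rec.query_length != rule.trimmed_length_required:
            continue
        if rec.reference_name is None or rec.reference_start is None:
            raise ValueError(f"malformed SAM record {i}: missing alignment")
        site = None
        for ref, lo, hi in rule.on_target_sites:
            if rec.reference_name == ref and lo <= rec.reference_start < hi:
                site = f"{ref}:{lo}-{hi}"
                break
        key = site if site else f"off:{rec.reference_name}"
        tally.site_reads[key] = tally.site_reads.get(key, 0) + 1
        seen_positions.setdefault(key, set()).add(
            (rec.reference_start, rec.is_reverse)
        )
        if site:
            tally.on_target_reads += 1
        else:
            tally.off_target_reads += 1
    tally.site_unique_positions = {
        k: len(v) for k, v in seen_positions.items()
    }
    return tally


# ---------------------------------------------------------------------------
# ddPCR arithmetic
# ---------------------------------------------------------------------------


def insertion_frequency(inserts: float, templates: float) -> float:
    """Insertion frequency in percent: inserts / templates x 100."""
    if templates <= 0:
        raise ValueError("templates must be > 0")
    return 100.0 * inserts / templates


# ---------------------------------------------------------------------------
# Anchor config I/O
# ---------------------------------------------------------------------------


def anchors_from_yaml(path: str | Path) -> dict[str, list[AnchorSpec]]:
    """Load filter/class anchor sets from a YAML file with top-level keys
    ``filter_anchors`` and ``class_anchors``, each a list of mappings with
    ``name``, ``sequence`` and optional ``max_mismatches`` /
    ``search_both_strands``."""
    import yaml

    doc = yaml.safe_load(Path(path).read_text())
    out: dict[str, list[AnchorSpec]] = {}
    for key in ("filter_anchors", "class_anchors"):
        out[key] = [
            AnchorSpec(
                name=str(item["name"]),
                sequence=str(item["sequence"]),
                max_mismatches=int(
                    item.get("max_mismatches", DEFAULT_ANCHOR_MAX_MISMATCHES)
                ),
                search_both_strands=bool(item.get("search_both_strands", True)),
            )
            for item in doc.get(key, [])
        ]
    return out
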