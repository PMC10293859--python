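"""Transposon end detection from clusters of short approximate repeats, and
target-site duplication (TSD) search.

Tn7-like transposon ends carry arrays of short TnsB-binding repeats.  Ends are
located by finding, in windows flanking the span of the component genes,
clusters of 12-nt windows that agree with a consensus unit up to a small
number of mismatches and occur at least twice per end.  Boundary placement is
refined by searching for a TSD — an exact short duplication of the target
site immediately outside both ends, the signature of Tn7-type transposition.

A cluster is built by consensus closure: starting from each window as a seed,
membership (all windows within ``max_mismatches`` of the consensus, on either
strand) and the per-column majority consensus are alternately recomputed until
stable.  Because an end-repeat array is a compact tandem structure — not
matches dispersed over the whole flank — members must additionally form a
positional chain (consecutive occurrence starts no more than
``max_occurrence_gap`` apart) containing the seed, and the seed itself must
remain a member; without this, chance 12-mer matches on random sequence (a
12-nt window matches a given consensus within 3 mismatches at a rate of
~4e-4, i.e. several times per kilobase of flank) accrete into spurious
high-copy clusters.  Overlapping member windows are collapsed to the best
copy, clusters with fewer than ``min_copies`` collapsed occurrences are
dropped, and the survivors are ranked by copy number, then total mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_UNIT_LENGTH = 12
DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MIN_COPIES = 2
DEFAULT_SEARCH_WINDOW = 1_000
DEFAULT_TSD_RANGE = (3, 12)
DEFAULT_TSD_MAX_OFFSET = 2
DEFAULT_MAX_OCCURRENCE_GAP = 60
_TSD_FLANK = 16
_MAX_CLOSURE_ROUNDS = 10

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[c] for c in seq], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in sequence: {exc}") from exc


def _decode(arr: np.ndarray) -> str:
    return "".join(_CODE_BASE[int(c)] for c in arr)


@dataclass(frozen=True)
class RepeatOccurrence:
    position: int  # window start, 0-based within the searched sequence
    strand: str  # '+' if the window matches the consensus directly
    mismatches: int


@dataclass(frozen=True)
class RepeatCluster:
    consensus: str
    occurrences: tuple[RepeatOccurrence, ...]
    unit_length: int = DEFAULT_UNIT_LENGTH
    max_mismatches: int = DEFAULT_MAX_MISMATCHES
    side: str | None = None  # 'left' | 'right' when tied to a span

    @property
    def n_copies(self) -> int:
        return len(self.occurrences)

    @property
    def total_mismatches(self) -> int:
        return sum(o.mismatches for o in self.occurrences)


@dataclass(frozen=True)
class TsdHit:
    sequence: str
    left_offset: int  # bp between the word and the left boundary
    right_offset: int  # bp between the right boundary and the word


@dataclass
class EndCall:
    left_end: int
    right_end: int
    left_evidence: RepeatCluster
    right_evidence: RepeatCluster
    tsd: TsdHit | None = None
    diagnostics: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class TsyEndConfig:
    """Minimal end/homology-arm lengths sufficient for Tsy transposition."""

    end1_length: int = 135
    end2_length: int = 20
    hom1_length: int = 12
    hom2_length: int = 12

    def __post_init__(self) -> None:
        for name in ("end1_length", "end2_length", "hom1_length", "hom2_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Repeat cluster search
# ---------------------------------------------------------------------------


def find_repeat_clusters(
    flank: str,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    min_copies: int = DEFAULT_MIN_COPIES,
    search_revcomp: bool = True,
    max_occurrence_gap: int = DEFAULT_MAX_OCCURRENCE_GAP,
) -> list[RepeatCluster]:
    """Find ranked repeat clusters in ``flank`` (see module docstring).

    Both direct and inverted (reverse-complement) copies of a unit join a
    cluster when ``search_revcomp`` is on; each occurrence records its strand
    relative to the consensus.  Overlapping occurrences within a cluster are
    collapsed to the copy with fewest mismatches (ties: leftmost).
    """
    flank = flank.upper()
    n_win = len(flank) - unit_length + 1
    if n_win < 1:
        raise ValueError("flank shorter than unit_length")
    enc = _encode(flank)
    idx = np.arange(n_win)[:, None] + np.arange(unit_length)[None, :]
    fwd = enc[idx]  # (n_win, unit)
    rev = (3 - fwd)[:, ::-1] if search_revcomp else None

    seen: set[tuple] = set()
    clusters: list[RepeatCluster] = []
    for seed in range(n_win):
        consensus = fwd[seed].copy()
        prev_key = None
        members = strands = dists = None
        for _ in range(_MAX_CLOSURE_ROUNDS):
            d_fwd = (fwd != consensus[None, :]).sum(axis=1)
            if rev is not None:
                d_rev = (rev != consensus[None, :]).sum(axis=1)
                use_fwd = d_fwd <= d_rev
                dist = np.where(use_fwd, d_fwd, d_rev)
            else:
                use_fwd = np.ones(n_win, dtype=bool)
                dist = d_fwd
            member_mask = dist <= max_mismatches
            if not member_mask[seed]:
                members = None  # consensus drifted away from the seed
                break
            members = np.flatnonzero(member_mask)
            # keep only the positional chain containing the seed
            gaps = np.diff(members)
            breaks = np.flatnonzero(gaps > max_occurrence_gap)
            lo, hi = 0, members.size
            seed_at = int(np.searchsorted(members, seed))
            for b in breaks:
                if b < seed_at:
                    lo = max(lo, b + 1)
                else:
                    hi = min(hi, b + 1)
            members = members[lo:hi]
            strands = use_fwd[members]
            dists = dist[members]
            oriented = np.where(
                strands[:, None], fwd[members], rev[members] if rev is not None else 0
            )
            # per-column majority; ties -> smallest base code (A<C<G<T)
            counts = np.zeros((4, unit_length), dtype=np.int64)
            for b in range(4):
                counts[b] = (oriented == b).sum(axis=0)
            new_consensus = counts.argmax(axis=0).astype(np.uint8)
            key = (tuple(members.tolist()), new_consensus.tobytes())
            if key == prev_key:
                break
            prev_key = key
            consensus = new_consensus
        if members is None or members.size < min_copies:
            continue
        occs = _collapse_overlaps(
            [
                RepeatOccurrence(int(p), "+" if s else "-", int(d))
                for p, s, d in zip(members, strands, dists)
            ],
            unit_length,
        )
        if len(occs) < min_copies:
            continue
        pos_key = tuple(o.position for o in occs)
        if pos_key in seen:
            continue
        seen.add(pos_key)
        clusters.append(
            RepeatCluster(
                consensus=_decode(consensus),
                occurrences=tuple(occs),
                unit_length=unit_length,
                max_mismatches=max_mismatches,
            )
        )
    clusters.sort(
        key=lambda c: (-c.n_copies, c.total_mismatches, c.occurrences[0].position)
    )
    return clusters


def _collapse_overlaps(
    occs: list[RepeatOccurrence], unit_length: int
) -> list[RepeatOccurrence]:
    occs = sorted(occs, key=lambda o: o.position)
    kept: list[RepeatOccurrence] = []
    for o in occs:
        if kept and o.position < kept[-1].position + unit_length:
            if o.mismatches < kept[-1].mismatches:
                kept[-1] = o
        else:
            kept.append(o)
    return kept


# ---------------------------------------------------------------------------
# TSD search
# ---------------------------------------------------------------------------


def find_tsd(
    left_outer_flank: str,
    right_outer_flank: str,
    length_range: tuple[int, int] = DEFAULT_TSD_RANGE,
    max_offset: int = DEFAULT_TSD_MAX_OFFSET,
) -> TsdHit | None:
    """Longest exact word duplicated immediately outside both proposed ends.

    The word must end within ``max_offset`` bp of the left boundary (suffix
    side of ``left_outer_flank``) and begin within ``max_offset`` bp of the
    right boundary (prefix side of ``right_outer_flank``).  Ties between equal
    lengths are broken by total offset, i.e. the word closest to the ends.
    TSDs are exact copies of the same target site, so no mismatches are
    allowed.
    """
    if not left_outer_flank or not right_outer_flank:
        raise ValueError("flanks must be non-empty")
    lo, hi = length_range
    left = left_outer_flank.upper()
    right = right_outer_flank.upper()
    for length in range(min(hi, len(left), len(right)), lo - 1, -1):
        for total in range(0, 2 * max_offset + 1):
            for i in range(0, min(total, max_offset) + 1):
                j = total - i
                if j > max_offset:
                    continue
                if i + length > len(left) or j + length > len(right):
                    continue
                lword = left[len(left) - i - length : len(left) - i]
                rword = right[j : j + length]
                if lword == rword:
                    return TsdHit(lword, i, j)
    return None


# ---------------------------------------------------------------------------
# End calling
# ---------------------------------------------------------------------------


def call_transposon_ends(
    contig: str,
    component_span: tuple[int, int],
    search_window: int = DEFAULT_SEARCH_WINDOW,
    unit_length: int = DEFAULT_UNIT_LENGTH,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    min_copies: int = DEFAULT_MIN_COPIES,
    tsd_range: tuple[int, int] = DEFAULT_TSD_RANGE,
) -> EndCall | None:
    """Place transposon boundaries from flanking repeat clusters.

    Repeat clusters are searched in ``search_window`` bp on each side of the
    component-gene span.  Cluster pairs whose consensus units agree between
    sides (directly or reverse-complemented, within ``max_mismatches``) are
    preferred; the best pair by (copies, mismatches) provides candidate
    boundaries at its occurrence edges.  Among candidate boundary pairs the
    one supported by the longest TSD wins; outermost placement breaks ties.
    Returns ``None`` (with a log message) when either side lacks a qualifying
    cluster — absence of canonical ends is reported honestly rather than
    forcing a call.
    """
    span_lo, span_hi = component_span
    if span_lo < 0 or span_hi > len(contig) or span_lo >= span_hi:
        raise ValueError(f"component span {component_span} outside contig")
    lf_start = max(0, span_lo - search_window)
    left_flank = contig[lf_start:span_lo]
    right_flank = contig[span_hi : span_hi + search_window]
    if len(left_flank) < unit_length or len(right_flank) < unit_length:
        logger.info("no call: flank shorter than repeat unit")
        return None

    kw = dict(
        unit_length=unit_length,
        max_mismatches=max_mismatches,
        min_copies=min_copies,
    )
    left_clusters = find_repeat_clusters(left_flank, **kw)
    right_clusters = find_repeat_clusters(right_flank, **kw)
    if not left_clusters or not right_clusters:
        logger.info(
            "no call: qualifying clusters left=%d right=%d",
            len(left_clusters),
            len(right_clusters),
        )
        return None

    def consensus_distance(a: RepeatCluster, b: RepeatCluster) -> int:
        d1 = sum(x != y for x, y in zip(a.consensus, b.consensus))
        d2 = sum(x != y for x, y in zip(a.consensus, revcomp(b.consensus)))
        return min(d1, d2)

    # prefer cluster pairs sharing a consensus unit between the two sides
    # (transposon ends carry arrays of the same repeat), then copy number;
    # pairs qualify only if the consensi agree within the mismatch budget —
    # no shared unit between the flanks means no canonical ends, which is
    # reported honestly as no call
    ranked_pairs = sorted(
        ((a, b) for a in left_clusters for b in right_clusters),
        key=lambda p: (
            consensus_distance(p[0], p[1]),
            -(p[0].n_copies + p[1].n_copies),
            p[0].total_mismatches + p[1].total_mismatches,
        ),
    )
    ranked_pairs = [
        p for p in ranked_pairs if consensus_distance(p[0], p[1]) <= max_mismatches
    ]
    if not ranked_pairs:
        logger.info("no call: flank clusters do not share a consensus unit")
        return None
    cl, cr = ranked_pairs[0]

    # Boundary refinement.  Candidate boundaries sit at the outermost
    # occurrence edges (the second-outermost is also tried, tolerating one
    # chance window chained onto an array edge).  The repeat search cannot
    # fix the reading frame of the unit — a cluster shifted by a few bases
    # scores almost identically — so both boundaries are slid jointly by a
    # small offset and the position exposing a strictly adjacent TSD is
    # taken: the TSD is the signature that pins the exact ends.  The longest
    # TSD wins, then the smallest slide, then the outermost placement.
    left_bounds = sorted(lf_start + o.position for o in cl.occurrences)[:2]
    right_bounds = sorted(
        (span_hi + o.position + unit_length for o in cr.occurrences), reverse=True
    )[:2]
    max_shift = 3
    unit_content = "|".join(
        (cl.consensus, cr.consensus, revcomp(cl.consensus), revcomp(cr.consensus))
    )
    best = None
    for le0 in left_bounds:
        for re0 in right_bounds:
            for s in range(-max_shift, max_shift + 1):
                le, re_ = le0 + s, re0 + s
                if le < 1 or le > span_lo or re_ < span_hi or re_ >= len(contig):
                    continue
                tsd = find_tsd(
                    contig[max(0, le - _TSD_FLANK) : le],
                    contig[re_ : re_ + _TSD_FLANK],
                    length_range=tsd_range,
                    max_offset=0,
                )
                if tsd is None:
                    continue
                if tsd.sequence in unit_content:
                    # array content, not target sequence: a boundary slid
                    # into the repeat array duplicates the unit, not a TSD
                    continue
                # the element must begin and end with the repeat unit: the
                # terminal windows just inside the two boundaries agree with
                # each other (directly or inverted) only in the true frame
                head = contig[le : le + unit_length]
                tail = contig[re_ - unit_length : re_]
                terminal_mm = min(
                    sum(x != y for x, y in zip(head, tail)),
                    sum(x != y for x, y in zip(head, revcomp(tail))),
                )
                score = (len(tsd.sequence), -terminal_mm, -abs(s), re_ - le)
                if best is None or score > best[0]:
                    best = (score, le, re_, tsd)
    if best is not None:
        _, left_end, right_end, tsd = best
    else:  # no TSD anywhere: report the outermost boundaries as proposed
        left_end, right_end, tsd = left_bounds[0], right_bounds[0], None
    return EndCall(
        left_end=left_end,
        right_end=right_end,
        left_evidence=RepeatCluster(
            cl.consensus, cl.occurrences, unit_length, max_mismatches, side="left"
        ),
        right_evidence=RepeatCluster(
            cr.consensus, cr.occurrences, unit_length, max_mismatches, side="right"
        ),
        tsd=tsd,
    )
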