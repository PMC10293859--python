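"""Association of TniQ/TnsD target selectors with TnsC, and neighborhood
annotation around TnsC genes.

Because TniQ/TnsD genes are abundant, TnsC false positives occur among cargo
(AAA+ ATPases), and several transposons may co-occur on one contig, assigning
a selector to the right TnsC is ambiguous.  The association rule implemented
here: a representative TnsC claims every selector in its vicinity unless
another TnsC is present; a selector moves to a closer TnsC only when that
closer TnsC is operonized with a TnsB gene (evidence it belongs to a real
transposase operon), and is otherwise retained by the representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .loci import ComponentHit, Operon

DEFAULT_VICINITY = 50_000
DEFAULT_CAS_SCORE_MIN = 25.0
DEFAULT_SELECTOR_LENGTH_THRESHOLD = 400

RATIONALE_SOLE = "sole_tnsC_in_vicinity"
RATIONALE_CLOSER = "closer_tnsC_with_operonized_tnsB"
RATIONALE_FALLBACK = "fallback_to_representative"


@dataclass
class SelectorAssignment:
    """Selectors retained by one representative TnsC, with per-selector
    rationale, plus the selectors ceded to closer TnsC genes."""

    tnsC_gene_id: str
    associated: list[str] = field(default_factory=list)
    rationale: dict[str, str] = field(default_factory=dict)
    reassigned: dict[str, str] = field(default_factory=dict)
    vicinity_used: int = DEFAULT_VICINITY


@dataclass(frozen=True)
class SelectorClass:
    gene_id: str
    protein_length: int
    selector_class: str  # "TniQ_like" | "TnsD_like"


@dataclass
class NeighborhoodAnnotation:
    center_gene_id: str
    window: int
    annotated: list[tuple[str, str, float]] = field(default_factory=list)


def interval_distance(a: ComponentHit, b: ComponentHit) -> int:
    """Minimal distance between two gene intervals; 0 if they overlap."""
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def _operonized_with(
    gene_id: str, other_ids: set[str], operons: Sequence[Operon]
) -> bool:
    for op in operons:
        members = set(op.member_gene_ids)
        if gene_id in members and members & other_ids:
            return True
    return False


def associate_selectors(
    representative: ComponentHit,
    all_tnsc: Sequence[ComponentHit],
    selectors: Sequence[ComponentHit],
    tnsb_hits: Sequence[ComponentHit],
    operons: Sequence[Operon],
    vicinity: int = DEFAULT_VICINITY,
) -> SelectorAssignment:
    """Assign the TniQ/TnsD genes in the representative's vicinity.

    If no other TnsC lies within ``vicinity`` of the representative, every
    selector in the vicinity is assigned to it.  Otherwise each selector is
    ceded to the closest strictly-closer TnsC that is operonized with a TnsB;
    when no such TnsC exists the representative keeps it
    (``fallback_to_representative``).  Distance ties favour the
    representative.
    """
    if representative.component_class != "TnsC":
        raise ValueError(
            f"representative {representative.gene_id} is not a TnsC hit"
        )
    others = [
        t
        for t in all_tnsc
        if t.gene_id != representative.gene_id
        and t.contig_id == representative.contig_id
    ]
    others_near = [t for t in others if interval_distance(t, representative) <= vicinity]
    tnsb_ids = {b.gene_id for b in tnsb_hits if b.contig_id == representative.contig_id}

    assignment = SelectorAssignment(
        tnsC_gene_id=representative.gene_id, vicinity_used=vicinity
    )
    in_vicinity = [
        s
        for s in selectors
        if s.contig_id == representative.contig_id
        and interval_distance(s, representative) <= vicinity
    ]
    for sel in sorted(in_vicinity, key=lambda s: (s.start, s.gene_id)):
        if not others_near:
            assignment.associated.append(sel.gene_id)
            assignment.rationale[sel.gene_id] = RATIONALE_SOLE
            continue
        d_rep = interval_distance(sel, representative)
        closer = [
            t
            for t in others_near
            if interval_distance(sel, t) < d_rep
            and _operonized_with(t.gene_id, tnsb_ids, operons)
        ]
        if closer:
            winner = min(
                closer, key=lambda t: (interval_distance(sel, t), t.gene_id)
            )
            assignment.reassigned[sel.gene_id] = winner.gene_id
        else:
            assignment.associated.append(sel.gene_id)
            assignment.rationale[sel.gene_id] = RATIONALE_FALLBACK
    return assignment


def classify_selector(
    gene_id: str,
    protein_length: int,
    threshold: int = DEFAULT_SELECTOR_LENGTH_THRESHOLD,
) -> SelectorClass:
    """Size-based TniQ vs TnsD call: strictly longer than ``threshold`` aa is
    TnsD-like (direct target selection), otherwise TniQ-like."""
    if protein_length <= 0:
        raise ValueError(f"non-positive protein length for {gene_id}")
    cls = "TnsD_like" if protein_length > threshold else "TniQ_like"
    return SelectorClass(gene_id, protein_length, cls)


def pick_representative_selectors(
    selectors: Sequence[ComponentHit],
) -> list[str]:
    """The up-to-two largest selectors in a vicinity; ties leftmost-first."""
    ranked = sorted(
        selectors, key=lambda s: (-s.protein_length, s.start, s.gene_id)
    )
    return [s.gene_id for s in ranked[:2]]


def annotate_neighborhood(
    center: ComponentHit,
    gene_table: Sequence[tuple[str, str, int, int, str]],
    profile_hits: Sequence[ComponentHit],
    window: int = DEFAULT_VICINITY,
    cas_score_min: float = DEFAULT_CAS_SCORE_MIN,
    partner_candidates: Iterable[str] = (),
) -> NeighborhoodAnnotation:
    """Label genes within ``window`` bp of a central TnsC.

    Cas labels (Cas_effector, Cas6) require a profile-hit score of at least
    ``cas_score_min``; sub-threshold cas hits and unrecognised genes are
    labeled ``other``.  ``partner_candidates`` (from
    :func:`find_partner_candidates`) are labeled ``partner_candidate``.
    """
    hit_by_gene: dict[str, ComponentHit] = {}
    for h in profile_hits:
        if h.contig_id != center.contig_id:
            continue
        prev = hit_by_gene.get(h.gene_id)
        if prev is None or h.score > prev.score:
            hit_by_gene[h.gene_id] = h
    partner_ids = set(partner_candidates)

    ann = NeighborhoodAnnotation(center_gene_id=center.gene_id, window=window)
    for ctg, gid, s, e, strand in gene_table:
        if ctg != center.contig_id:
            continue
        dist = max(0, max(s, center.start) - min(e, center.end))
        if dist > window:
            continue
        hit = hit_by_gene.get(gid)
        score = hit.score if hit is not None else float("nan")
        if hit is not None and hit.component_class in ("Cas_effector", "Cas6"):
            label = hit.component_class if hit.score >= cas_score_min else "other"
        elif hit is not None and hit.component_class == "TnsE":
            label = "TnsE"
        elif gid in partner_ids:
            label = "partner_candidate"
        else:
            label = "other"
        ann.annotated.append((gid, label, score))
    return ann


def find_partner_candidates(
    selector_gene_id: str,
    operons: Sequence[Operon],
    component_classes: Mapping[str, str],
) -> list[str]:
    """Genes operonized with a TniQ/TnsD selector that are not themselves any
    core Tn7 component — candidate partner target selectors (the pattern that
    revealed TnsF)."""
    from .loci import TN7_COMPONENT_CLASSES

    out: list[str] = []
    for op in operons:
        if selector_gene_id not in op.member_gene_ids:
            continue
        for gid in op.member_gene_ids:
            if gid == selector_gene_id:
                continue
            if component_classes.get(gid) in TN7_COMPONENT_CLASSES:
                continue
            out.append(gid)
    return sorted(set(out))
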