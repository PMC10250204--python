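"""Long-read truncation bias correction.

Reads that do not span a transcript end to end deplete upfi counts at their
5'-most covered exon and dofi counts at their 3'-most covered exon. The
correction cuts each long read at its first and last covered exons: those
two exons and all evidence beyond them are dropped, so order counts are
extracted only for strictly interior exons of the read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from insplico.annotation import ExonEntity
from insplico.classify import DEFAULT_MIN_INTRON_OVERLAP
from insplico.evidence import FragmentEvidence


@dataclass
class TrimmedFragment:
    """A fragment after removal of its terminal covered exons."""

    fragment: FragmentEvidence
    dropped_exons: list[str]


def covered_entities(
    frag: FragmentEvidence,
    entities: Sequence[ExonEntity],
    min_overlap: int = DEFAULT_MIN_INTRON_OVERLAP,
) -> list[ExonEntity]:
    """Entities whose maximal extent overlaps a fragment block by >= min_overlap,
    in genomic order."""
    hits = []
    for ent in entities:
        lo, hi = ent.extent
        if any(min(e, hi) - max(s, lo) >= min_overlap for s, e in frag.blocks):
            hits.append(ent)
    hits.sort(key=lambda ent: ent.extent)
    return hits


def truncate_long_read(
    frag: FragmentEvidence,
    entities: Sequence[ExonEntity],
    min_overlap: int = DEFAULT_MIN_INTRON_OVERLAP,
) -> TrimmedFragment:
    """Cut a long read at its first and last covered exons.

    Evidence is kept only inside the interval between the two terminal
    covered exons (junction boundaries may sit exactly on the interval
    edges, i.e. splice sites of the dropped exons' inner boundaries are
    retained so interior exons keep their neighbor junctions). A read
    covering two or fewer exons retains no evidence.
    """
    cov = covered_entities(frag, entities, min_overlap)
    if len(cov) <= 2:
        trimmed = FragmentEvidence(
            fragment_id=frag.fragment_id,
            chrom=frag.chrom,
            blocks=[],
            junctions=[],
            mate_gap=None,
            is_long_read=frag.is_long_read,
            orientation=frag.orientation,
        )
        return TrimmedFragment(trimmed, [e.entity_id for e in cov])
    first, last = cov[0], cov[-1]
    lo = first.extent[1]
    hi = last.extent[0]
    blocks = []
    for s, e in frag.blocks:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            blocks.append((s2, e2))
    junctions = [(d, a) for d, a in frag.junctions if d >= lo and a <= hi]
    trimmed = FragmentEvidence(
        fragment_id=frag.fragment_id,
        chrom=frag.chrom,
        blocks=blocks,
        junctions=junctions,
        mate_gap=None,
        is_long_read=frag.is_long_read,
        orientation=frag.orientation,
    )
    return TrimmedFragment(trimmed, [first.entity_id, last.entity_id])


def apply_bias_correction(
    fragments: Sequence[FragmentEvidence],
    entities: Sequence[ExonEntity],
    min_overlap: int = DEFAULT_MIN_INTRON_OVERLAP,
) -> list[FragmentEvidence]:
    """Truncate every eligible long read; short/paired fragments pass through.

    A fragment is eligible when it has no mate gap and either carries the
    long-read flag or covers three or more annotated exons.
    """
    out = []
    for frag in fragments:
        if frag.mate_gap is not None:
            out.append(frag)
            continue
        if frag.is_long_read or len(covered_entities(frag, entities, min_overlap)) >= 3:
            trimmed = truncate_long_read(frag, entities, min_overlap).fragment
            if trimmed.blocks:
                out.append(trimmed)
        else:
            out.append(frag)
    return out
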