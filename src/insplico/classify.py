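"""Per-exon fragment classification into AISO and junction categories.

For a focus exon the two flanking introns are trimmed, adjacent to the
exon, to the length of the shorter one (the *effective* regions), which
removes intron-length-driven counting bias. A fragment is then labelled

* ``upfi``  — spliced junction to an upstream neighbor + unspliced downstream intron,
* ``dofi``  — unspliced upstream intron + spliced junction to a downstream neighbor,
* ``bus``   — unspliced evidence in both effective regions,
* ``bos``   — spliced junctions on both sides,

with at most one label per fragment per exon. Fragments carrying
contradictory evidence for the same intron (spliced and unspliced) are
discarded. Junction counts (``inup``, ``indo``, ``skip``) and unspliced
boundary-spanning counts feeding PIR are accumulated alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional, Sequence

import pysam

from insplico.annotation import ExonEntity
from insplico.evidence import (
    DEFAULT_TOLERANCE,
    FragmentEvidence,
    LibraryLayout,
    detect_layout,
    fuzzy_match,
    iterate_fragments,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_INTRON_OVERLAP = 6

AISO_LABELS = ("upfi", "dofi", "bus", "bos")


@dataclass
class EffectiveRegions:
    """Length-matched intronic regions flanking a focus exon.

    ``up_full``/``do_full`` are the complete introns (exon maximal extent to
    the nearest neighbor boundary); ``up_intron``/``do_intron`` are trimmed
    to the shorter intron's length, adjacent to the exon.
    """

    up_intron: tuple[int, int]
    do_intron: tuple[int, int]
    effective_length: int
    up_full: tuple[int, int]
    do_full: tuple[int, int]


@dataclass
class AISOCounts:
    """Per-exon integer counts extracted from fragments."""

    upfi: int = 0
    dofi: int = 0
    bus: int = 0
    bos: int = 0
    skip: int = 0
    inup: int = 0
    indo: int = 0
    ei_up: int = 0  # unspliced upstream-intron/exon boundary (exon side)
    ei_do: int = 0  # unspliced exon/downstream-intron boundary (exon side)
    nb_up: int = 0  # unspliced boundary at the upstream intron's neighbor side
    nb_do: int = 0  # unspliced boundary at the downstream intron's neighbor side
    discarded: int = 0

    def add(self, other: "AISOCounts") -> None:
        for f in dc_fields(self):
            setattr(self, f.name, getattr(self, f.name) + getattr(other, f.name))


def effective_regions(entity: ExonEntity) -> Optional[EffectiveRegions]:
    """Compute flanking intron regions; ``None`` when a neighbor is missing.

    Full intron extents run from the exon's maximal extent to the nearest
    neighbor boundary on each side; both are then trimmed, adjacent to the
    exon, to the shorter intron's length.
    """
    lo, hi = entity.extent
    if entity.strand == "+":
        up_cands = [c for c in entity.upstream_neighbor_ends if c <= lo]
        do_cands = [c for c in entity.downstream_neighbor_starts if c >= hi]
        if not up_cands or not do_cands:
            return None
        up_full = (max(up_cands), lo)
        do_full = (hi, min(do_cands))
    else:
        up_cands = [c for c in entity.upstream_neighbor_ends if c >= hi]
        do_cands = [c for c in entity.downstream_neighbor_starts if c <= lo]
        if not up_cands or not do_cands:
            return None
        up_full = (hi, min(up_cands))
        do_full = (max(do_cands), lo)
    up_len = up_full[1] - up_full[0]
    do_len = do_full[1] - do_full[0]
    if up_len <= 0 or do_len <= 0:
        return None
    eff = min(up_len, do_len)
    if entity.strand == "+":
        up_region = (lo - eff, lo)
        do_region = (hi, hi + eff)
    else:
        up_region = (hi, hi + eff)
        do_region = (lo - eff, lo)
    return EffectiveRegions(up_region, do_region, eff, up_full, do_full)


def _side_sets(entity: ExonEntity, side: str) -> tuple[set[int], set[int]]:
    """(donor candidates, acceptor candidates) for inclusion junctions on one side."""
    if entity.strand == "+":
        if side == "up":
            return entity.upstream_neighbor_ends, entity.starts
        return entity.ends, entity.downstream_neighbor_starts
    if side == "up":
        return entity.ends, entity.upstream_neighbor_ends
    return entity.downstream_neighbor_starts, entity.starts


def junction_evidence(
    frag: FragmentEvidence, entity: ExonEntity, side: str, tol: int = DEFAULT_TOLERANCE
) -> bool:
    """True if a fragment junction joins the exon to an annotated neighbor on ``side``."""
    donors, acceptors = _side_sets(entity, side)
    if not donors or not acceptors:
        return False
    for donor, acceptor in frag.junctions:
        if (
            fuzzy_match(donor, donors, tol) is not None
            and fuzzy_match(acceptor, acceptors, tol) is not None
        ):
            return True
    return False


def _block_overlap(frag: FragmentEvidence, region: tuple[int, int]) -> int:
    best = 0
    for s, e in frag.blocks:
        best = max(best, min(e, region[1]) - max(s, region[0]))
    return best


def intronic_evidence(
    frag: FragmentEvidence,
    region: tuple[int, int],
    min_overlap: int = DEFAULT_MIN_INTRON_OVERLAP,
    entity: Optional[ExonEntity] = None,
    side: Optional[str] = None,
    tol: int = DEFAULT_TOLERANCE,
) -> bool:
    """True iff a block overlaps the region by >= ``min_overlap`` nt and no
    junction of the fragment splices out the corresponding intron."""
    if _block_overlap(frag, region) < min_overlap:
        return False
    if entity is not None and side is not None and junction_evidence(frag, entity, side, tol):
        return False
    return True


def _skip_evidence(frag: FragmentEvidence, entity: ExonEntity, tol: int) -> bool:
    if entity.strand == "+":
        donors, acceptors = entity.upstream_neighbor_ends, entity.downstream_neighbor_starts
    else:
        donors, acceptors = entity.downstream_neighbor_starts, entity.upstream_neighbor_ends
    if not donors or not acceptors:
        return False
    for donor, acceptor in frag.junctions:
        if (
            fuzzy_match(donor, donors, tol) is not None
            and fuzzy_match(acceptor, acceptors, tol) is not None
        ):
            return True
    return False


def _spans_boundary(frag: FragmentEvidence, boundary: int, min_overlap: int) -> bool:
    for s, e in frag.blocks:
        if boundary - s >= min_overlap and e - boundary >= min_overlap:
            return True
    return False


def classify_fragment(
    frag: FragmentEvidence,
    entity: ExonEntity,
    regions: EffectiveRegions,
    tol: int = DEFAULT_TOLERANCE,
    min_overlap: int = DEFAULT_MIN_INTRON_OVERLAP,
) -> tuple[str, AISOCounts]:
    """Classify one fragment against one exon; returns (label, count increments).

    ``label`` is one of upfi/dofi/bus/bos/none. The increments also carry
    junction and boundary-spanning counts; contradictory fragments yield
    only ``discarded``.
    """
    delta = AISOCounts()
    ju = junction_evidence(frag, entity, "up", tol)
    jd = junction_evidence(frag, entity, "do", tol)
    iu = _block_overlap(frag, regions.up_intron) >= min_overlap
    idn = _block_overlap(frag, regions.do_intron) >= min_overlap

    if (ju and iu) or (jd and idn):
        delta.discarded = 1
        return "none", delta

    label = "none"
    if ju and idn:
        label = "upfi"
        delta.upfi = 1
    elif iu and jd:
        label = "dofi"
        delta.dofi = 1
    elif ju and jd:
        label = "bos"
        delta.bos = 1
    elif iu and idn:
        label = "bus"
        delta.bus = 1

    if ju:
        delta.inup = 1
    if jd:
        delta.indo = 1
    if _skip_evidence(frag, entity, tol):
        delta.skip = 1

    # unspliced boundary spans over the full introns (for PIR)
    if entity.strand == "+":
        up_nb_boundary, up_ex_boundary = regions.up_full
        do_ex_boundary, do_nb_boundary = regions.do_full
    else:
        up_ex_boundary, up_nb_boundary = regions.up_full
        do_nb_boundary, do_ex_boundary = regions.do_full
    if _spans_boundary(frag, up_ex_boundary, min_overlap):
        delta.ei_up = 1
    if _spans_boundary(frag, up_nb_boundary, min_overlap):
        delta.nb_up = 1
    if _spans_boundary(frag, do_ex_boundary, min_overlap):
        delta.ei_do = 1
    if _spans_boundary(frag, do_nb_boundary, min_overlap):
        delta.nb_do = 1
    return label, delta


def count_exon(
    entity: ExonEntity,
    fragments: Iterable[FragmentEvidence],
    tol: int = DEFAULT_TOLERANCE,
    min_overlap: int = DEFAULT_MIN_INTRON_OVERLAP,
    regions: Optional[EffectiveRegions] = None,
) -> AISOCounts:
    """Accumulate AISO counts for one exon over a set of fragments.

    Exons lacking a neighbor on either side get all-zero counts (their
    metrics are reported NA downstream).
    """
    counts = AISOCounts()
    if regions is None:
        regions = effective_regions(entity)
    if regions is None:
        return counts
    for frag in fragments:
        if frag.chrom != entity.chrom or not frag.blocks:
            continue
        _, delta = classify_fragment(frag, entity, regions, tol, min_overlap)
        counts.add(delta)
    return counts


def _keep_by_strand(frag: FragmentEvidence, entity: ExonEntity, strandedness: str) -> bool:
    if strandedness == "unstranded" or frag.orientation is None:
        return True
    if strandedness == "forward":
        return frag.orientation == entity.strand
    return frag.orientation != entity.strand


def process_bam(
    bam_path: str,
    entities: Sequence[ExonEntity],
    tol: int = DEFAULT_TOLERANCE,
    min_overlap: int = DEFAULT_MIN_INTRON_OVERLAP,
    min_mapq: int = 0,
    biascorr: bool = False,
    long_reads: bool = False,
    layout: Optional[LibraryLayout] = None,
    sample_size: int = 100_000,
) -> list[AISOCounts]:
    """Count every exon of the table against a coordinate-sorted, indexed BAM.

    Returns one :class:`AISOCounts` per input entity, in input order. When
    the library is stranded (auto-detected unless ``layout`` is given),
    fragments antisense to the focus exon are ignored. With ``biascorr``,
    long reads are cut at their first and last covered exons before
    classification.
    """
    from insplico.biascorr import apply_bias_correction

    with pysam.AlignmentFile(bam_path) as bam:
        if not bam.has_index():
            raise ValueError(f"{bam_path} has no index; coordinate-sort and index it first")
        if layout is None:
            layout = detect_layout(bam, entities, sample_size=sample_size,
                                   tol=tol, min_mapq=min_mapq)
        logger.info("library layout: paired=%s strandedness=%s", layout.paired,
                    layout.strandedness)
        by_chrom_strand: dict[tuple[str, str], list[ExonEntity]] = {}
        for ent in entities:
            by_chrom_strand.setdefault((ent.chrom, ent.strand), []).append(ent)

        results: list[AISOCounts] = []
        n_discarded = 0
        valid_chroms = set(bam.references)
        for ent in entities:
            regions = effective_regions(ent)
            if regions is None or ent.chrom not in valid_chroms:
                results.append(AISOCounts())
                continue
            coords = [*regions.up_full, *regions.do_full, *ent.extent]
            window = (min(coords) - tol, max(coords) + tol)
            frags = [
                f
                for f in iterate_fragments(
                    bam, ent.chrom, window[0], window[1],
                    min_mapq=min_mapq, long_reads=long_reads,
                )
                if _keep_by_strand(f, ent, layout.strandedness)
            ]
            if biascorr:
                frags = apply_bias_correction(
                    frags,
                    by_chrom_strand[(ent.chrom, ent.strand)],
                    min_overlap=min_overlap,
                )
            counts = count_exon(ent, frags, tol=tol, min_overlap=min_overlap, regions=regions)
            n_discarded += counts.discarded
            results.append(counts)
        logger.info("fragments discarded as contradictory: %d", n_discarded)
    return results
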