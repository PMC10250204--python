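"""Alignment evidence: fragment assembly, junction extraction, layout detection.

Coordinates are 0-based half-open throughout. A splice junction is the pair
(donor_end, acceptor_start): the exclusive end of the block preceding an N
gap and the start of the block following it.
"""

from __future__ import annotations

import bisect
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pysam

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 3

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# pysam numeric opcodes
_OPS = "MIDNSHP=X"


@dataclass
class FragmentEvidence:
    """Splice junctions and aligned blocks carried by one sequencing fragment."""

    fragment_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    junctions: list[tuple[int, int]]
    mate_gap: Optional[tuple[int, int]] = None
    is_long_read: bool = False
    orientation: Optional[str] = None  # inferred transcript strand under a forward library

    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


@dataclass
class LibraryLayout:
    """Sequencing layout inferred from the data."""

    paired: bool
    strandedness: str  # forward | reverse | unstranded


@dataclass
class FuzzyMatcher:
    """Symmetric coordinate matching within a fixed tolerance (default 3 nt)."""

    tolerance: int = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")

    def match(self, coord: int, candidates: Iterable[int]) -> Optional[int]:
        return fuzzy_match(coord, candidates, self.tolerance)


def fuzzy_match(coord: int, candidates: Iterable[int], tolerance: int = DEFAULT_TOLERANCE
                ) -> Optional[int]:
    """Candidate with smallest |offset| <= tolerance, ties toward the smaller coordinate."""
    best = None
    best_key = None
    for cand in candidates:
        key = (abs(cand - coord), cand)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    if best is None or abs(best - coord) > tolerance:
        return None
    return best


def _normalize_cigar(cigar) -> list[tuple[int, int]]:
    """Accept a CIGAR string or pysam cigartuples; return [(op_index, length), ...]."""
    if isinstance(cigar, str):
        out = []
        pos = 0
        for m in _CIGAR_RE.finditer(cigar):
            if m.start() != pos:
                raise ValueError(f"invalid CIGAR {cigar!r}")
            out.append((_OPS.index(m.group(2)), int(m.group(1))))
            pos = m.end()
        if pos != len(cigar) or not out:
            raise ValueError(f"invalid CIGAR {cigar!r}")
        return out
    return list(cigar)


def walk_cigar(cigar, pos: int) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Walk a CIGAR from reference position ``pos``; return (blocks, junctions).

    M/=/X and D advance the reference within the current block; N closes the
    block and records a junction; I/S/H/P consume no reference.
    """
    ref = pos
    block_start = pos
    blocks: list[tuple[int, int]] = []
    junctions: list[tuple[int, int]] = []
    for op, length in _normalize_cigar(cigar):
        if length < 0:
            raise ValueError("negative CIGAR length")
        if op in (0, 7, 8, 2):  # M, =, X, D
            ref += length
        elif op == 3:  # N
            if ref > block_start:
                blocks.append((block_start, ref))
            junctions.append((ref, ref + length))
            ref += length
            block_start = ref
        elif op in (1, 4, 5, 6):  # I, S, H, P
            pass
        else:
            raise ValueError(f"unknown CIGAR op index {op}")
    if ref > block_start:
        blocks.append((block_start, ref))
    return blocks, junctions


def extract_junctions(cigar, pos: int) -> list[tuple[int, int]]:
    """Junctions (donor_end, acceptor_start) implied by a CIGAR starting at ``pos``."""
    return walk_cigar(cigar, pos)[1]


def merge_blocks(blocks: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and union possibly-overlapping intervals."""
    merged: list[list[int]] = []
    for s, e in sorted(blocks):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _record_orientation(rec: pysam.AlignedSegment) -> str:
    """Fragment alignment orientation: strand of read1 (mate2 is flipped)."""
    strand = "-" if rec.is_reverse else "+"
    if rec.is_paired and rec.is_read2:
        strand = "-" if strand == "+" else "+"
    return strand


def _usable(rec: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        rec.is_unmapped
        or rec.is_secondary
        or rec.is_supplementary
        or rec.is_duplicate
        or rec.mapping_quality < min_mapq
    )


def iterate_fragments(
    bam: pysam.AlignmentFile,
    chrom: str,
    start: int,
    end: int,
    min_mapq: int = 0,
    long_reads: bool = False,
) -> Iterator[FragmentEvidence]:
    """Assemble fragments from primary alignments overlapping a region.

    Paired mates fetched within the region are joined by query name into one
    fragment (blocks unioned, junctions concatenated, insert gap recorded);
    a paired record whose mate falls outside the fetched region is emitted
    on its own. Emission order follows the leftmost record of each fragment,
    so it is independent of within-region record order.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    fragments: list[tuple[int, FragmentEvidence]] = []
    unpaired_pe = 0
    for rec in bam.fetch(chrom, max(0, start), end):
        if not _usable(rec, min_mapq):
            continue
        if rec.is_paired:
            other = pending.pop(rec.query_name, None)
            if other is None:
                pending[rec.query_name] = rec
            else:
                fragments.append(_pair_fragment(other, rec))
        else:
            fragments.append(_single_fragment(rec, long_reads))
    for rec in pending.values():
        unpaired_pe += 1
        fragments.append(_single_fragment(rec, long_reads=False, forced_paired=True))
    if unpaired_pe:
        logger.debug("%d paired records without in-region mate treated as single", unpaired_pe)
    fragments.sort(key=lambda item: (item[0], item[1].fragment_id))
    for _, frag in fragments:
        yield frag


def _single_fragment(
    rec: pysam.AlignedSegment, long_reads: bool, forced_paired: bool = False
) -> tuple[int, FragmentEvidence]:
    blocks, junctions = walk_cigar(rec.cigartuples, rec.reference_start)
    frag = FragmentEvidence(
        fragment_id=rec.query_name,
        chrom=rec.reference_name,
        blocks=merge_blocks(blocks),
        junctions=sorted(junctions),
        mate_gap=None,
        is_long_read=long_reads and not forced_paired,
        orientation=_record_orientation(rec),
    )
    return rec.reference_start, frag


def _pair_fragment(
    a: pysam.AlignedSegment, b: pysam.AlignedSegment
) -> tuple[int, FragmentEvidence]:
    blocks_a, junc_a = walk_cigar(a.cigartuples, a.reference_start)
    blocks_b, junc_b = walk_cigar(b.cigartuples, b.reference_start)
    gap = None
    end_a, end_b = blocks_a[-1][1], blocks_b[-1][1]
    lo = min(a.reference_start, b.reference_start)
    inner_lo = min(end_a, end_b)
    inner_hi = max(a.reference_start, b.reference_start)
    if inner_lo < inner_hi:
        gap = (inner_lo, inner_hi)
    read1 = a if a.is_read1 or not b.is_read1 else b
    frag = FragmentEvidence(
        fragment_id=a.query_name,
        chrom=a.reference_name,
        blocks=merge_blocks(blocks_a + blocks_b),
        junctions=sorted(set(junc_a + junc_b)),
        mate_gap=gap,
        is_long_read=False,
        orientation=_record_orientation(read1),
    )
    return lo, frag


class _BoundaryIndex:
    """Per (chrom, strand) sorted boundary coordinates for fuzzy lookup."""

    def __init__(self, entities) -> None:
        coords: dict[tuple[str, str], set[int]] = {}
        for ent in entities:
            key = (ent.chrom, ent.strand)
            bag = coords.setdefault(key, set())
            bag.update(ent.starts)
            bag.update(ent.ends)
            bag.update(ent.upstream_neighbor_ends)
            bag.update(ent.downstream_neighbor_starts)
        self._sorted = {k: sorted(v) for k, v in coords.items()}

    def near(self, chrom: str, strand: str, coord: int, tol: int) -> bool:
        arr = self._sorted.get((chrom, strand))
        if not arr:
            return False
        i = bisect.bisect_left(arr, coord - tol)
        return i < len(arr) and arr[i] <= coord + tol


def detect_layout(
    bam: pysam.AlignmentFile,
    entities: Sequence,
    sample_size: int = 100_000,
    tol: int = DEFAULT_TOLERANCE,
    min_mapq: int = 0,
) -> LibraryLayout:
    """Infer pairing and strandedness from a sample of primary alignments.

    Pairing is a majority vote of paired flags. Strandedness is voted by
    junction-bearing records whose junction boundaries fuzzy-match annotated
    exon boundaries on exactly one strand; if neither orientation exceeds
    80% of votes the library is called unstranded.
    """
    index = _BoundaryIndex(entities)
    sampled = 0
    paired_votes = 0
    fw = rv = 0
    for rec in bam.fetch(until_eof=True):
        if not _usable(rec, min_mapq):
            continue
        sampled += 1
        if rec.is_paired:
            paired_votes += 1
        if "N" in (rec.cigarstring or ""):
            gene_strand = None
            for donor, acceptor in extract_junctions(rec.cigartuples, rec.reference_start):
                hits = {
                    s
                    for s in ("+", "-")
                    if index.near(rec.reference_name, s, donor, tol)
                    or index.near(rec.reference_name, s, acceptor, tol)
                }
                if len(hits) == 1:
                    gene_strand = hits.pop()
                    break
            if gene_strand is not None:
                if _record_orientation(rec) == gene_strand:
                    fw += 1
                else:
                    rv += 1
        if sampled >= sample_size:
            break
    if sampled == 0:
        raise ValueError("no usable alignments sampled for layout detection")
    votes = fw + rv
    if votes and fw / votes > 0.8:
        strandedness = "forward"
    elif votes and rv / votes > 0.8:
        strandedness = "reverse"
    else:
        strandedness = "unstranded"
    return LibraryLayout(paired=paired_votes * 2 > sampled, strandedness=strandedness)
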