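"""Gene-annotation handling: GTF parsing, exon clustering, typing and the exon table.

Internally all coordinates are 0-based half-open. Files (GTF and the exon
table) use 1-based inclusive coordinates. Neighbor boundary sets are kept
in *junction space*: the coordinate of the intron boundary on the neighbor
side, expressed so that it compares directly with splice-junction donor
(exclusive block end) and acceptor (block start) coordinates extracted from
CIGAR strings:

* ``+`` strand: ``upstream_neighbor_ends`` hold exclusive genomic ends of
  the transcription-upstream neighbor (donor side); ``downstream_neighbor_starts``
  hold genomic starts of the downstream neighbor (acceptor side).
* ``-`` strand: the transcription-upstream neighbor lies genomically to the
  right, so ``upstream_neighbor_ends`` hold its genomic *starts* (acceptor
  side) and ``downstream_neighbor_starts`` hold exclusive genomic *ends* of
  the left-adjacent neighbor (donor side).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

EXON_TYPES = ("first", "last", "sfrst", "slst", "internal", "diverse", "retained_intron")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

EXON_TABLE_COLUMNS = (
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "upstream_neighbor_ends",
    "downstream_neighbor_starts",
    "gene_id",
    "exon_type",
)


@dataclass
class TranscriptModel:
    """A transcript as an ordered chain of exons.

    ``exons`` are (start, end) 0-based half-open intervals in transcription
    order: ascending genomic coordinates on ``+``, descending on ``-``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty/inverted exon ({s},{e}) in {self.transcript_id}")


@dataclass
class ExonEntity:
    """A cluster of overlapping exons of one gene, with all observed boundaries."""

    gene_id: str
    chrom: str
    strand: str
    starts: set[int]
    ends: set[int]
    upstream_neighbor_ends: set[int] = field(default_factory=set)
    downstream_neighbor_starts: set[int] = field(default_factory=set)
    exon_type: str = "internal"

    def __post_init__(self) -> None:
        if not self.starts or not self.ends:
            raise ValueError("ExonEntity needs at least one start and one end")
        if min(self.starts) > min(self.ends):
            raise ValueError("ExonEntity with min(start) > min(end)")

    @property
    def extent(self) -> tuple[int, int]:
        """Maximal genomic extent [min start, max end)."""
        return min(self.starts), max(self.ends)

    @property
    def entity_id(self) -> str:
        s, e = self.extent
        return f"{self.gene_id}:{self.chrom}:{s}-{e}:{self.strand}"


def parse_gtf(path: str) -> list[TranscriptModel]:
    """Parse exon features from a GTF file into transcript models.

    Non-exon features are ignored; malformed lines are skipped with a
    warning. Raises ``ValueError`` if the file contains no exon features.
    """
    exons_by_tx: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                logger.warning("skipping malformed GTF line %d (%d fields)", lineno, len(fields))
                continue
            if fields[2] != "exon":
                continue
            try:
                start = int(fields[3]) - 1  # to 0-based
                end = int(fields[4])
            except ValueError:
                logger.warning("skipping GTF line %d: non-integer coordinates", lineno)
                continue
            strand = fields[6]
            attrs = dict(_ATTR_RE.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            tx_id = attrs.get("transcript_id")
            if gene_id is None or tx_id is None or strand not in ("+", "-") or start >= end:
                logger.warning("skipping GTF line %d: missing attributes or bad interval", lineno)
                continue
            exons_by_tx.setdefault(tx_id, []).append((start, end))
            meta[tx_id] = (gene_id, fields[0], strand)
    if not exons_by_tx:
        raise ValueError(f"no exon features found in {path}")

    transcripts = []
    for tx_id, exons in exons_by_tx.items():
        gene_id, chrom, strand = meta[tx_id]
        exons = sorted(exons, reverse=(strand == "-"))
        transcripts.append(TranscriptModel(tx_id, gene_id, chrom, strand, exons))
    return transcripts


def _neighbor_boundary_upstream(prev_exon: tuple[int, int], strand: str) -> int:
    """Junction-space coordinate of the transcription-upstream neighbor's intron boundary."""
    return prev_exon[1] if strand == "+" else prev_exon[0]


def _neighbor_boundary_downstream(next_exon: tuple[int, int], strand: str) -> int:
    return next_exon[0] if strand == "+" else next_exon[1]


def detect_retained_intron_intervals(
    transcripts: Iterable[TranscriptModel],
) -> set[tuple[str, tuple[int, int]]]:
    """Exon intervals that span two transcript-adjacent exons plus their intron.

    Interval I of a gene is a retained-intron event when some transcript of
    the gene has genomically adjacent exons A -> B with I.start == A.start
    and I.end == B.end (and I is neither A nor B). Detected before
    clustering because such intervals overlap both flanking exons and would
    otherwise be merged with them.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    flagged: set[tuple[str, tuple[int, int]]] = set()
    for gene_id, txs in by_gene.items():
        intervals = {iv for tx in txs for iv in tx.exons}
        spans: set[tuple[int, int]] = set()
        for tx in txs:
            for a, b in zip(tx.exons, tx.exons[1:]):
                left, right = (a, b) if a[0] <= b[0] else (b, a)
                spans.add((left[0], right[1]))
        for iv in intervals:
            if iv in spans:
                flagged.add((gene_id, iv))
    return flagged


def cluster_exons(
    transcripts: Iterable[TranscriptModel],
    exclude: set[tuple[str, tuple[int, int]]] | frozenset = frozenset(),
) -> list[ExonEntity]:
    """Merge overlapping exons of each gene into exon entities.

    Single-linkage on >=1 bp genomic overlap within a gene; entities of
    different genes are never merged. Neighbor boundary sets accumulate
    over all member transcripts. Intervals listed in ``exclude`` (keyed by
    (gene_id, interval)) take part in neighbor bookkeeping but are not
    clustered into entities. Raises on a gene annotated on both strands.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)

    entities: list[ExonEntity] = []
    for gene_id, txs in by_gene.items():
        strands = {tx.strand for tx in txs}
        chroms = {tx.chrom for tx in txs}
        if len(strands) > 1:
            raise ValueError(f"gene {gene_id} has transcripts on both strands")
        if len(chroms) > 1:
            raise ValueError(f"gene {gene_id} has transcripts on multiple chromosomes")
        strand = strands.pop()
        chrom = chroms.pop()

        intervals = sorted(
            {iv for tx in txs for iv in tx.exons if (gene_id, iv) not in exclude}
        )
        clusters: list[list[tuple[int, int]]] = []
        cur: list[tuple[int, int]] = []
        cur_end = -1
        for iv in intervals:
            if cur and iv[0] < cur_end:
                cur.append(iv)
                cur_end = max(cur_end, iv[1])
            else:
                if cur:
                    clusters.append(cur)
                cur = [iv]
                cur_end = iv[1]
        if cur:
            clusters.append(cur)

        gene_entities = []
        lookup: dict[tuple[int, int], ExonEntity] = {}
        for members in clusters:
            ent = ExonEntity(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                starts={s for s, _ in members},
                ends={e for _, e in members},
            )
            gene_entities.append(ent)
            for iv in members:
                lookup[iv] = ent

        for tx in txs:
            for i, exon in enumerate(tx.exons):
                ent = lookup.get(exon)
                if ent is None:  # excluded (retained-intron) interval
                    continue
                if i > 0:
                    ent.upstream_neighbor_ends.add(
                        _neighbor_boundary_upstream(tx.exons[i - 1], strand)
                    )
                if i < len(tx.exons) - 1:
                    ent.downstream_neighbor_starts.add(
                        _neighbor_boundary_downstream(tx.exons[i + 1], strand)
                    )
        entities.extend(gene_entities)
    return entities


def _positional_labels(index: int, n_exons: int) -> frozenset[str]:
    """Set of positional labels an exon carries within one transcript."""
    labels = set()
    if index == 0:
        labels.add("first")
    if index == n_exons - 1:
        labels.add("last")
    if index == 1:
        labels.add("sfrst")
    if index == n_exons - 2:
        labels.add("slst")
    if not labels:
        labels.add("internal")
    return frozenset(labels)


def classify_exon_type(
    entity: ExonEntity, transcripts: Iterable[TranscriptModel]
) -> str:
    """Positional type of an exon entity over all transcripts containing it.

    Each membership yields a positional label (first / sfrst / internal /
    slst / last). If every membership agrees on a single unambiguous label
    that label is returned; any disagreement or ambiguity (e.g. an exon that
    is simultaneously first and second-last in a 2-exon transcript, or a
    single-exon transcript) yields ``diverse``.
    """
    intervals = {
        (s, e)
        for s in entity.starts
        for e in entity.ends
    }
    ext = entity.extent
    label_sets = []
    for tx in transcripts:
        if tx.gene_id != entity.gene_id:
            continue
        for i, exon in enumerate(tx.exons):
            if exon in intervals or (ext[0] <= exon[0] and exon[1] <= ext[1] and exon[1] > ext[0]):
                label_sets.append(_positional_labels(i, len(tx.exons)))
    if not label_sets:
        raise ValueError(f"entity {entity.entity_id} not present in any transcript")
    first = label_sets[0]
    if all(ls == first for ls in label_sets) and len(first) == 1:
        return next(iter(first))
    return "diverse"


def flag_retained_intron_entities(entities: Sequence[ExonEntity],
                                  transcripts: Iterable[TranscriptModel]) -> list[ExonEntity]:
    """Flag entities that span two adjacent entities plus their intron.

    An entity is flagged ``retained_intron`` when, within the same gene, its
    start matches a start of a genomically-left entity X and its end matches
    an end of a genomically-right entity Y, with X and Y adjacent exons in
    some transcript of the gene. Returns the flagged entities (exon_type
    mutated in place).
    """
    by_gene: dict[str, list[ExonEntity]] = {}
    for ent in entities:
        by_gene.setdefault(ent.gene_id, []).append(ent)

    # genomically-ordered adjacent entity pairs per gene
    adjacency: dict[str, set[tuple[int, int]]] = {}
    lookup: dict[str, dict[tuple[int, int], int]] = {}
    for gene_id, ents in by_gene.items():
        table = {}
        for idx, ent in enumerate(ents):
            for s in ent.starts:
                for e in ent.ends:
                    table[(s, e)] = idx
        lookup[gene_id] = table
    for tx in transcripts:
        ents = by_gene.get(tx.gene_id)
        if not ents:
            continue
        table = lookup[tx.gene_id]

        def find(exon: tuple[int, int]) -> int | None:
            if exon in table:
                return table[exon]
            for idx, ent in enumerate(ents):
                lo, hi = ent.extent
                if lo <= exon[0] and exon[1] <= hi:
                    return idx
            return None

        for a, b in zip(tx.exons, tx.exons[1:]):
            ia, ib = find(a), find(b)
            if ia is None or ib is None or ia == ib:
                continue
            left, right = (ia, ib) if tx.strand == "+" else (ib, ia)
            adjacency.setdefault(tx.gene_id, set()).add((left, right))

    flagged = []
    for gene_id, ents in by_gene.items():
        pairs = adjacency.get(gene_id, set())
        for ent in ents:
            for left_idx, right_idx in pairs:
                left, right = ents[left_idx], ents[right_idx]
                if ent is left or ent is right:
                    continue
                if ent.starts & left.starts and ent.ends & right.ends:
                    ent.exon_type = "retained_intron"
                    flagged.append(ent)
                    break
    return flagged


def build_exon_table(
    transcripts: Iterable[TranscriptModel], keep_retained_introns: bool = False
) -> list[ExonEntity]:
    """Cluster, type and retained-intron-filter exons from transcript models.

    Retained-intron intervals are detected before clustering (they overlap
    both flanking exons and would otherwise absorb them); by default they
    are excluded from the table, with ``keep_retained_introns`` they are
    appended as their own entities typed ``retained_intron``.
    """
    transcripts = list(transcripts)
    ri_intervals = detect_retained_intron_intervals(transcripts)
    entities = cluster_exons(transcripts, exclude=ri_intervals)
    for ent in entities:
        ent.exon_type = classify_exon_type(ent, transcripts)
    flag_retained_intron_entities(entities, transcripts)
    if not keep_retained_introns:
        entities = [e for e in entities if e.exon_type != "retained_intron"]
    else:
        for gene_id, (s, e) in sorted(ri_intervals):
            tx = next(t for t in transcripts if t.gene_id == gene_id)
            entities.append(
                ExonEntity(
                    gene_id=gene_id,
                    chrom=tx.chrom,
                    strand=tx.strand,
                    starts={s},
                    ends={e},
                    exon_type="retained_intron",
                )
            )
    return entities


def _fmt_coords(coords: set[int], one_based: bool) -> str:
    if not coords:
        return "."
    offset = 1 if one_based else 0
    return ",".join(str(c + offset) for c in sorted(coords))


def _parse_coords(text: str, one_based: bool) -> set[int]:
    text = text.strip()
    if text in (".", "", "NA"):
        return set()
    offset = 1 if one_based else 0
    return {int(tok) - offset for tok in text.split(",")}


def write_exon_table(entities: Sequence[ExonEntity], path: str) -> None:
    """Serialize entities to the tab-separated exon table (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(EXON_TABLE_COLUMNS) + "\n")
        for ent in entities:
            plus = ent.strand == "+"
            # starts are written 1-based; exclusive ends equal the 1-based
            # inclusive coordinate of the last base, so they go unshifted
            row = [
                ent.chrom,
                ent.strand,
                _fmt_coords(ent.starts, one_based=True),
                _fmt_coords(ent.ends, one_based=False),
                _fmt_coords(ent.upstream_neighbor_ends, one_based=not plus),
                _fmt_coords(ent.downstream_neighbor_starts, one_based=plus),
                ent.gene_id,
                ent.exon_type,
            ]
            fh.write("\t".join(row) + "\n")


def read_exon_table(path: str) -> list[ExonEntity]:
    """Read an exon table written by :func:`write_exon_table`."""
    entities = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line[1:].split("\t")
                for required in EXON_TABLE_COLUMNS:
                    if required not in header:
                        raise ValueError(
                            f"exon table missing mandatory column '{required}'"
                        )
                continue
            fields = line.split("\t")
            cols = header or list(EXON_TABLE_COLUMNS)
            rec = dict(zip(cols, fields))
            if len(fields) < len(cols):
                raise ValueError(f"truncated exon table row at line {lineno}")
            strand = rec["strand"]
            if strand not in ("+", "-"):
                raise ValueError(f"invalid strand {strand!r} at line {lineno}")
            plus = strand == "+"
            starts = _parse_coords(rec["exon_starts"], one_based=True)
            ends = _parse_coords(rec["exon_ends"], one_based=False)
            if not starts or not ends or min(starts) > min(ends) or min(starts) >= max(ends):
                raise ValueError(f"invalid exon coordinates at line {lineno}")
            entities.append(
                ExonEntity(
                    gene_id=rec["gene_id"],
                    chrom=rec["chrom"],
                    strand=strand,
                    starts=starts,
                    ends=ends,
                    upstream_neighbor_ends=_parse_coords(
                        rec["upstream_neighbor_ends"], one_based=not plus
                    ),
                    downstream_neighbor_starts=_parse_coords(
                        rec["downstream_neighbor_starts"], one_based=plus
                    ),
                    exon_type=rec["exon_type"],
                )
            )
    return entities
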