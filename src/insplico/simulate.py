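"""Synthetic data generation: annotations, partially spliced molecules, aligned reads.

Each simulated gene carries one focus internal exon. Molecules of a gene
are fully spliced except for exactly one retained intron flanking the focus
exon; the proportion of molecules retaining the downstream intron is the
gene's target Fupfi (an up-retained molecule is dofi evidence and vice
versa), drawn from a 0-to-1 grid in 0.1 steps. Reads are emitted as exact
pre-computed alignments, so no external mapper is involved; an optional
FASTA export preserves the mapper-based pathway.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from insplico.annotation import (
    ExonEntity,
    TranscriptModel,
    build_exon_table,
    write_exon_table,
)
from insplico.evidence import FragmentEvidence, merge_blocks

logger = logging.getLogger(__name__)

DEFAULT_FUPFI_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass
class SimConfig:
    """Parameters of one simulation run; the seed fully determines the output."""

    n_genes: int = 100
    n_exons: tuple[int, int] = (3, 3)  # inclusive range, >= 3
    exon_length: tuple[int, int] = (50, 200)
    focus_exon_length: Optional[tuple[int, int]] = None
    intron_length: tuple[int, int] = (300, 1000)
    fupfi_grid: Sequence[float] = DEFAULT_FUPFI_GRID
    molecules_per_gene: tuple[int, int] = (10, 20)
    read_length: int = 75
    paired: bool = False
    insert_size: int = 250
    strandedness: str = "unstranded"  # forward | reverse | unstranded
    strands: str = "both"  # '+', '-', or 'both'
    fragments_per_molecule: int = 30
    tile: bool = False  # one fragment per transcript position (saturating depth)
    tile_step: int = 1
    long_reads: bool = False
    reads_per_molecule_long: int = 2
    p5: float = 0.0  # 5'-truncation probability (at truncation_length_scale, if set)
    p3: float = 0.0
    truncation_length_scale: Optional[float] = None  # probability scales with length/scale
    error_rate: float = 0.0  # substitutions, FASTA export only
    seed: int = 0
    chrom: str = "simChr"
    gene_gap: int = 2000


@dataclass
class SimGene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # ascending genomic order
    focus_tx_index: int

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def focus_genomic_index(self) -> int:
        if self.strand == "+":
            return self.focus_tx_index
        return self.n_exons - 1 - self.focus_tx_index

    @property
    def focus_exon(self) -> tuple[int, int]:
        return self.exons[self.focus_genomic_index]

    def flanking_introns(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """(upstream, downstream) intron intervals in transcription orientation."""
        g = self.focus_genomic_index
        left = (self.exons[g - 1][1], self.exons[g][0])
        right = (self.exons[g][1], self.exons[g + 1][0])
        return (left, right) if self.strand == "+" else (right, left)


@dataclass
class SimMolecule:
    molecule_id: str
    gene_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]  # ascending genomic, retained intron merged in
    retained_side: str  # up | do

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class SimTruth:
    """Ground truth for one simulated focus exon."""

    gene_id: str
    chrom: str
    strand: str
    exon_length: int
    up_intron_length: int
    do_intron_length: int
    n_molecules: int
    n_up_retained: int
    n_do_retained: int
    target_fupfi: float
    realized_fupfi: float


@dataclass
class SimRead:
    """One alignment record (a mate, a single-end read or a long read)."""

    qname: str
    chrom: str
    blocks: list[tuple[int, int]]
    reverse: bool
    paired: bool = False
    is_read1: bool = True
    mate_start: int = -1
    mate_reverse: bool = False
    is_long: bool = False


@dataclass
class SimResult:
    config: SimConfig
    genes: list[SimGene]
    transcripts: list[TranscriptModel]
    entities: list[ExonEntity]
    focus_entities: list[ExonEntity]  # one per gene, same order as genes
    molecules: dict[str, list[SimMolecule]]
    truths: list[SimTruth]
    reads: list[SimRead] = field(default_factory=list)
    bam_path: Optional[str] = None
    exon_table_path: Optional[str] = None
    gtf_path: Optional[str] = None
    truth_path: Optional[str] = None


def _rand_int(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    lo, hi = bounds
    if lo > hi or lo < 1:
        raise ValueError(f"infeasible length range {bounds}")
    return int(rng.integers(lo, hi + 1))


def simulate_annotation(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[SimGene], list[TranscriptModel]]:
    """Build gene models, one transcript each, laid out along one chromosome."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.n_exons[0] < 3:
        raise ValueError("genes need at least 3 exons for a focus internal exon")
    genes: list[SimGene] = []
    transcripts: list[TranscriptModel] = []
    cursor = 1000
    for gi in range(config.n_genes):
        n_ex = _rand_int(rng, config.n_exons)
        focus_tx = n_ex // 2
        if config.strands == "both":
            strand = "+" if rng.integers(0, 2) == 0 else "-"
        else:
            strand = config.strands
        focus_genomic = focus_tx if strand == "+" else n_ex - 1 - focus_tx
        exons = []
        pos = cursor
        for ei in range(n_ex):
            if ei == focus_genomic and config.focus_exon_length is not None:
                elen = _rand_int(rng, config.focus_exon_length)
            else:
                elen = _rand_int(rng, config.exon_length)
            exons.append((pos, pos + elen))
            pos += elen
            if ei < n_ex - 1:
                pos += _rand_int(rng, config.intron_length)
        cursor = pos + config.gene_gap
        gene = SimGene(f"g{gi:05d}", config.chrom, strand, exons, focus_tx)
        genes.append(gene)
        tx_exons = exons if strand == "+" else list(reversed(exons))
        transcripts.append(
            TranscriptModel(f"t{gi:05d}", gene.gene_id, config.chrom, strand, tx_exons)
        )
    return genes, transcripts


def simulate_molecules(
    gene: SimGene, config: SimConfig, rng: np.random.Generator
) -> tuple[list[SimMolecule], SimTruth]:
    """Molecule population of one gene realizing a drawn target Fupfi.

    ``round(target * n)`` molecules retain the downstream intron (upfi
    evidence); the remainder retain the upstream intron (dofi evidence).
    """
    n = _rand_int(rng, config.molecules_per_gene)
    target = float(rng.choice(np.asarray(config.fupfi_grid, dtype=float)))
    n_do_retained = int(np.floor(target * n + 0.5))
    n_up_retained = n - n_do_retained
    up_intron, do_intron = gene.flanking_introns()
    molecules = []
    for mi in range(n):
        side = "up" if mi < n_up_retained else "do"
        intron = up_intron if side == "up" else do_intron
        blocks = merge_blocks(list(gene.exons) + [intron])
        molecules.append(
            SimMolecule(
                molecule_id=f"{gene.gene_id}_m{mi}",
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                blocks=blocks,
                retained_side=side,
            )
        )
    fe = gene.focus_exon
    truth = SimTruth(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        exon_length=fe[1] - fe[0],
        up_intron_length=up_intron[1] - up_intron[0],
        do_intron_length=do_intron[1] - do_intron[0],
        n_molecules=n,
        n_up_retained=n_up_retained,
        n_do_retained=n_do_retained,
        target_fupfi=target,
        realized_fupfi=n_do_retained / n,
    )
    return molecules, truth


def _genomic_sub(blocks: Sequence[tuple[int, int]], a: int, b: int) -> list[tuple[int, int]]:
    """Genomic blocks for ascending-orientation molecule offsets [a, b)."""
    out = []
    offset = 0
    for s, e in blocks:
        length = e - s
        lo = max(a, offset)
        hi = min(b, offset + length)
        if lo < hi:
            out.append((s + lo - offset, s + hi - offset))
        offset += length
    return out


def molecule_interval_blocks(mol: SimMolecule, t0: int, t1: int) -> list[tuple[int, int]]:
    """Genomic blocks for transcript-space interval [t0, t1), 0 = 5' end."""
    if mol.strand == "+":
        return _genomic_sub(mol.blocks, t0, t1)
    length = mol.length
    return _genomic_sub(mol.blocks, length - t1, length - t0)


def _sense_read1(config: SimConfig, rng: np.random.Generator) -> bool:
    if config.strandedness == "forward":
        return True
    if config.strandedness == "reverse":
        return False
    return bool(rng.integers(0, 2) == 0)


def simulate_short_reads(
    molecules: Iterable[SimMolecule], config: SimConfig, rng: np.random.Generator
) -> list[SimRead]:
    """Fragments placed uniformly over all (molecule, start) positions.

    Sampling every possible fragment start with equal probability makes the
    expected read count of a molecule proportional to its length, as in
    uniform fragmentation of an RNA pool; ``fragments_per_molecule`` sets
    the average depth. In tile mode every start position of every molecule
    is emitted once (saturating depth). Paired mode emits two mates per
    fragment. Molecules shorter than the fragment length are skipped with a
    warning.
    """
    rl = config.read_length
    flen = config.insert_size if config.paired else rl
    mols = list(molecules)
    spans = [m.length - flen + 1 for m in mols]
    usable = [(m, sp) for m, sp in zip(mols, spans) if sp > 0]
    skipped = len(mols) - len(usable)
    if skipped:
        logger.warning("%d molecules shorter than the fragment length were skipped", skipped)
    if not usable:
        return []

    if config.tile:
        placements = [
            (mol, t) for mol, sp in usable for t in range(0, sp, config.tile_step)
        ]
    else:
        cum = np.cumsum([sp for _, sp in usable])
        total_frags = config.fragments_per_molecule * len(mols)
        draws = np.sort(rng.integers(0, cum[-1], size=total_frags))
        idx = np.searchsorted(cum, draws, side="right")
        placements = [
            (usable[i][0], int(d - (cum[i - 1] if i else 0))) for i, d in zip(idx, draws)
        ]

    reads: list[SimRead] = []
    counter: dict[str, int] = {}
    for mol, t in placements:
        fi = counter.get(mol.molecule_id, 0)
        counter[mol.molecule_id] = fi + 1
        qname = f"{mol.molecule_id}_f{fi}"
        sense1 = _sense_read1(config, rng)
        if not config.paired:
            blocks = molecule_interval_blocks(mol, t, t + rl)
            reverse = (mol.strand == "-") == sense1
            reads.append(SimRead(qname, mol.chrom, blocks, reverse=reverse))
            continue
        b1 = molecule_interval_blocks(mol, t, t + rl)
        b2 = molecule_interval_blocks(mol, t + flen - rl, t + flen)
        r1_rev = (mol.strand == "-") == sense1
        r2_rev = not r1_rev
        reads.append(
            SimRead(qname, mol.chrom, b1, reverse=r1_rev, paired=True, is_read1=True,
                    mate_start=b2[0][0], mate_reverse=r2_rev)
        )
        reads.append(
            SimRead(qname, mol.chrom, b2, reverse=r2_rev, paired=True, is_read1=False,
                    mate_start=b1[0][0], mate_reverse=r1_rev)
        )
    return reads


def _truncation_prob(p: float, length: int, scale: Optional[float]) -> float:
    if scale is None:
        return p
    return min(1.0, p * length / scale)


def simulate_long_reads(
    molecules: Iterable[SimMolecule],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[SimRead]:
    """Full-molecule reads with optional 5'/3' truncations.

    With probability p5 (p3), scaled by molecule length when
    ``truncation_length_scale`` is set, a uniform 5' (3') portion of the
    molecule is lost; the emitted alignment covers the remaining interval.
    """
    reads: list[SimRead] = []
    for mol in molecules:
        for ri in range(config.reads_per_molecule_long):
            t0, t1 = 0, mol.length
            if rng.random() < _truncation_prob(config.p5, mol.length, config.truncation_length_scale):
                t0 = int(rng.integers(0, mol.length))
            if rng.random() < _truncation_prob(config.p3, mol.length, config.truncation_length_scale):
                t1 = int(rng.integers(t0 + 1, mol.length + 1))
            if t1 - t0 < 20:
                continue
            blocks = molecule_interval_blocks(mol, t0, t1)
            sense = True if config.strandedness != "reverse" else False
            reverse = (mol.strand == "-") == sense
            reads.append(
                SimRead(f"{mol.molecule_id}_l{ri}", mol.chrom, blocks,
                        reverse=reverse, is_long=True)
            )
    return reads


def reads_to_fragments(reads: Sequence[SimRead]) -> list[FragmentEvidence]:
    """Assemble FragmentEvidence directly from simulated reads (no BAM round trip)."""
    by_name: dict[str, list[SimRead]] = {}
    order: list[str] = []
    for r in reads:
        if r.qname not in by_name:
            order.append(r.qname)
        by_name.setdefault(r.qname, []).append(r)
    frags = []
    for qname in order:
        group = by_name[qname]
        blocks = merge_blocks([b for r in group for b in r.blocks])
        junctions = sorted(
            {
                (group_blocks[i][1], group_blocks[i + 1][0])
                for r in group
                for group_blocks in [r.blocks]
                for i in range(len(group_blocks) - 1)
            }
        )
        mate_gap = None
        if len(group) == 2:
            ends = sorted((r.blocks[0][0], r.blocks[-1][1]) for r in group)
            if ends[0][1] < ends[1][0]:
                mate_gap = (ends[0][1], ends[1][0])
        read1 = next((r for r in group if r.is_read1), group[0])
        if read1.is_read1:
            orientation = "-" if read1.reverse else "+"
        else:  # lone mate2: fragment orientation is the flip of its strand
            orientation = "+" if read1.reverse else "-"
        frags.append(
            FragmentEvidence(
                fragment_id=qname,
                chrom=group[0].chrom,
                blocks=blocks,
                junctions=junctions,
                mate_gap=mate_gap,
                is_long_read=any(r.is_long for r in group),
                orientation=orientation,
            )
        )
    return frags


def _cigar_from_blocks(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i:
            cig.append((3, s - blocks[i - 1][1]))  # N
        cig.append((0, e - s))  # M
    return cig


def write_bam(
    reads: Sequence[SimRead], path: str, chrom: str, chrom_length: int
) -> str:
    """Write reads as a coordinate-sorted, indexed BAM; returns the path."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": chrom, "LN": chrom_length}]}
    ordered = sorted(reads, key=lambda r: (r.blocks[0][0], r.qname, not r.is_read1))
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for r in ordered:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.qname
            seg.reference_id = 0
            seg.reference_start = r.blocks[0][0]
            seg.cigartuples = _cigar_from_blocks(r.blocks)
            seg.mapping_quality = 60
            flag = 0
            if r.reverse:
                flag |= 0x10
            if r.paired:
                flag |= 0x1 | 0x2
                flag |= 0x40 if r.is_read1 else 0x80
                if r.mate_reverse:
                    flag |= 0x20
                seg.next_reference_id = 0
                seg.next_reference_start = r.mate_start
            seg.flag = flag
            out.write(seg)
    pysam.index(path)
    return path


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def export_fasta(
    reads: Sequence[SimRead],
    path: str,
    chrom_length: int,
    seed: int,
    error_rate: float = 0.0,
) -> None:
    """Write read sequences drawn from a seeded random genome (optional pathway
    for mapper-based end-to-end checks)."""
    rng = np.random.default_rng(seed)
    genome = rng.integers(0, 4, size=chrom_length)
    err_rng = np.random.default_rng(seed + 1)
    comp = {65: "T", 67: "G", 71: "C", 84: "A"}
    with open(path, "w") as fh:
        for r in reads:
            codes = np.concatenate([genome[s:e] for s, e in r.blocks])
            if error_rate > 0:
                hit = err_rng.random(codes.size) < error_rate
                codes = np.where(hit, (codes + err_rng.integers(1, 4, codes.size)) % 4, codes)
            seq = b"".join(_BASES[codes]).decode()
            if r.reverse:
                seq = "".join(comp[ord(c)] for c in reversed(seq))
            suffix = "" if not r.paired else ("/1" if r.is_read1 else "/2")
            fh.write(f">{r.qname}{suffix}\n{seq}\n")


def simulate_dataset(
    config: SimConfig, out_dir: Optional[str] = None, write_fasta: bool = False
) -> SimResult:
    """Run a full simulation: annotation, molecules, reads, optional files on disk."""
    rng = np.random.default_rng(config.seed)
    genes, transcripts = simulate_annotation(config, rng)
    entities = build_exon_table(transcripts)
    by_interval = {}
    for ent in entities:
        for s in ent.starts:
            for e in ent.ends:
                by_interval[(ent.chrom, ent.strand, s, e)] = ent
    focus_entities = [
        by_interval[(g.chrom, g.strand, g.focus_exon[0], g.focus_exon[1])] for g in genes
    ]
    molecules: dict[str, list[SimMolecule]] = {}
    truths: list[SimTruth] = []
    all_reads: list[SimRead] = []
    for gene in genes:
        mols, truth = simulate_molecules(gene, config, rng)
        molecules[gene.gene_id] = mols
        truths.append(truth)
        if config.long_reads:
            all_reads.extend(simulate_long_reads(mols, config, rng))
        else:
            all_reads.extend(simulate_short_reads(mols, config, rng))

    result = SimResult(
        config=config,
        genes=genes,
        transcripts=transcripts,
        entities=entities,
        focus_entities=focus_entities,
        molecules=molecules,
        truths=truths,
        reads=all_reads,
    )
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        chrom_length = max(g.exons[-1][1] for g in genes) + 1000
        result.gtf_path = os.path.join(out_dir, "annotation.gtf")
        _write_gtf(transcripts, result.gtf_path)
        result.exon_table_path = os.path.join(out_dir, "exons.tsv")
        write_exon_table(entities, result.exon_table_path)
        result.bam_path = os.path.join(out_dir, "reads.bam")
        write_bam(all_reads, result.bam_path, config.chrom, chrom_length)
        result.truth_path = os.path.join(out_dir, "truth.tsv")
        write_truth_table(truths, result.truth_path)
        if write_fasta:
            export_fasta(
                all_reads,
                os.path.join(out_dir, "reads.fasta"),
                chrom_length,
                config.seed,
                config.error_rate,
            )
    return result


def detection_sweep(
    lengths: Sequence[int],
    seed: int = 0,
    read_length: int = 75,
    paired: bool = False,
    insert_size: int = 250,
    tile_step: int = 2,
    intron_length: tuple[int, int] = (300, 1000),
    flank_exon_length: tuple[int, int] = (80, 150),
) -> SimResult:
    """Detection-bound experiment: one 3-exon gene per requested focus-exon length.

    Each gene gets exactly one up-retained and one do-retained molecule,
    tiled with reads at every ``tile_step`` start position (saturating
    depth), so an exon is detected iff the read geometry permits it at all.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(
        n_genes=len(lengths),
        n_exons=(3, 3),
        exon_length=flank_exon_length,
        intron_length=intron_length,
        read_length=read_length,
        paired=paired,
        insert_size=insert_size,
        tile=True,
        tile_step=tile_step,
        seed=seed,
        strandedness="unstranded",
        strands="both",
    )
    genes: list[SimGene] = []
    transcripts: list[TranscriptModel] = []
    cursor = 1000
    for gi, focus_len in enumerate(lengths):
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        e1 = _rand_int(rng, flank_exon_length)
        e3 = _rand_int(rng, flank_exon_length)
        i1 = _rand_int(rng, intron_length)
        i2 = _rand_int(rng, intron_length)
        exons = [
            (cursor, cursor + e1),
            (cursor + e1 + i1, cursor + e1 + i1 + focus_len),
            (cursor + e1 + i1 + focus_len + i2, cursor + e1 + i1 + focus_len + i2 + e3),
        ]
        cursor = exons[-1][1] + config.gene_gap
        gene = SimGene(f"g{gi:05d}", config.chrom, strand, exons, 1)
        genes.append(gene)
        tx_exons = exons if strand == "+" else list(reversed(exons))
        transcripts.append(
            TranscriptModel(f"t{gi:05d}", gene.gene_id, config.chrom, strand, tx_exons)
        )
    entities = build_exon_table(transcripts)
    by_interval = {
        (ent.chrom, ent.strand, s, e): ent
        for ent in entities
        for s in ent.starts
        for e in ent.ends
    }
    focus_entities = [
        by_interval[(g.chrom, g.strand, g.focus_exon[0], g.focus_exon[1])] for g in genes
    ]
    molecules: dict[str, list[SimMolecule]] = {}
    truths: list[SimTruth] = []
    reads: list[SimRead] = []
    for gene in genes:
        up_intron, do_intron = gene.flanking_introns()
        mols = []
        for mi, (side, intron) in enumerate([("up", up_intron), ("do", do_intron)]):
            mols.append(
                SimMolecule(
                    molecule_id=f"{gene.gene_id}_m{mi}",
                    gene_id=gene.gene_id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    blocks=merge_blocks(list(gene.exons) + [intron]),
                    retained_side=side,
                )
            )
        molecules[gene.gene_id] = mols
        fe = gene.focus_exon
        truths.append(
            SimTruth(
                gene_id=gene.gene_id,
                chrom=gene.chrom,
                strand=gene.strand,
                exon_length=fe[1] - fe[0],
                up_intron_length=up_intron[1] - up_intron[0],
                do_intron_length=do_intron[1] - do_intron[0],
                n_molecules=2,
                n_up_retained=1,
                n_do_retained=1,
                target_fupfi=0.5,
                realized_fupfi=0.5,
            )
        )
        reads.extend(simulate_short_reads(mols, config, rng))
    return SimResult(
        config=config,
        genes=genes,
        transcripts=transcripts,
        entities=entities,
        focus_entities=focus_entities,
        molecules=molecules,
        truths=truths,
        reads=reads,
    )


def _write_gtf(transcripts: Sequence[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for tx in transcripts:
            for s, e in sorted(tx.exons):
                attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}";'
                fh.write(
                    f"{tx.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def write_truth_table(truths: Sequence[SimTruth], path: str) -> None:
    import pandas as pd

    pd.DataFrame([t.__dict__ for t in truths]).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
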