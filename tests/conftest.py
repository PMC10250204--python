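from __future__ import annotations

import numpy as np
import pytest

from insplico.annotation import ExonEntity, TranscriptModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_transcript(tx_id, gene_id, exons, strand="+", chrom="chr1"):
    """Exons given in ascending genomic order; reordered for minus strand."""
    ordered = sorted(exons, reverse=(strand == "-"))
    return TranscriptModel(tx_id, gene_id, chrom, strand, ordered)


def make_entity(
    starts,
    ends,
    up_nb=(),
    dn_nb=(),
    strand="+",
    gene_id="g1",
    chrom="chr1",
    exon_type="internal",
):
    return ExonEntity(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        starts=set(starts),
        ends=set(ends),
        upstream_neighbor_ends=set(up_nb),
        downstream_neighbor_starts=set(dn_nb),
        exon_type=exon_type,
    )


@pytest.fixture
def simple_plus_entity():
    """Internal + exon [1000,1100) with neighbors ending at 700 / starting at 1400."""
    return make_entity({1000}, {1100}, up_nb={700}, dn_nb={1400})
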