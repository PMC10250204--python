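from __future__ import annotations

import numpy as np
import pytest

from conftest import make_entity, make_transcript
from insplico.annotation import (
    ExonEntity,
    build_exon_table,
    classify_exon_type,
    cluster_exons,
    flag_retained_intron_entities,
    parse_gtf,
    read_exon_table,
    write_exon_table,
)


def _gtf_line(chrom, feature, start, end, strand, gene, tx):
    attrs = f'gene_id "{gene}"; transcript_id "{tx}";'
    return f"{chrom}\tsrc\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"


class TestParseGtf:
    def test_two_transcripts(self, tmp_path):
        path = tmp_path / "toy.gtf"
        lines = []
        for i, (s, e) in enumerate([(101, 200), (301, 400), (501, 600)]):
            lines.append(_gtf_line("chr1", "exon", s, e, "+", "gA", "t1"))
        for s, e in [(101, 200), (301, 400), (501, 600), (701, 800)]:
            lines.append(_gtf_line("chr1", "exon", s, e, "+", "gA", "t2"))
        path.write_text("".join(lines))
        txs = {t.transcript_id: t for t in parse_gtf(str(path))}
        assert len(txs) == 2
        assert len(txs["t1"].exons) == 3
        assert len(txs["t2"].exons) == 4
        assert txs["t1"].exons[0] == (100, 200)  # 0-based conversion

    def test_minus_strand_transcription_order(self, tmp_path):
        path = tmp_path / "minus.gtf"
        path.write_text(
            _gtf_line("chr1", "exon", 101, 200, "-", "gB", "t3")
            + _gtf_line("chr1", "exon", 301, 400, "-", "gB", "t3")
        )
        (tx,) = parse_gtf(str(path))
        assert tx.exons == [(300, 400), (100, 200)]  # descending = transcription order

    def test_only_cds_features_errors(self, tmp_path):
        path = tmp_path / "cds.gtf"
        path.write_text(_gtf_line("chr1", "CDS", 101, 200, "+", "gC", "t4"))
        with pytest.raises(ValueError, match="no exon features"):
            parse_gtf(str(path))

    def test_malformed_line_skipped(self, tmp_path, caplog):
        path = tmp_path / "bad.gtf"
        path.write_text(
            "garbage line\n" + _gtf_line("chr1", "exon", 101, 200, "+", "gD", "t5")
        )
        txs = parse_gtf(str(path))
        assert len(txs) == 1


class TestClusterExons:
    def test_alternative_boundary_merged(self):
        t1 = make_transcript("t1", "g1", [(100, 200), (300, 400)])
        t2 = make_transcript("t2", "g1", [(100, 200), (300, 400)])
        t3 = make_transcript("t3", "g1", [(100, 210), (300, 400)])
        entities = sorted(cluster_exons([t1, t2, t3]), key=lambda e: e.extent)
        assert len(entities) == 2
        assert entities[0].starts == {100}
        assert entities[0].ends == {200, 210}

    def test_gene_scoping(self):
        t1 = make_transcript("t1", "g1", [(100, 200), (300, 400)])
        t2 = make_transcript("t2", "g2", [(100, 200), (300, 400)])
        assert len(cluster_exons([t1, t2])) == 4

    def test_neighbor_collection(self):
        a = make_transcript("a", "g1", [(1, 50), (100, 200), (300, 400)])
        b = make_transcript("b", "g1", [(1, 50), (100, 200), (500, 600)])
        entities = {e.extent: e for e in cluster_exons([a, b])}
        mid = entities[(100, 200)]
        assert mid.downstream_neighbor_starts == {300, 500}
        assert mid.upstream_neighbor_ends == {50}

    def test_minus_strand_neighbors(self):
        # transcription order on '-': rightmost exon first
        t = make_transcript("t", "g1", [(100, 200), (300, 400), (500, 600)], strand="-")
        entities = {e.extent: e for e in cluster_exons([t])}
        mid = entities[(300, 400)]
        # upstream neighbor is the genomically-right exon; boundary is its start
        assert mid.upstream_neighbor_ends == {500}
        assert mid.downstream_neighbor_starts == {200}

    def test_opposite_strands_error(self):
        t1 = make_transcript("t1", "g1", [(100, 200)], strand="+")
        t2 = make_transcript("t2", "g1", [(150, 250)], strand="-")
        with pytest.raises(ValueError, match="both strands"):
            cluster_exons([t1, t2])

    def test_every_interval_in_exactly_one_entity(self, rng):
        txs = []
        for g in range(5):
            base = g * 10_000
            for t in range(3):
                pos = base + int(rng.integers(0, 50))
                exons = []
                for _ in range(int(rng.integers(2, 6))):
                    length = int(rng.integers(20, 300))
                    exons.append((pos, pos + length))
                    pos += length + int(rng.integers(50, 500))
                txs.append(make_transcript(f"g{g}t{t}", f"g{g}", exons))
        entities = cluster_exons(txs)
        for tx in txs:
            for s, e in tx.exons:
                owners = [
                    ent
                    for ent in entities
                    if ent.gene_id == tx.gene_id
                    and ent.extent[0] <= s
                    and e <= ent.extent[1]
                ]
                assert len(owners) == 1

    def test_clustering_idempotent(self):
        txs = [
            make_transcript("t1", "g1", [(100, 200), (300, 400)]),
            make_transcript("t2", "g1", [(100, 210), (290, 400)]),
            make_transcript("t3", "g1", [(150, 220), (300, 380)]),
        ]
        first = cluster_exons(txs)
        # re-express each entity's member intervals as single-exon transcripts
        rexprs = []
        n = 0
        for ent in first:
            for tx in txs:
                for exon in tx.exons:
                    if ent.extent[0] <= exon[0] and exon[1] <= ent.extent[1]:
                        rexprs.append(make_transcript(f"r{n}", ent.gene_id, [exon]))
                        n += 1
        second = cluster_exons(rexprs)
        assert sorted((e.starts, e.ends) for e in first) == sorted(
            (e.starts, e.ends) for e in second
        )


class TestClassifyExonType:
    def _chain(self, n, gene="g1", tx="t1", strand="+"):
        exons = [(i * 1000, i * 1000 + 100) for i in range(1, n + 1)]
        return make_transcript(tx, gene, exons, strand=strand)

    def test_second_first(self):
        tx = self._chain(5)
        entities = sorted(cluster_exons([tx]), key=lambda e: e.extent)
        assert classify_exon_type(entities[1], [tx]) == "sfrst"

    def test_second_last_and_ends(self):
        tx = self._chain(5)
        entities = sorted(cluster_exons([tx]), key=lambda e: e.extent)
        types = [classify_exon_type(e, [tx]) for e in entities]
        assert types == ["first", "sfrst", "internal", "slst", "last"]

    def test_minus_strand_positions(self):
        tx = self._chain(5, strand="-")
        entities = sorted(cluster_exons([tx]), key=lambda e: e.extent)
        types = [classify_exon_type(e, [tx]) for e in entities]
        # genomically ascending = reverse transcription order
        assert types == ["last", "slst", "internal", "sfrst", "first"]

    def test_diverse_on_disagreement(self):
        a = make_transcript("a", "g1", [(i * 1000, i * 1000 + 100) for i in range(1, 6)])
        b = make_transcript(
            "b", "g1", [(500, 600)] + [(i * 1000, i * 1000 + 100) for i in range(1, 6)]
        )
        entities = {e.extent: e for e in cluster_exons([a, b])}
        # second exon of 'a' (sfrst) is third exon of 'b' (internal)
        assert classify_exon_type(entities[(2000, 2100)], [a, b]) == "diverse"

    def test_single_exon_transcript_diverse(self):
        tx = make_transcript("t", "g1", [(100, 200)])
        (ent,) = cluster_exons([tx])
        assert classify_exon_type(ent, [tx]) == "diverse"

    def test_unknown_entity_errors(self):
        tx = self._chain(3)
        stray = make_entity({99_000}, {99_100})
        with pytest.raises(ValueError):
            classify_exon_type(stray, [tx])

    def test_hand_derived_distribution(self):
        """Synthetic annotation with known construction matches hand labels."""
        txs = [
            self._chain(4, tx="tA"),
            make_transcript("tB", "g1", [(1000, 1100), (2000, 2100), (4000, 4100)]),
        ]
        entities = {e.extent: e for e in cluster_exons(txs)}
        assert classify_exon_type(entities[(1000, 1100)], txs) == "first"
        # exon 2 is sfrst in tA but both sfrst and slst in the 3-exon tB:
        # ambiguous membership forces diverse
        assert classify_exon_type(entities[(2000, 2100)], txs) == "diverse"
        # exon 3 appears only in tA at position 3 of 4 -> slst
        assert classify_exon_type(entities[(3000, 3100)], txs) == "slst"
        # exon 4: last in tA and tB -> last
        assert classify_exon_type(entities[(4000, 4100)], txs) == "last"


class TestRetainedIntron:
    def test_spanning_entity_flagged(self):
        a = make_transcript("a", "g1", [(100, 200), (300, 400)])
        b = make_transcript("b", "g1", [(100, 400)])
        entities = cluster_exons([a, b])
        # the [100,400) interval merges everything into one entity under
        # single-linkage, so construct the scenario explicitly instead
        ents = [
            make_entity({100}, {200}),
            make_entity({300}, {400}),
            make_entity({100}, {400}),
        ]
        flagged = flag_retained_intron_entities(ents, [a])
        assert [e.extent for e in flagged] == [(100, 400)]
        assert ents[2].exon_type == "retained_intron"
        assert ents[0].exon_type != "retained_intron"

    def test_no_spanning_entity(self):
        a = make_transcript("a", "g1", [(100, 200), (300, 400)])
        ents = [make_entity({100}, {200}), make_entity({300}, {400})]
        assert flag_retained_intron_entities(ents, [a]) == []

    def test_cross_gene_not_flagged(self):
        a = make_transcript("a", "g1", [(100, 200), (300, 400)])
        ents = [
            make_entity({100}, {200}, gene_id="g1"),
            make_entity({300}, {400}, gene_id="g1"),
            make_entity({100}, {400}, gene_id="g2"),
        ]
        assert flag_retained_intron_entities(ents, [a]) == []

    def test_minus_strand_adjacency(self):
        a = make_transcript("a", "g1", [(100, 200), (300, 400)], strand="-")
        ents = [
            make_entity({100}, {200}, strand="-"),
            make_entity({300}, {400}, strand="-"),
            make_entity({100}, {400}, strand="-"),
        ]
        flagged = flag_retained_intron_entities(ents, [a])
        assert [e.extent for e in flagged] == [(100, 400)]


class TestExonTable:
    def _random_entities(self, rng, n=100):
        entities = []
        for i in range(n):
            base = 1000 * (i + 1)
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            starts = {base + int(d) for d in rng.integers(0, 20, rng.integers(1, 3))}
            ends = {base + 100 + int(d) for d in rng.integers(0, 20, rng.integers(1, 3))}
            if strand == "+":
                up = {base - int(d) for d in rng.integers(100, 300, rng.integers(0, 3))}
                dn = {base + 500 + int(d) for d in rng.integers(0, 300, rng.integers(0, 3))}
            else:
                up = {base + 500 + int(d) for d in rng.integers(0, 300, rng.integers(0, 3))}
                dn = {base - int(d) for d in rng.integers(100, 300, rng.integers(0, 3))}
            entities.append(
                make_entity(starts, ends, up, dn, strand=strand, gene_id=f"g{i}")
            )
        return entities

    def test_round_trip(self, tmp_path, rng):
        entities = self._random_entities(rng)
        path = tmp_path / "exons.tsv"
        write_exon_table(entities, str(path))
        back = read_exon_table(str(path))
        assert len(back) == len(entities)
        for a, b in zip(entities, back):
            assert (a.chrom, a.strand, a.gene_id, a.exon_type) == (
                b.chrom, b.strand, b.gene_id, b.exon_type
            )
            assert a.starts == b.starts and a.ends == b.ends
            assert a.upstream_neighbor_ends == b.upstream_neighbor_ends
            assert a.downstream_neighbor_starts == b.downstream_neighbor_starts

    def test_round_trip_bit_identical(self, tmp_path, rng):
        entities = self._random_entities(rng, n=30)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_exon_table(entities, str(p1))
        write_exon_table(read_exon_table(str(p1)), str(p2))
        assert p1.read_text() == p2.read_text()

    def test_empty_neighbors_accepted(self, tmp_path):
        ent = make_entity({100}, {200}, exon_type="last")
        path = tmp_path / "exons.tsv"
        write_exon_table([ent], str(path))
        (back,) = read_exon_table(str(path))
        assert back.downstream_neighbor_starts == set()

    def test_swapped_coordinates_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#chrom\tstrand\texon_starts\texon_ends\tupstream_neighbor_ends\t"
            "downstream_neighbor_starts\tgene_id\texon_type\n"
            "chr1\t+\t500\t200\t.\t.\tg1\tinternal\n"
        )
        with pytest.raises(ValueError):
            read_exon_table(str(path))

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#chrom\tstrand\texon_starts\texon_ends\tupstream_neighbor_ends\t"
            "gene_id\texon_type\n"
        )
        with pytest.raises(ValueError, match="downstream_neighbor_starts"):
            read_exon_table(str(path))


def test_build_exon_table_drops_retained_introns():
    txs = [
        make_transcript("a", "gX", [(100, 200), (300, 400), (500, 600)]),
        make_transcript("b", "gX", [(100, 400), (500, 600)]),
    ]
    kept = build_exon_table(txs)
    assert sorted(e.extent for e in kept) == [(100, 200), (300, 400), (500, 600)]
    all_ents = build_exon_table(txs, keep_retained_introns=True)
    ri = [e for e in all_ents if e.exon_type == "retained_intron"]
    assert [e.extent for e in ri] == [(100, 400)]
    # the spanning interval must not have polluted the true exons' boundaries
    first = next(e for e in kept if e.extent == (100, 200))
    assert first.ends == {200}
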