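"""Parsing, translation and redundancy handling."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phamkit.fixtures import FixtureSpec, back_translate, write_fixture
from phamkit.genome_io import (
    ConsistencyError,
    GeneRecord,
    InputError,
    deduplicate,
    expand_clusters,
    parse_genome,
    translate_cds,
)

proteins = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=40)


class TestTranslateCds:
    @pytest.mark.parametrize(
        "nt,expected",
        [
            ("ATGGCTTAA", "MA"),
            ("GTGGCTTAA", "MA"),  # GTG is a table-11 initiator, rendered M
            ("TTGGCTTAA", "MA"),
            ("ATGGCTGCT", "MAA"),  # no stop codon at all is tolerated
        ],
    )
    def test_standard_and_initiator_codons(self, nt, expected):
        assert translate_cds(nt) == expected

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            translate_cds("ATGTAAGCT")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            translate_cds("ATGGC")

    def test_ambiguous_codon_becomes_x(self):
        assert translate_cds("ATGANATAA") == "MX"

    @given(proteins)
    @settings(max_examples=30, deadline=None)
    def test_synonymous_codon_substitution_preserves_protein(self, protein):
        """Swapping codons for synonymous ones never changes the protein."""
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[11].forward_table
        by_aa = {}
        for codon, aa in table.items():
            by_aa.setdefault(aa, []).append(codon)
        nt = back_translate(protein)
        base = translate_cds(nt)
        rng = random.Random(hash(protein) % 2**32)
        codons = [nt[i : i + 3] for i in range(0, len(nt) - 3, 3)]
        # Re-pick every non-initial codon among its synonyms.
        swapped = [codons[0]] + [
            rng.choice(by_aa[table[c]]) for c in codons[1:]
        ]
        assert translate_cds("".join(swapped) + "TAA") == base


class TestParseGenome:
    def test_genbank_round_trip(self, tmp_path):
        fixture = write_fixture(
            FixtureSpec(n_families=2, members_per_family=3,
                        family_identities=(0.9, 0.5), ancestor_length=60,
                        n_orphams=1, orpham_length=60, seed=4),
            tmp_path,
        )
        for genome in fixture.genomes:
            parsed = parse_genome(tmp_path / f"{genome.genome_id}.gbk", "genbank")
            assert len(parsed.genes) == len(genome.genes)
            assert [g.protein for g in parsed.genes] == [
                g.protein for g in genome.genes
            ]
            assert [g.annotation for g in parsed.genes] == [
                g.annotation for g in genome.genes
            ]
            # 1-based inclusive coordinates survive the round trip
            assert [(g.start, g.stop) for g in parsed.genes] == [
                (g.start, g.stop) for g in genome.genes
            ]

    def test_fasta_protein_records(self, tmp_path):
        path = tmp_path / "two.faa"
        path.write_text(
            ">gene1 portal protein\nMKTAYIAKQRQISFVKSHFSRQ\n"
            ">gene2\nMSNNNAYIAKQRQISFVKSHFS\n"
        )
        genome = parse_genome(path, "fasta-aa")
        assert len(genome.genes) == 2
        assert genome.genes[0].annotation == "portal protein"
        assert genome.genes[0].start is None

    def test_internal_stop_cds_skipped_with_warning(self, tmp_path, caplog):
        # 9-codon CDS with TAA at codon 5 and no /translation qualifier.
        nt = "ATGGCTGCTGCT" + "TAA" + "GCTGCTGCTGCT"
        good = back_translate("MKTAYIAKQRQI")
        gbk = tmp_path / "broken.gbk"
        _write_minimal_genbank(gbk, [("bad1", nt, None), ("ok1", good, None)])
        with caplog.at_level("WARNING"):
            genome = parse_genome(gbk, "genbank")
        assert [g.gene_id for g in genome.genes] == ["ok1"]
        assert any("bad1" in rec.message for rec in caplog.records)

    def test_missing_file(self):
        with pytest.raises(InputError):
            parse_genome("/nonexistent/path.gbk")


def _write_minimal_genbank(path, cds_list):
    """cds_list: (locus_tag, nt, translation-or-None) laid out head to tail."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqIO import write
    from Bio.SeqRecord import SeqRecord

    seq = ""
    features = []
    for tag, nt, translation in cds_list:
        start = len(seq)
        seq += nt
        quals = {"locus_tag": [tag], "transl_table": ["11"]}
        if translation:
            quals["translation"] = [translation]
        features.append(
            SeqFeature(FeatureLocation(start, len(seq), strand=1),
                       type="CDS", qualifiers=quals)
        )
    rec = SeqRecord(Seq(seq), id="TEST1", name="TEST1", description="test",
                    features=features, annotations={"molecule_type": "DNA"})
    write(rec, path, "genbank")


class TestDeduplicate:
    def _genes(self, seqs):
        return [
            GeneRecord(gene_id=f"g{i}", genome_id="G", protein=s)
            for i, s in enumerate(seqs)
        ]

    def test_shared_sequence_collapses(self):
        seqs = ["MKTAYIAKQR", "MSNNNAYIAK", "MKTAYIAKQR", "MPPPAYIAKQ",
                "MWWWAYIAKQ"]
        nr = deduplicate(self._genes(seqs))
        assert nr.n_sequences == 4
        assert nr.n_genes == 5

    def test_all_unique_and_empty(self):
        assert deduplicate(self._genes(["MKTAYIAKQR", "MSNNNAYIAK"])).n_sequences == 2
        assert deduplicate([]).n_sequences == 0

    def test_duplicate_gene_id_rejected(self):
        genes = self._genes(["MKTAYIAKQR"]) * 2
        with pytest.raises(ConsistencyError):
            deduplicate(genes)

    def test_expand_round_trip_identity_partition(self):
        genes = self._genes(
            ["MKTAYIAKQR", "MSNNNAYIAK", "MKTAYIAKQR", "MPPPAYIAKQ"]
        )
        nr = deduplicate(genes)
        identity = [[d] for d in nr.digests()]
        expanded = expand_clusters(identity, nr)
        assert sorted(g for cluster in expanded for g in cluster) == sorted(
            g.gene_id for g in genes
        )
        assert len(expanded) == nr.n_sequences

    def test_expand_single_cluster_holds_everything(self):
        genes = self._genes(["MKTAYIAKQR", "MSNNNAYIAK", "MKTAYIAKQR"])
        nr = deduplicate(genes)
        expanded = expand_clusters([nr.digests()], nr)
        assert len(expanded) == 1
        assert sorted(expanded[0]) == ["g0", "g1", "g2"]

    def test_expand_unknown_digest_rejected(self):
        nr = deduplicate(self._genes(["MKTAYIAKQR"]))
        with pytest.raises(ConsistencyError):
            expand_clusters([["deadbeef"]], nr)

    @given(st.lists(proteins, min_size=1, max_size=15))
    @settings(max_examples=30, deadline=None)
    def test_gene_conservation_property(self, seqs):
        genes = self._genes(seqs)
        nr = deduplicate(genes)
        assert nr.n_genes == len(genes)
        expanded = expand_clusters([nr.digests()], nr)
        assert sum(len(c) for c in expanded) == len(genes)
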