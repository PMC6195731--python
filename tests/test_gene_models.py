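"""Guide enumeration, cut-site arithmetic, and protein coordinate mapping."""

import numpy as np
import pytest
from oracle_helpers import aa_pair_from_cut, brute_force_guides

from tilescope import (
    GeneModel,
    GuideRecord,
    Transcript,
    cut_site,
    enumerate_guides,
    map_cut_to_amino_acids,
    mrna_features,
)


def _single_exon_gene(seq_len=60, gene_id="toy", strand="+"):
    tx = Transcript("toy_T1", exons=[(0, seq_len)], cds=[(0, seq_len)])
    return GeneModel(gene_id, "toy", strand, [tx], "toy_T1")


class TestCutSite:
    def test_plus_strand_cut_three_bp_from_pam(self):
        assert cut_site((100, 120), "+") == 117

    def test_minus_strand_mirror(self):
        assert cut_site((100, 120), "-") == 103

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            cut_site((100, 119), "+")


class TestEnumerateGuides:
    def test_two_planted_pams_yield_two_guides(self):
        # A/T background carries no GG or CC; plant exactly two GG PAMs
        seq = list("AT" * 30)
        seq[24] = seq[25] = "G"
        seq[45] = seq[46] = "G"
        seq = "".join(seq)
        gene = _single_exon_gene()
        guides = enumerate_guides({"toy": seq}, gene)
        assert len(guides) == 2
        assert sorted(g.cut_coord for g in guides) == [20, 41]
        assert all(g.guide_strand == "+" for g in guides)

    def test_no_gc_genome_yields_nothing(self):
        gene = _single_exon_gene(seq_len=60)
        assert enumerate_guides({"toy": "AT" * 30}, gene) == []

    def test_motif_relaxation_is_monotone(self, screen):
        gene_id = next(iter(screen.gene_models))
        model = screen.gene_models[gene_id]
        ngg = enumerate_guides(screen.genome, model, "NGG")
        ngn = enumerate_guides(screen.genome, model, "NGN")
        assert len(ngn) >= len(ngg)

    def test_missing_contig_is_fatal(self):
        with pytest.raises(KeyError):
            enumerate_guides({"other": "A" * 100}, _single_exon_gene())

    def test_cds_outside_genome_is_fatal(self):
        gene = _single_exon_gene(seq_len=60)
        with pytest.raises(ValueError):
            enumerate_guides({"toy": "ACGT" * 10}, gene)

    def test_matches_regex_brute_force_on_fixture_genomes(self, screen):
        """Set equality with an independent regex scan on both strands."""
        for gid, model in screen.gene_models.items():
            seq = screen.genome[model.contig]
            cds_pos = {
                g for a, b in model.principal.cds for g in range(a, b)
            }
            expected = brute_force_guides(seq, cds_pos)
            got = {
                (g.spacer, g.guide_strand, g.cut_coord)
                for g in enumerate_guides(screen.genome, model)
            }
            assert got == expected


class TestAminoAcidMapping:
    def test_codon_boundary_maps_to_flanking_codons(self):
        tx = _single_exon_gene().principal
        assert map_cut_to_amino_acids(3, tx, "+") == (1, 2)

    def test_same_codon_collapse_extends_downstream(self):
        tx = _single_exon_gene().principal
        # k = 17: both flanking bases in codon 6 -> (6, 7)
        assert map_cut_to_amino_acids(17, tx, "+") == (6, 7)

    def test_intron_cut_returns_none(self):
        tx = Transcript("t", exons=[(0, 30), (90, 120)],
                        cds=[(0, 30), (90, 120)])
        assert map_cut_to_amino_acids(40, tx, "+") is None

    def test_matches_list_lookup_oracle_on_all_fixture_guides(self, screen):
        """Explicit coding-position enumeration reproduces every (aa1, aa2)."""
        for gid, model in screen.gene_models.items():
            tx = model.principal
            for g in enumerate_guides(screen.genome, model):
                expected = aa_pair_from_cut(
                    g.cut_coord, tx.cds, model.strand, tx.protein_length
                )
                assert (g.aa1, g.aa2) == expected, (gid, g.cut_coord)

    def test_aa_pair_bounds(self, screen):
        for gid, model in screen.gene_models.items():
            L = model.principal.protein_length
            for g in enumerate_guides(screen.genome, model):
                assert 1 <= g.aa1 <= g.aa2 <= L


class TestMrnaFeatures:
    @pytest.fixture
    def two_exon_gene(self):
        # coding exon lengths 300 + 162; last junction at coding 300
        tx = Transcript("t", exons=[(0, 300), (400, 562)],
                        cds=[(0, 300), (400, 562)])
        return GeneModel("g", "c", "+", [tx], "t")

    def _guide_at(self, cut_coord, strand="+"):
        return GuideRecord("g1", "A" * 20, "AGG", "c", strand, cut_coord)

    def test_cut_far_upstream_of_last_junction_triggers_nmd(self, two_exon_gene):
        feats = mrna_features(self._guide_at(200), two_exon_gene)
        assert feats.nmd_escape is False  # 100 nt upstream > 55

    def test_cut_near_last_junction_escapes_nmd(self, two_exon_gene):
        feats = mrna_features(self._guide_at(290), two_exon_gene)
        assert feats.nmd_escape is True  # 10 nt upstream <= 55

    def test_single_transcript_isoform_fraction_is_one(self, two_exon_gene):
        feats = mrna_features(self._guide_at(200), two_exon_gene)
        assert feats.isoform_fraction == 1.0

    def test_border_distances_sum_to_exon_length_minus_one(self, two_exon_gene):
        feats = mrna_features(self._guide_at(200), two_exon_gene)
        assert feats.exon_length == 300
        assert feats.dist_5p_exon_border + feats.dist_3p_exon_border == 299
        assert feats.exon_multiple_of_3 is True

    def test_non_cds_guide_warns_and_nulls(self, two_exon_gene):
        with pytest.warns(UserWarning):
            feats = mrna_features(self._guide_at(350), two_exon_gene)
        assert feats.nmd_escape is None
        assert feats.protein_fraction is None

    def test_nmd_escape_monotone_toward_last_exon(self, screen):
        """Moving the cut 3' (increasing coding position) never flips
        escape back to False."""
        for gid, model in screen.gene_models.items():
            tx = model.principal
            order = [
                g
                for a, b in (tx.cds if model.strand == "+" else
                             reversed(tx.cds))
                for g in (range(a, b) if model.strand == "+" else
                          range(b - 1, a - 1, -1))
            ]
            flags = []
            for k0 in range(0, len(order) - 1, 7):
                genomic = order[k0]
                cut = genomic + 1 if model.strand == "+" else genomic
                feats = mrna_features(self._guide_at(cut), model)
                flags.append(bool(feats.nmd_escape))
            switched = False
            for prev, cur in zip(flags, flags[1:]):
                if prev and not cur:
                    switched = True
            assert not switched

    def test_fraction_ranges_on_fixture(self, screen):
        df = screen.guides.dropna(subset=["gene_id"])
        assert ((df["protein_fraction"] > 0) & (df["protein_fraction"] <= 1)).all()
        assert ((df["isoform_fraction"] > 0) & (df["isoform_fraction"] <= 1)).all()


class TestTranscriptInvariants:
    def test_cds_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            Transcript("t", exons=[(0, 10)], cds=[(0, 10)])

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            Transcript("t", exons=[(0, 30), (20, 50)], cds=[(0, 30)])

    def test_protein_length_excludes_stop(self):
        tx = Transcript("t", exons=[(0, 63)], cds=[(0, 63)])
        assert tx.protein_length == 20

    def test_principal_must_be_member(self):
        tx = Transcript("t", exons=[(0, 63)], cds=[(0, 63)])
        with pytest.raises(ValueError):
            GeneModel("g", "c", "+", [tx], "absent")

    def test_fixture_translation_matches_coding_order(self, screen):
        """Reading coding bases in translation order reproduces the stored
        protein for both strands."""
        from Bio.Seq import Seq
        from oracle_helpers import coding_position_list

        for gid, model in screen.gene_models.items():
            seq = screen.genome[model.contig]
            order = coding_position_list(model.principal.cds, model.strand)
            bases = "".join(seq[g] for g in order)
            if model.strand == "-":
                bases = "".join(
                    {"A": "T", "T": "A", "G": "C", "C": "G"}[b] for b in bases
                )
            assert str(Seq(bases).translate())[:-1] == screen.proteins[gid]


def test_gff_fasta_round_trip(screen, screen_dir):
    """Models written to GFF3/FASTA and re-read reproduce the coordinates."""
    from tilescope import read_gene_models, read_genome

    genome = read_genome(str(screen_dir / "genome.fa"))
    models = read_gene_models(str(screen_dir / "genes.gff3"))
    assert set(models) == set(screen.gene_models)
    for gid, model in models.items():
        orig = screen.gene_models[gid]
        assert genome[model.contig] == screen.genome[orig.contig]
        assert model.strand == orig.strand
        assert model.principal.cds == orig.principal.cds
        got = {
            (g.spacer, g.guide_strand, g.cut_coord)
            for g in enumerate_guides(genome, model)
        }
        want = {
            (g.spacer, g.guide_strand, g.cut_coord)
            for g in enumerate_guides(screen.genome, orig)
        }
        assert got == want
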