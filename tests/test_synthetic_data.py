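import pytest

from fdefminer.duplication_analysis import count_synonymous
from fdefminer.errors import SpecError
from fdefminer.genemodel import translate
from fdefminer.synthetic_data import (
    FAMILY_TEMPLATES,
    GenePlan,
    PlantSpec,
    cys_positions,
    default_benchmark_spec,
    generate_mature,
    plant_genes,
)


class TestGenerateMature:
    @pytest.mark.parametrize("template", sorted(FAMILY_TEMPLATES))
    def test_six_cysteines_and_size_range(self, template):
        for seed in range(20):
            pep = generate_mature(seed, template)
            assert pep.count("C") == 6
            assert 33 <= len(pep) <= 60

    def test_deterministic(self):
        assert generate_mature(5, "plectasin") == generate_mature(5, "plectasin")

    def test_spacing_matches_template(self):
        anchor, _ = FAMILY_TEMPLATES["plectasin"]
        pep = generate_mature(3, "plectasin")
        assert cys_positions(pep) == cys_positions(anchor)

    def test_unknown_template_rejected(self):
        with pytest.raises(SpecError):
            generate_mature(0, "no-such-family")


class TestPlantGenes:
    def test_intronless_gene_contains_mature(self):
        spec = PlantSpec(
            genes=[GenePlan(name="g", architecture="no_pro")], seed=1
        )
        contigs, truth = plant_genes(spec)
        (g,) = truth.genes
        contig = {c.id: c for c in contigs}[g.contig]
        prot = g.gene_model().cds(contig.seq)
        assert g.matures[0] in translate(prot)

    def test_planned_phases_recorded(self):
        spec = PlantSpec(
            genes=[GenePlan(name="g",
                            introns=[("alpha_helix", 0), ("c_loop", 2)])],
            seed=2,
        )
        _, truth = plant_genes(spec)
        assert truth.genes[0].intron_phases == [0, 2]
        assert truth.genes[0].intron_regions == ["alpha_helix", "c_loop"]

    def test_paralog_pair_synonymous_count(self):
        """Verified against the codon-level substitution counter."""
        spec = PlantSpec(
            genes=[GenePlan(name="g", paralog_syn=4)], seed=3
        )
        _, truth = plant_genes(spec)
        a, b = truth.genes
        assert translate(a.cds) == translate(b.cds)
        total, syn, non = count_synonymous(a.cds, b.cds)
        assert (total, syn, non) == (4, 4, 0)

    def test_infeasible_plan_rejected(self):
        with pytest.raises(SpecError):
            plant_genes(PlantSpec(
                genes=[GenePlan(name="g", architecture="no_pro",
                                introns=[("propeptide", 0)])], seed=0,
            ))


class TestTruthInvariants:
    def test_spliced_cds_translates_to_precursor(self, benchmark):
        _, contigs, truth = benchmark
        seqs = {c.id: c.seq for c in contigs}
        for g in truth.genes:
            if g.pseudogene:
                continue
            assert translate(g.gene_model().cds(seqs[g.contig])) == g.precursor

    def test_introns_are_gt_ag(self, benchmark):
        _, contigs, truth = benchmark
        seqs = {c.id: c.seq for c in contigs}
        for g in truth.genes:
            if g.pseudogene:
                continue
            model = g.gene_model()
            for s, e in model.introns():
                raw = seqs[g.contig][s - 1 : e]
                if g.strand == "-":
                    from fdefminer.genemodel import revcomp

                    raw = revcomp(raw)
                assert raw.startswith("GT") and raw.endswith("AG")

    def test_regeneration_is_byte_identical(self):
        spec = default_benchmark_spec(n_genes=6, seed=9)
        c1, t1 = plant_genes(spec)
        c2, t2 = plant_genes(default_benchmark_spec(n_genes=6, seed=9))
        assert [(c.id, c.seq) for c in c1] == [(c.id, c.seq) for c in c2]
        assert [g.cds for g in t1.genes] == [g.cds for g in t2.genes]

    def test_coordinates_within_contigs(self, benchmark):
        _, contigs, truth = benchmark
        lengths = {c.id: len(c) for c in contigs}
        for g in truth.genes:
            for s, e in g.exons:
                assert 1 <= s <= e <= lengths[g.contig]

    def test_propeptides_acidic_with_basic_terminus(self, benchmark):
        from fdefminer.physchem import net_charge

        _, _, truth = benchmark
        seen = 0
        for g in truth.genes:
            for pro in g.propeptides:
                seen += 1
                assert pro[-1] in "KR"
                assert net_charge(pro, ph=7.0, include_termini=False) < 0
        assert seen > 0

    def test_amidated_genes_encode_gly_arg(self, benchmark):
        _, _, truth = benchmark
        seen = 0
        for g in truth.genes:
            if g.amidation and not g.pseudogene:
                seen += 1
                assert g.matures[-1].endswith("G")
                assert g.precursor.endswith(("GR", "GRR"))
        assert seen > 0
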