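import random

import pytest

from fdefminer.errors import ValidationError
from fdefminer.genemodel import GenomicContig, revcomp
from fdefminer.motif_scan import (
    SeedProfile,
    complete_spliced_model,
    scan_six_frames,
    spacing_envelope,
)
from fdefminer.synthetic_data import GenePlan, PlantSpec, _random_dna, plant_genes

from conftest import overlap


def _single_gene(plan, seed=1):
    contigs, truth = plant_genes(PlantSpec(genes=[plan], seed=seed))
    return contigs[0], truth.genes[0]


class TestProfile:
    def test_envelope_has_five_ranges(self, profile):
        assert len(profile.envelope) == 5
        assert all(lo <= hi for lo, hi in profile.envelope)

    def test_threshold_derived_from_seeds(self, profile):
        assert profile.min_score > 0

    def test_envelope_requires_six_cysteines(self):
        with pytest.raises(ValidationError):
            spacing_envelope(["ACDEFG"])  # no framework


class TestScan:
    def test_planted_intronless_gene_found(self, profile):
        contig, g = _single_gene(GenePlan(name="g"))
        loci = [l for l in scan_six_frames(contig, profile)
                if not l.pseudogene_candidate]
        hits = [l for l in loci if l.strand == g.strand
                and overlap(l.interval, (g.exons[0][0], g.exons[-1][1]))]
        assert len(hits) >= 1

    def test_strand_symmetry(self, profile):
        contig, g = _single_gene(GenePlan(name="g", strand="+"), seed=4)
        flipped = GenomicContig(contig.id, revcomp(contig.seq))
        fwd = [l for l in scan_six_frames(contig, profile)
               if not l.pseudogene_candidate]
        rev = [l for l in scan_six_frames(flipped, profile)
               if not l.pseudogene_candidate]
        L = len(contig.seq)
        mirrored = sorted(
            (("-" if l.strand == "+" else "+"),
             (L - l.interval[1] + 1, L - l.interval[0] + 1))
            for l in fwd
        )
        assert mirrored == sorted((l.strand, l.interval) for l in rev)

    def test_contig_order_invariance(self, profile, benchmark):
        _, contigs, _ = benchmark
        a, b = contigs[0], contigs[1]
        first = [(l.strand, l.interval) for l in scan_six_frames(a, profile)]
        # scanning b in between must not change a's result
        scan_six_frames(b, profile)
        again = [(l.strand, l.interval) for l in scan_six_frames(a, profile)]
        assert first == again

    def test_short_contig_rejected(self, profile):
        with pytest.raises(ValidationError):
            scan_six_frames(GenomicContig("t", "ACGT" * 10), profile)

    def test_random_contigs_yield_no_loci(self, profile):
        """False-positive calibration on GC-matched random sequence."""
        rng = random.Random(123)
        clean = 0
        trials = 25
        for t in range(trials):
            contig = GenomicContig(f"r{t}", _random_dna(5000, 0.45, rng))
            clean += not scan_six_frames(contig, profile)
        assert clean / trials >= 0.95


class TestCompletion:
    def test_two_intron_gene_recovered_exactly(self, profile):
        plan = GenePlan(name="g", introns=[("alpha_helix", 0), ("c_loop", 2)])
        contig, g = _single_gene(plan, seed=6)
        loci = scan_six_frames(contig, profile)
        models = [l.model or complete_spliced_model(contig, l, profile)
                  for l in loci if not l.pseudogene_candidate]
        assert any(m is not None and m.exons == g.exons for m in models)

    def test_intronless_gene_gets_zero_intron_model(self, profile):
        contig, g = _single_gene(GenePlan(name="g"), seed=8)
        locus = next(l for l in scan_six_frames(contig, profile)
                     if l.strand == g.strand)
        model = locus.model or complete_spliced_model(contig, locus, profile)
        assert model is not None
        assert model.exons == g.exons
        assert model.introns() == []

    def test_pseudogene_yields_null_model(self, profile):
        plan = GenePlan(name="p", introns=[("c_loop", 2)], pseudogene=True,
                        p_sub=0.12)
        contig, g = _single_gene(plan, seed=10)
        loci = scan_six_frames(contig, profile)
        assert loci, "pseudogene locus must be reported"
        for l in loci:
            model = None if l.pseudogene_candidate else (
                l.model or complete_spliced_model(contig, l, profile,
                                                  min_final_score=profile.min_score)
            )
            assert model is None

    def test_no_introns_below_configured_minimum(self, profile, benchmark):
        _, contigs, truth = benchmark
        min_len = profile.intron_length[0]
        for contig in contigs[:3]:
            for l in scan_six_frames(contig, profile):
                if l.model is None and not l.pseudogene_candidate:
                    l.model = complete_spliced_model(contig, l, profile)
                if l.model is not None:
                    for s, e in l.model.introns():
                        assert e - s + 1 >= min_len
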