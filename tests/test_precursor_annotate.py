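import pytest

from fdefminer.errors import ValidationError
from fdefminer.precursor_annotate import (
    annotate_precursor,
    detect_amidation,
    detect_propeptide,
    predict_signal,
    split_domains,
)
from fdefminer.synthetic_data import GenePlan, PlantSpec, plant_genes


class TestPredictSignal:
    def test_classic_signal_cleaved_at_boundary(self):
        # hydrophobic core, then S-N-A end: first (-3, -1) match is at 20
        prec = "MKFLSLVALLLLLLLLNSNA" + "EDDEAKRGFGCNGPWDEDD"
        assert predict_signal(prec) == (1, 20)

    def test_all_hydrophilic_returns_none(self):
        assert predict_signal("MKRNDSEQKRNDSEQKRNDSEQRKND") is None

    def test_planted_boundaries_recovered(self, benchmark):
        _, _, truth = benchmark
        total = good = 0
        for g in truth.genes:
            if g.pseudogene:
                continue
            total += 1
            sig = predict_signal(g.precursor)
            if sig and abs(sig[1] - len(g.signal)) <= 2:
                good += 1
        assert good / total >= 0.90


class TestDetectPropeptide:
    @pytest.mark.parametrize("seg,expect", [
        ("EEDDAASLEKR", True),   # acidic with KR terminus
        ("GGSSGG", False),       # no basic terminus
        ("DDK", True),           # minimal acidic + K
        ("KKKDDK", False),       # net positive despite K terminus
    ])
    def test_rule(self, seg, expect):
        ok, cleave = detect_propeptide(seg)
        assert ok is expect
        if expect:
            assert cleave == len(seg)

    def test_case_invariant(self):
        assert detect_propeptide("eeddaaslekr")[0] is True


class TestDetectAmidation:
    @pytest.mark.parametrize("seq,amidated,trimmed", [
        ("KCYGR", True, "KCYG"),
        ("KCY", False, "KCY"),
        ("KCYGRR", True, "KCYG"),
    ])
    def test_rule(self, seq, amidated, trimmed):
        assert detect_amidation(seq) == (amidated, trimmed)


class TestSplitDomains:
    def test_two_domain_precursor(self, profile):
        contigs, truth = plant_genes(PlantSpec(
            genes=[GenePlan(name="g", architecture="two_domain")], seed=5
        ))
        g = truth.genes[0]
        after = g.precursor[len(g.signal):]
        domains = split_domains(after, profile.envelope)
        assert len(domains) == 2
        s1, e1 = domains[0]
        assert after[s1 - 1 : e1] == g.matures[0]
        s2, _ = domains[1]
        assert after[s2 - 1 :].startswith(g.matures[1])

    def test_single_domain(self, profile):
        contigs, truth = plant_genes(PlantSpec(
            genes=[GenePlan(name="g", architecture="no_pro")], seed=5
        ))
        g = truth.genes[0]
        after = g.precursor[len(g.signal):]
        assert split_domains(after, profile.envelope) == [(1, len(after))]


class TestAnnotatePrecursor:
    def test_segmentation_tiles_precursor(self, benchmark):
        _, _, truth = benchmark
        for g in truth.genes:
            if g.pseudogene:
                continue
            prec = annotate_precursor(g.precursor)
            parts = []
            if prec.signal:
                parts.append(prec.signal)
            pieces = sorted(parts + prec.propeptides + prec.domains)
            covered = []
            for s, e in pieces:
                covered.extend(range(s, e + 1))
            assert covered == list(range(1, len(g.precursor) + 1))

    def test_architecture_recovery(self, benchmark):
        _, _, truth = benchmark
        total = good = 0
        for g in truth.genes:
            if g.pseudogene:
                continue
            total += 1
            prec = annotate_precursor(g.precursor)
            good += prec.architecture == g.architecture
        assert good / total >= 0.95

    def test_mature_of_amidated_gene_keeps_glycine(self, benchmark):
        _, _, truth = benchmark
        g = next(g for g in truth.genes if g.amidation and not g.pseudogene)
        prec = annotate_precursor(g.precursor)
        assert prec.matures[-1].amidated
        assert prec.matures[-1].sequence == g.matures[-1]
        assert prec.matures[-1].sequence.endswith("G")

    def test_signal_override(self):
        prec_seq = "MKFLSLVALLLLVLLVAHSA" + "GFGCNGPWDEDDMQCHNHCKSIKGYKGGYCAKGGFVCKCY"
        prec = annotate_precursor(prec_seq, signal_override=20)
        assert prec.signal == (1, 20)
        assert prec.matures[0].sequence == prec_seq[20:]

    def test_too_many_frameworks_rejected(self, profile):
        fake = "M" + "CAACAAACAAAAAAACAAAAAACAAAAC" * 3
        with pytest.raises(ValidationError):
            annotate_precursor(fake, envelope=[(1, 30)] * 5)

    def test_n_extension_flagged(self):
        # >=15 non-propeptide residues between signal end and C1
        ext = "GGSGGSGGSGGSGGSG"  # 16 residues, not acidic-basic
        prec_seq = ("MKFLSLVALLLLVLLVAHSA" + ext
                    + "GFGCNGPWDEDDMQCHNHCKSIKGYKGGYCAKGGFVCKCY")
        prec = annotate_precursor(prec_seq)
        assert prec.n_extension is not None
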