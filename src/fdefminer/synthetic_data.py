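"""Synthetic fungal contigs with planted defensin genes and a truth table.

The generator emulates every precursor/gene architecture the pipeline must
recognize: 0–2-intron genes (GT..AG introns at chosen regions and phases),
optional acidic propeptides ending in K/R/KR/RR, two-domain precursors with
spacer propeptides, C-terminal Gly-Arg(-Arg) amidation signals, tandem gene
clusters, exon-1-only pseudogenes, and identical-protein paralog pairs
differing only by synonymous codon changes.

Coding sequence is obtained by back-translating the designed precursor with
the standard nuclear codon table and uniform random synonymous codon choice;
intergenic sequence is i.i.d. at a configurable GC fraction.  Everything is
driven by one seeded RNG, so regeneration with the same spec is
byte-identical.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio.Data import CodonTable

from .errors import SpecError
from .genemodel import GeneModel, GenomicContig, revcomp, translate
from .io_formats import SequenceRecord, packaged_seed_path, read_fasta, write_fasta, write_gff3

REGIONS = {"signal", "propeptide", "n_loop", "alpha_helix", "c_loop", "none"}
ARCHITECTURES = {"no_pro", "pro_mature", "two_domain"}

_SUB_POOL = "GASTNQDEKRHYFLIVWP"  # never introduces cysteines

_table = CodonTable.unambiguous_dna_by_id[1]
CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    CODONS_FOR.setdefault(aa, []).append(codon)
STOP_CODONS = sorted(_table.stop_codons)


def _family_templates() -> dict[str, tuple[str, str]]:
    out = {}
    for rec in read_fasta(packaged_seed_path()):
        family = "fDEF1"
        for token in rec.description.split():
            if token.startswith("family="):
                family = token.split("=", 1)[1]
        out[rec.id] = (rec.seq, family)
    return out


FAMILY_TEMPLATES = _family_templates()


def cys_positions(peptide: str) -> list[int]:
    """1-based positions of cysteines."""
    return [i + 1 for i, c in enumerate(peptide) if c == "C"]


def generate_mature(seed: int, family_template: str = "plectasin",
                    p_sub: float = 0.3) -> str:
    """A mature defensin: the named anchor with seeded point substitutions.

    The six framework cysteines are kept fixed and substitutions never
    introduce new cysteines, so the output always carries exactly six
    cysteines in the template's spacing envelope.
    """
    if family_template not in FAMILY_TEMPLATES:
        raise SpecError(f"unknown family template {family_template!r}")
    anchor, _ = FAMILY_TEMPLATES[family_template]
    rng = random.Random(seed)
    out = []
    for c in anchor:
        if c != "C" and rng.random() < p_sub:
            out.append(rng.choice(_SUB_POOL))
        else:
            out.append(c)
    return "".join(out)


def _generate_signal(rng: random.Random) -> str:
    """A cleavable signal peptide: M, charged stub, hydrophobic core, A-X-A end."""
    length = rng.randint(18, 24)
    # core avoids M (no internal start codons) and the small residues that
    # could create premature (-3,-1) cleavage matches
    core = "".join(rng.choice("LFI") for _ in range(length - 6))
    return (
        "M"
        + "".join(rng.choice("KRQNS") for _ in range(2))
        + core
        + rng.choice("AGS")
        + rng.choice("QNH")
        + rng.choice("AGS")
    )


def _generate_propeptide(rng: random.Random) -> str:
    """An acidic propeptide ending in K, R, KR or RR (convertase site)."""
    n_acid = rng.randint(4, 6)
    n_other = rng.randint(3, 7)
    body = [rng.choice("DE") for _ in range(n_acid)]
    body += [rng.choice("ASGTNQLP") for _ in range(n_other)]
    rng.shuffle(body)
    return "".join(body) + rng.choice(["K", "R", "KR", "RR"])


def backtranslate(peptide: str, rng: random.Random) -> str:
    return "".join(rng.choice(CODONS_FOR[aa]) for aa in peptide)


def mutate_synonymous(cds: str, n: int, rng: random.Random) -> str:
    """Apply exactly ``n`` single-nucleotide synonymous changes to ``cds``."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    candidates = []
    for i, codon in enumerate(codons):
        aa = _table.forward_table.get(codon)
        if aa is None:
            continue
        alts = [
            alt
            for alt in CODONS_FOR[aa]
            if sum(a != b for a, b in zip(alt, codon)) == 1
        ]
        if alts:
            candidates.append((i, alts))
    if len(candidates) < n:
        raise SpecError(f"cannot place {n} synonymous changes in CDS")
    for i, alts in rng.sample(candidates, n):
        codons[i] = rng.choice(alts)
    return "".join(codons)


# -- plans ------------------------------------------------------------------


@dataclass
class GenePlan:
    """Design of a single planted gene."""

    name: str
    family_template: str = "plectasin"
    architecture: str = "no_pro"
    introns: list[tuple[str, int]] = field(default_factory=list)
    amidation: bool = False
    pseudogene: bool = False
    cluster: Optional[str] = None
    strand: Optional[str] = None
    paralog_syn: Optional[int] = None
    p_sub: Optional[float] = None  # per-gene divergence override

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise SpecError(f"{self.name}: unknown architecture {self.architecture!r}")
        if len(self.introns) > 2:
            raise SpecError(f"{self.name}: at most 2 introns supported")
        for region, phase in self.introns:
            if region not in REGIONS:
                raise SpecError(f"{self.name}: unknown intron region {region!r}")
            if phase not in (0, 1, 2):
                raise SpecError(f"{self.name}: intron phase must be 0/1/2")
        if self.paralog_syn is not None and self.paralog_syn < 0:
            raise SpecError(f"{self.name}: synonymous-difference count must be >= 0")


@dataclass
class PlantSpec:
    """Full plan for a synthetic genome."""

    genes: list[GenePlan]
    seed: int = 0
    gc: float = 0.45
    p_sub: float = 0.3
    intergenic: tuple[int, int] = (500, 5000)
    intron_length: tuple[int, int] = (60, 300)
    tandem_max_gap: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise SpecError(f"gc fraction out of [0, 1]: {self.gc}")
        if self.intron_length[0] < 10:
            raise SpecError("intron length minimum too small")


@dataclass
class PlantedGene:
    """Ground truth for one planted gene."""

    name: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    intron_phases: list[int]
    intron_regions: list[str]
    architecture: str
    signal: str
    propeptides: list[str]
    matures: list[str]
    amidation: bool
    cluster: Optional[str]
    pseudogene: bool
    precursor: str
    cds: str  # spliced CDS including stop codon

    def gene_model(self) -> GeneModel:
        return GeneModel(self.name, self.contig, self.strand, list(self.exons))


@dataclass
class TruthTable:
    genes: list[PlantedGene]

    def by_name(self) -> dict[str, PlantedGene]:
        return {g.name: g for g in self.genes}

    def to_tsv(self, path: str | Path) -> None:
        header = [
            "name", "contig", "strand", "exons", "intron_phases",
            "intron_regions", "architecture", "amidation", "cluster",
            "pseudogene", "signal", "propeptides", "matures", "precursor",
        ]
        rows = [
            [
                g.name, g.contig, g.strand,
                ";".join(f"{s}-{e}" for s, e in g.exons),
                ";".join(map(str, g.intron_phases)),
                ";".join(g.intron_regions),
                g.architecture, str(int(g.amidation)), g.cluster or "",
                str(int(g.pseudogene)), g.signal,
                ";".join(g.propeptides), ";".join(g.matures), g.precursor,
            ]
            for g in self.genes
        ]
        Path(path).write_text(
            "\n".join("\t".join(r) for r in [header] + rows) + "\n"
        )


# -- gene construction ------------------------------------------------------


def _region_window(region: str, signal: str, propeptides: list[str],
                   matures: list[str], architecture: str,
                   precursor_len: int) -> tuple[int, int]:
    """Residue window (1-based, inclusive, precursor coordinates) for a region."""
    sig_len = len(signal)
    pro_len = len(propeptides[0]) if architecture == "pro_mature" else 0
    dom1_start = sig_len + pro_len + 1
    cys = [dom1_start - 1 + p for p in cys_positions(matures[0])]
    if region == "signal":
        return 3, sig_len - 2
    if region == "propeptide":
        if architecture != "pro_mature":
            raise SpecError("propeptide intron requires pro_mature architecture")
        return sig_len + 1, sig_len + pro_len
    if region == "n_loop":
        return cys[0] + 1, cys[1] - 3
    if region == "alpha_helix":
        return cys[1] - 2, cys[2]
    if region == "c_loop":
        return cys[3] + 1, cys[4] - 1
    if region == "none":
        return 3, precursor_len - 2
    raise SpecError(f"unknown region {region!r}")


@dataclass
class _BuiltGene:
    plan: GenePlan
    gene_seq: str  # genomic sequence of the locus, coding strand
    exons_local: list[tuple[int, int]]
    cds: str
    precursor: str
    signal: str
    propeptides: list[str]
    matures: list[str]
    phases: list[int]
    regions: list[str]


def _sanitize_mature(mature: str, rng: random.Random, *, after_propeptide: bool,
                     amidated: bool) -> str:
    """Keep planted matures unambiguous for the annotation rules.

    A domain that follows a propeptide must not start with K/R (would merge
    into the convertase cleavage run); a domain that directly follows the
    signal must carry no K/R before its first cysteine (would mimic a
    convertase site); a non-amidated terminal domain must not end in GR/GRR
    (would spuriously trigger the amidation rule).
    """
    if after_propeptide:
        if mature[0] in "KR":
            mature = rng.choice("SANQG") + mature[1:]
    else:
        c1 = mature.index("C")
        prefix = "".join(
            rng.choice("SANQG") if c in "KR" else c for c in mature[:c1]
        )
        mature = prefix + mature[c1:]
    if not amidated and (mature.endswith("GR") or mature.endswith("GRR")):
        mature = mature[:-1] + rng.choice("SNYQ")
    return mature


def _build_gene(plan: GenePlan, spec: PlantSpec, rng: random.Random) -> _BuiltGene:
    p_sub = spec.p_sub if plan.p_sub is None else plan.p_sub
    signal = _generate_signal(rng)
    mat_seed = rng.randrange(2**31)
    mature1 = generate_mature(mat_seed, plan.family_template, p_sub)
    propeptides: list[str] = []
    matures: list[str]
    if plan.architecture == "no_pro":
        mature1 = _sanitize_mature(mature1, rng, after_propeptide=False,
                                   amidated=plan.amidation)
        body = mature1
        matures = [mature1]
    elif plan.architecture == "pro_mature":
        propeptides = [_generate_propeptide(rng)]
        mature1 = _sanitize_mature(mature1, rng, after_propeptide=True,
                                   amidated=plan.amidation)
        body = propeptides[0] + mature1
        matures = [mature1]
    else:  # two_domain: domain N truncated at C6, spacer, domain C
        dom_n = mature1[: cys_positions(mature1)[5]]
        dom_c = generate_mature(rng.randrange(2**31), plan.family_template,
                                p_sub)
        propeptides = [_generate_propeptide(rng)]
        dom_c = _sanitize_mature(dom_c, rng, after_propeptide=True,
                                 amidated=plan.amidation)
        body = dom_n + propeptides[0] + dom_c
        matures = [dom_n, dom_c]
    if plan.amidation:
        # terminal domain ends in G (amide donor); genome encodes G-R(-R)
        matures[-1] = matures[-1][:-1] + "G"
        if plan.architecture == "two_domain":
            body = matures[0] + propeptides[0] + matures[1]
        elif plan.architecture == "pro_mature":
            body = propeptides[0] + matures[0]
        else:
            body = matures[0]
        tail = rng.choice(["R", "RR"])
    else:
        tail = ""
    precursor = signal + body + tail
    cds = backtranslate(precursor, rng) + rng.choice(STOP_CODONS)

    # choose intron insertion offsets (coding nucleotides upstream of intron)
    offsets: list[tuple[int, str, int]] = []
    for region, phase in plan.introns:
        lo, hi = _region_window(region, signal, propeptides, matures,
                                plan.architecture, len(precursor))
        if hi < lo:
            raise SpecError(f"{plan.name}: empty window for region {region!r}")
        for _ in range(50):
            residue = rng.randint(lo, hi)
            off = 3 * (residue - 1) + phase
            if 0 < off < len(cds) and all(abs(off - o) >= 6 for o, _, _ in offsets):
                offsets.append((off, region, phase))
                break
        else:
            raise SpecError(f"{plan.name}: cannot place intron in {region!r}")
    offsets.sort()

    if plan.architecture == "two_domain":
        # an AG acceptor inside the coding sequence would allow a chimeric
        # single-domain splice joining the two frameworks; recode it away
        cds = _recode_avoid_ag(cds, 0, len(cds), rng)

    lengths = [rng.randint(*spec.intron_length) for _ in offsets]
    for (off, _, _), length in zip(offsets, lengths):
        # strip AG acceptor decoys from the donor's overshoot reach
        reach = spec.intron_length[1] - length
        cds = _recode_avoid_ag(cds, off, min(len(cds), off + reach + 2), rng)
    introns = [_make_intron(length, spec.gc, rng) for length in lengths]
    gene_seq, exons_local = _insert_introns(cds, [o for o, _, _ in offsets], introns)
    # 5'-delimit the ORF: an in-frame stop immediately upstream of the start
    # codon keeps upstream intergenic ATGs from extending the reading frame
    gene_seq = "TAA" + gene_seq
    exons_local = [(s + 3, e + 3) for s, e in exons_local]

    if plan.pseudogene:
        # keep only exon 1 plus the start of intron 1 (lost downstream
        # exons); the degenerate intron remnant offers no acceptor within
        # splice reach, so the locus cannot be completed into a gene
        if not offsets:
            raise SpecError(f"{plan.name}: a pseudogene plan needs >= 1 intron")
        s, e = exons_local[0]
        remnant = _random_dna(spec.intron_length[1] - 14, spec.gc, rng)
        while "AG" in remnant or "ATG" in remnant:
            remnant = remnant.replace("AG", "A" + rng.choice("CT"), 1)
            remnant = remnant.replace("ATG", "AT" + rng.choice("CT"), 1)
        gene_seq = gene_seq[:e] + "GT" + _STOP_ALL_FRAMES + remnant
        exons_local = [(s, e)]

    return _BuiltGene(
        plan=plan, gene_seq=gene_seq, exons_local=exons_local, cds=cds,
        precursor=precursor, signal=signal, propeptides=propeptides,
        matures=matures, phases=[p for _, _, p in offsets],
        regions=[r for _, r, _ in offsets],
    )


def _copy_gene(built: _BuiltGene, n_syn: int, spec: PlantSpec,
               rng: random.Random) -> _BuiltGene:
    """A paralog copy with exactly ``n_syn`` synonymous CDS differences."""
    cds = mutate_synonymous(built.cds, n_syn, rng)
    # same exon layout as the original: offsets are upstream coding lengths
    lengths = [e - s + 1 for s, e in built.exons_local]
    offsets = []
    total = 0
    for length in lengths[:-1]:
        total += length
        offsets.append(total)
    introns = [
        _make_intron(rng.randint(*spec.intron_length), spec.gc, rng)
        for _ in offsets
    ]
    gene_seq, exons_local = _insert_introns(cds, offsets, introns)
    gene_seq = "TAA" + gene_seq
    exons_local = [(s + 3, e + 3) for s, e in exons_local]
    plan = GenePlan(
        name=built.plan.name + "_syncopy",
        family_template=built.plan.family_template,
        architecture=built.plan.architecture,
        introns=list(built.plan.introns),
        amidation=built.plan.amidation,
        cluster=built.plan.cluster,
        strand=built.plan.strand,
    )
    return _BuiltGene(
        plan=plan, gene_seq=gene_seq, exons_local=exons_local, cds=cds,
        precursor=built.precursor, signal=built.signal,
        propeptides=list(built.propeptides), matures=list(built.matures),
        phases=list(built.phases), regions=list(built.regions),
    )


def _insert_introns(cds: str, offsets: list[int], introns: list[str]):
    """Insert intron sequences after the given coding-nucleotide offsets."""
    pieces, exons, pos = [], [], 0
    cursor = 1
    prev = 0
    for off, intron in zip(offsets, introns):
        exon = cds[prev:off]
        pieces.append(exon)
        exons.append((cursor, cursor + len(exon) - 1))
        cursor += len(exon) + len(intron)
        pieces.append(intron)
        prev = off
    exon = cds[prev:]
    pieces.append(exon)
    exons.append((cursor, cursor + len(exon) - 1))
    return "".join(pieces), exons


def _random_dna(n: int, gc: float, rng: random.Random) -> str:
    return "".join(
        rng.choice("GC") if rng.random() < gc else rng.choice("AT")
        for _ in range(max(n, 0))
    )


#: 12-mer carrying a stop codon in every reading frame: read-through past a
#: donor or into an acceptor-proximal region terminates translation promptly.
_STOP_ALL_FRAMES = "TAAATAAATAAA"


def _make_intron(length: int, gc: float, rng: random.Random) -> str:
    """A GT..AG intron that offers no viable alternative splice/start sites:
    all-frame stop blocks flank the interior, and internal ATGs are excised."""
    interior = _random_dna(length - 4 - 2 * len(_STOP_ALL_FRAMES), gc, rng)
    while "ATG" in interior:
        interior = interior.replace("ATG", "AT" + rng.choice("CT"), 1)
    return "GT" + _STOP_ALL_FRAMES + interior + _STOP_ALL_FRAMES + "AG"


def _recode_avoid_ag(cds: str, lo: int, hi: int, rng: random.Random) -> str:
    """Synonymously recode ``cds[lo:hi]`` to remove AG dinucleotides.

    Keeps the decoy-acceptor overshoot zone downstream of a planted intron
    free of spurious AG acceptors; the translation is unchanged.
    """
    seq = list(cds)
    for _ in range(12):
        s = "".join(seq)
        pos = s.find("AG", lo, hi)
        if pos == -1:
            return s
        fixed = False
        for p in (pos, pos + 1):  # codon holding the A, then the one with G
            ci = p // 3
            codon = s[3 * ci : 3 * ci + 3]
            aa = _table.forward_table.get(codon)
            if aa is None or len(codon) < 3:
                continue
            left = s[3 * ci - 1] if ci > 0 else ""
            right = s[3 * ci + 3] if 3 * ci + 3 < len(s) else ""
            alts = [
                c for c in CODONS_FOR[aa]
                if c != codon and "AG" not in c
                and not (left == "A" and c[0] == "G")
                and not (c[-1] == "A" and right == "G")
            ]
            if alts:
                seq[3 * ci : 3 * ci + 3] = rng.choice(alts)
                fixed = True
                break
        if not fixed:  # no synonymous escape (e.g. Met/Trp codon); leave it
            lo = pos + 2
    return "".join(seq)


# -- genome assembly --------------------------------------------------------


def plant_genes(spec: PlantSpec) -> tuple[list[GenomicContig], TruthTable]:
    """Build the synthetic genome: contigs plus a machine-readable truth table."""
    rng = random.Random(spec.seed)

    built: list[_BuiltGene] = []
    for plan in spec.genes:
        b = _build_gene(plan, spec, rng)
        built.append(b)
        if plan.paralog_syn is not None:
            built.append(_copy_gene(b, plan.paralog_syn, spec, rng))

    # group genes into contigs (one contig per cluster, one per singleton)
    groups: dict[str, list[_BuiltGene]] = {}
    order: list[str] = []
    for b in built:
        key = f"cluster_{b.plan.cluster}" if b.plan.cluster else f"gene_{b.plan.name}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(b)

    contigs: list[GenomicContig] = []
    truth: list[PlantedGene] = []
    lo, hi = spec.intergenic
    cluster_hi = min(hi, spec.tandem_max_gap - 1)
    for idx, key in enumerate(order):
        members = groups[key]
        name = f"ctg{idx + 1:03d}_{key}"
        seq_parts = [_random_dna(rng.randint(300, 800), spec.gc, rng)]
        pos = len(seq_parts[0])
        for j, b in enumerate(members):
            if j > 0:
                gap = rng.randint(lo, cluster_hi if len(members) > 1 else hi)
                spacer = _random_dna(gap, spec.gc, rng)
                seq_parts.append(spacer)
                pos += gap
            strand = b.plan.strand or rng.choice("+-")
            insert = b.gene_seq if strand == "+" else revcomp(b.gene_seq)
            glen = len(insert)
            exons = []
            for s, e in b.exons_local:
                if strand == "+":
                    exons.append((pos + s, pos + e))
                else:
                    exons.append((pos + glen - e + 1, pos + glen - s + 1))
            exons.sort()
            seq_parts.append(insert)
            pos += glen
            truth.append(
                PlantedGene(
                    name=b.plan.name, contig=name, strand=strand, exons=exons,
                    intron_phases=list(b.phases), intron_regions=list(b.regions),
                    architecture=b.plan.architecture, signal=b.signal,
                    propeptides=list(b.propeptides),
                    matures=[] if b.plan.pseudogene else list(b.matures),
                    amidation=b.plan.amidation, cluster=b.plan.cluster,
                    pseudogene=b.plan.pseudogene, precursor=b.precursor,
                    cds=b.cds,
                )
            )
        seq_parts.append(_random_dna(rng.randint(300, 800), spec.gc, rng))
        contigs.append(GenomicContig(name, "".join(seq_parts)))

    table = TruthTable(truth)
    _validate_truth(contigs, table)
    return contigs, table


def _validate_truth(contigs: list[GenomicContig], truth: TruthTable) -> None:
    seqs = {c.id: c.seq for c in contigs}
    for g in truth.genes:
        if g.pseudogene:
            continue
        model = g.gene_model()
        if translate(model.cds(seqs[g.contig])) != g.precursor:
            raise SpecError(f"internal error: truth CDS mismatch for {g.name}")


# -- benchmark plan ---------------------------------------------------------

_INTRON_PLANS = [
    [],
    [("alpha_helix", 0)],
    [("c_loop", 2)],
    [("alpha_helix", 0), ("c_loop", 2)],
    [("signal", 1)],
    [],
    [("c_loop", 1)],
    [("alpha_helix", 0), ("c_loop", 2)],
    [("signal", 0)],
    [("alpha_helix", 2)],
]


def default_benchmark_spec(n_genes: int = 50, seed: int = 0,
                           n_pseudogenes: int = 2) -> PlantSpec:
    """The standard planted-truth benchmark used by the test-bench.

    ``n_genes`` complete genes cycling through family templates, intron
    plans (0–2 introns at the observed regions/phases) and architectures,
    plus tandem clusters of 4 and 7 genes, one identical-protein paralog
    pair with 4 synonymous differences, and ``n_pseudogenes`` exon-1-only
    pseudogene plants.
    """
    templates = sorted(FAMILY_TEMPLATES)
    plans: list[GenePlan] = []
    for i in range(n_genes):
        if i % 7 == 3:
            arch = "two_domain"
        elif i % 3 == 1:
            arch = "pro_mature"
        else:
            arch = "no_pro"
        cluster = None
        if i < 4:
            cluster = "A"
        elif i < 11:
            cluster = "B"
        plans.append(
            GenePlan(
                name=f"gene{i + 1:03d}",
                family_template=templates[i % len(templates)],
                architecture=arch,
                introns=list(_INTRON_PLANS[i % len(_INTRON_PLANS)]),
                amidation=(i % 5 == 2),
                cluster=cluster,
                paralog_syn=4 if i == 12 else None,
            )
        )
    for j in range(n_pseudogenes):
        plans.append(
            GenePlan(
                name=f"pseudo{j + 1:02d}",
                family_template=templates[j % len(templates)],
                architecture="no_pro",
                # a c-loop intron leaves the first four framework cysteines
                # on exon 1, mirroring a truncation that loses the last exons
                introns=[("c_loop", 2)],
                pseudogene=True,
                # pseudogenes are detectable through high first-exon
                # similarity, so they diverge less than intact paralogs
                p_sub=0.12,
            )
        )
    return PlantSpec(genes=plans, seed=seed)


def write_outputs(contigs: list[GenomicContig], truth: TruthTable,
                  outdir: str | Path) -> None:
    """Emit genome FASTA, truth GFF3 and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [SequenceRecord(c.id, "", c.seq, "dna") for c in contigs],
        outdir / "genome.fna",
    )
    write_gff3([g.gene_model() for g in truth.genes], outdir / "truth.gff3")
    truth.to_tsv(outdir / "truth.tsv")
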