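"""End-to-end orchestration: scan → annotate → physchem → structure →
classify → duplication, plus the catalog tally.

``run_pipeline`` is deterministic given the config seed and writes a
Table-style peptide report (name, family, size, MW, NC, ...), a GFF3 of
gene models, a newick family tree with bootstrap support, cluster/pair
tables and a summary.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .duplication_analysis import count_synonymous, find_clusters, paralog_pairs
from .errors import ValidationError
from .family_classify import (
    assign_family,
    bootstrap_support,
    pairwise_identity,
    star_alignment,
)
from .gene_structure import flag_pseudogene, intron_records
from .genemodel import GeneModel, GenomicContig
from .io_formats import CatalogRecord, read_fasta, write_gff3
from .motif_scan import SeedProfile, complete_spliced_model, scan_six_frames
from .precursor_annotate import DefensinPrecursor, MaturePeptide, annotate_precursor

logger = logging.getLogger("fdefminer")


@dataclass
class PipelineConfig:
    genome: str | Path
    out_dir: str | Path
    seeds: Optional[str | Path] = None
    seed: int = 0
    ph: float = 7.0
    bootstrap_reps: int = 100
    min_support: float = 50.0
    cluster_max_gap: int = 30_000
    paralog_identity_min: float = 0.70
    profile_overrides: dict = field(default_factory=dict)


@dataclass
class DiscoveredGene:
    model: GeneModel
    precursor: DefensinPrecursor
    introns: list
    matures: list[MaturePeptide]


@dataclass
class PipelineResult:
    genes: list[DiscoveredGene]
    pseudogenes: list[tuple[str, str, tuple[int, int], str]]  # name, contig, interval, reason
    families: dict[str, str]
    newick: str
    clusters: list
    pairs: list
    syn_counts: dict[tuple[str, str], tuple[int, int, int]]

    @property
    def matures(self) -> list[MaturePeptide]:
        return [m for g in self.genes for m in g.matures]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = [
        GenomicContig(r.id, r.seq) for r in read_fasta(config.genome)
    ]
    logger.info("loaded %d contigs", len(contigs))
    profile = SeedProfile.from_seed_fasta(config.seeds,
                                          **config.profile_overrides)

    genes: list[DiscoveredGene] = []
    pseudo: list[tuple[str, str, tuple[int, int], str]] = []
    for contig in contigs:
        modeled: list = []
        failed: list = []
        for locus in scan_six_frames(contig, profile):
            if locus.model is None and not locus.pseudogene_candidate:
                # a similarity-definite locus without a full motif hit must
                # complete into a model that itself clears the threshold
                gate = profile.min_score if (
                    locus.best_seed is not None
                    and locus.best_seed[1] >= profile.min_score
                    and not locus.motif_match
                ) else 0
                locus.model = complete_spliced_model(contig, locus, profile,
                                                     min_final_score=gate)
            if locus.model is None:
                failed.append(locus)
            else:
                modeled.append(locus)

        # among overlapping same-strand models keep the most complete one
        # (narrow provisional windows can yield partial single-domain
        # models of a two-domain gene)
        def rank(locus):
            from .precursor_annotate import predict_signal

            prot = locus.model.protein(contig.seq)
            introns = locus.model.introns()
            return (
                prot.count("C") // 6,
                predict_signal(prot) is not None,
                -len(introns),
                -sum(e - s + 1 for s, e in introns),
                -locus.model.coding_length,
                -locus.model.span[0],
            )

        kept: list = []
        for locus in sorted(modeled, key=rank, reverse=True):
            span = locus.model.span
            clash = any(
                k.model.strand == locus.model.strand
                and not (span[1] < k.model.span[0] or span[0] > k.model.span[1])
                for k in kept
            )
            if not clash:
                kept.append(locus)
        kept.sort(key=lambda l: l.model.span)

        counter = 0
        for locus in kept:
            counter += 1
            locus.model.name = f"{contig.id}_g{counter}"
            protein = locus.model.protein(contig.seq)
            try:
                prec = annotate_precursor(protein, name=locus.model.name,
                                          envelope=profile.envelope)
            except ValidationError as exc:
                logger.warning("annotation failed for %s: %s",
                               locus.model.name, exc)
                pseudo.append((locus.model.name, contig.id, locus.interval,
                               "missing_cysteines"))
                continue
            genes.append(
                DiscoveredGene(
                    model=locus.model, precursor=prec,
                    introns=intron_records(locus.model, prec),
                    matures=prec.matures,
                )
            )
        for locus in failed:
            is_pseudo, reason = flag_pseudogene(locus, profile, contig.seq)
            if is_pseudo:
                pseudo.append(
                    (f"{contig.id}_pseu{len(pseudo) + 1}", contig.id,
                     locus.interval, reason or "unknown")
                )
    # drop pseudogene loci overlapping a recovered gene (antisense or
    # flanking shadows of real loci)
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.model.contig, []).append(g.model.span)
    pseudo = [
        p for p in pseudo
        if not any(
            not (p[2][1] < s or p[2][0] > e) for s, e in spans.get(p[1], [])
        )
    ]
    # merge adjacent pseudogene loci (windowed hits on one truncated gene)
    pseudo.sort(key=lambda p: (p[1], p[2]))
    merged_pseudo: list = []
    for p in pseudo:
        if merged_pseudo and merged_pseudo[-1][1] == p[1] \
                and p[2][0] <= merged_pseudo[-1][2][1] + 2000:
            prev = merged_pseudo[-1]
            merged_pseudo[-1] = (prev[0], prev[1],
                                 (prev[2][0], max(prev[2][1], p[2][1])),
                                 prev[3])
        else:
            merged_pseudo.append(p)
    pseudo = merged_pseudo
    logger.info("scan+completion: %d genes, %d pseudogene loci",
                len(genes), len(pseudo))

    matures = [m for g in genes for m in g.matures]
    anchors = {name: fam for name, _, fam in profile.seeds
               if fam != "unassigned"}
    anchor_seqs = {name: seq for name, seq, _ in profile.seeds}
    peptides = [(m.name, m.sequence) for m in matures]
    peptides += [(n, anchor_seqs[n]) for n in sorted(anchors)]

    families: dict[str, str] = {}
    newick = ""
    if len(peptides) >= 3 and matures:
        msa = star_alignment(peptides)
        tree = bootstrap_support(msa, n_reps=config.bootstrap_reps,
                                 seed=config.seed)
        tree.anchors = dict(anchors)
        seq_of = dict(peptides)
        ident_cache: dict[tuple[str, str], float] = {}

        def ident(q: str, a: str) -> float:
            key = (q, a)
            if key not in ident_cache:
                ident_cache[key] = pairwise_identity(seq_of[q], seq_of[a])
            return ident_cache[key]

        for m in matures:
            families[m.name] = assign_family(
                tree, anchors, m.name, ident,
                min_support=config.min_support,
            )
            m.family = families[m.name]
        newick = tree.to_newick()
    logger.info("classified %d mature peptides", len(families))

    models = [g.model for g in genes]
    clusters = find_clusters(models, max_gap=config.cluster_max_gap)
    contig_of = {m.name: g.model.contig for g in genes for m in g.matures}
    pairs = paralog_pairs(
        [(m.name, m.sequence) for m in matures],
        identity_min=config.paralog_identity_min, contigs=contig_of,
    )
    seqs = {c.id: c.seq for c in contigs}
    cds_of = {g.model.name: g.model.cds(seqs[g.model.contig]) for g in genes}
    prot_of = {g.model.name: g.precursor.sequence for g in genes}
    syn_counts = {}
    names = sorted(prot_of)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if prot_of[a] == prot_of[b] and len(cds_of[a]) == len(cds_of[b]):
                syn_counts[(a, b)] = count_synonymous(cds_of[a], cds_of[b])
    logger.info("%d tandem clusters, %d paralog pairs, %d identical-protein "
                "CDS comparisons", len(clusters), len(pairs), len(syn_counts))

    result = PipelineResult(
        genes=genes, pseudogenes=pseudo, families=families, newick=newick,
        clusters=clusters, pairs=pairs, syn_counts=syn_counts,
    )
    _write_reports(result, config, out_dir)
    return result


def _write_reports(result: PipelineResult, config: PipelineConfig,
                   out_dir: Path) -> None:
    rows = ["\t".join([
        "name", "family", "size", "mw", "nc", "amidated", "architecture",
        "contig", "strand", "start", "end", "n_introns", "intron_phases",
        "intron_regions",
    ])]
    for g in result.genes:
        span = g.model.span
        phases = ";".join(str(i.phase) for i in g.introns)
        regions = ";".join(i.region for i in g.introns)
        for m in g.matures:
            rows.append("\t".join(map(str, [
                m.name, m.family, m.size, f"{m.mw:.0f}",
                f"{m.nc(config.ph):+.1f}", int(m.amidated),
                g.precursor.architecture, g.model.contig, g.model.strand,
                span[0], span[1], len(g.introns), phases, regions,
            ])))
    (out_dir / "peptides.tsv").write_text("\n".join(rows) + "\n")

    write_gff3([g.model for g in result.genes], out_dir / "genes.gff3")
    (out_dir / "tree.nwk").write_text(result.newick + "\n")

    rows = ["\t".join(["contig", "n_genes", "members", "orientations",
                       "max_gap"])]
    for c in result.clusters:
        rows.append("\t".join([
            c.contig, str(len(c.genes)),
            ";".join(g.name for g in c.genes), "".join(c.orientations),
            str(c.max_gap),
        ]))
    (out_dir / "clusters.tsv").write_text("\n".join(rows) + "\n")

    rows = ["\t".join(["name_a", "name_b", "identity", "same_contig",
                       "n_syn", "n_nonsyn"])]
    for p in result.pairs:
        syn = ""
        nonsyn = ""
        for (a, b), (_, s, n) in result.syn_counts.items():
            if {a, b} == {p.name_a, p.name_b}:
                syn, nonsyn = str(s), str(n)
        rows.append("\t".join([p.name_a, p.name_b, f"{p.identity:.3f}",
                               str(int(p.same_contig)), syn, nonsyn]))
    (out_dir / "pairs.tsv").write_text("\n".join(rows) + "\n")

    rows = ["\t".join(["name", "contig", "start", "end", "reason"])]
    for name, contig, (s, e), reason in result.pseudogenes:
        rows.append("\t".join([name, contig, str(s), str(e), reason]))
    (out_dir / "pseudogenes.tsv").write_text("\n".join(rows) + "\n")

    summary = {
        "n_genes": len(result.genes),
        "n_peptides": len(result.matures),
        "n_two_domain_genes": sum(
            1 for g in result.genes if len(g.matures) == 2
        ),
        "n_pseudogenes": len(result.pseudogenes),
        "n_clusters": len(result.clusters),
        "n_paralog_pairs": len(result.pairs),
        "per_family": dict(Counter(result.families.values())),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")


# -- catalog tally ----------------------------------------------------------


@dataclass
class CatalogSummary:
    n_peptides: int
    n_genes: int
    per_phylum: dict[str, int]
    per_family: dict[str, int]
    per_strain: dict[str, int]
    n_two_domain_genes: int
    n_pseudogenes: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides != self.n_genes + self.n_two_domain_genes:
            raise ValidationError("peptide/gene/two-domain counts inconsistent")
        if sum(self.per_family.values()) != self.n_peptides:
            raise ValidationError("family counts do not sum to peptide count")


def tally_catalog(records: list[CatalogRecord]) -> CatalogSummary:
    """Peptide- and gene-level tallies of the catalog.

    Rows whose names differ only by a terminal N/C domain tag and share an
    accession are merged into one (two-domain) gene.  An N without a
    matching C (or vice versa) is logged and counted as its own gene.
    """
    n_peptides = len(records)
    tags: dict[tuple[str, str], set[str]] = {}
    for r in records:
        if r.name and r.name[-1] in "NC" and len(r.name) > 1:
            tags.setdefault((r.name[:-1], r.accession), set()).add(r.name[-1])
    n_pairs = 0
    for (base, acc), seen in sorted(tags.items()):
        if seen == {"N", "C"}:
            n_pairs += 1
        else:
            logger.warning("domain-tagged row %s|%s lacks its partner; "
                           "counted as a separate gene", base, acc)
    strain_counts: Counter = Counter()
    for r in records:
        if r.strain:
            strain_counts[f"{r.organism} {r.strain}"] += 1
    return CatalogSummary(
        n_peptides=n_peptides,
        n_genes=n_peptides - n_pairs,
        per_phylum=dict(Counter(r.phylum for r in records)),
        per_family=dict(Counter(r.family for r in records)),
        per_strain=dict(strain_counts),
        n_two_domain_genes=n_pairs,
    )
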