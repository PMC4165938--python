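"""Tandem gene clusters, paralog pairs and synonymous-substitution counts.

Gene duplication leaves two signatures this module detects: tandem
arrangement of defensin genes on one contig (single-linkage chaining with a
configurable inter-gene gap), and paralog pairs whose proteins are (near-)
identical while their CDSs differ only by synonymous codon changes.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

from .errors import ValidationError
from .family_classify import pairwise_identity
from .genemodel import GeneModel

_TABLE = CodonTable.unambiguous_dna_by_id[1]


@dataclass
class GeneCluster:
    contig: str
    genes: list[GeneModel]  # ordered by genomic start
    gaps: list[int]  # inter-gene gaps in bp (len = len(genes) - 1)

    @property
    def max_gap(self) -> int:
        return max(self.gaps) if self.gaps else 0

    @property
    def orientations(self) -> list[str]:
        return [g.strand for g in self.genes]


def find_clusters(gene_models: list[GeneModel],
                  max_gap: int = 30_000) -> list[GeneCluster]:
    """Single-linkage tandem clusters per contig (singletons excluded)."""
    by_contig: dict[str, list[GeneModel]] = {}
    for gm in gene_models:
        by_contig.setdefault(gm.contig, []).append(gm)
    clusters = []
    for contig in sorted(by_contig):
        genes = sorted(by_contig[contig], key=lambda g: g.span)
        chain, gaps = [genes[0]], []
        for g in genes[1:]:
            gap = g.span[0] - chain[-1].span[1] - 1
            if gap <= max_gap:
                chain.append(g)
                gaps.append(gap)
            else:
                if len(chain) > 1:
                    clusters.append(GeneCluster(contig, chain, gaps))
                chain, gaps = [g], []
        if len(chain) > 1:
            clusters.append(GeneCluster(contig, chain, gaps))
    return clusters


def count_synonymous(cds_a: str, cds_b: str) -> tuple[int, int, int]:
    """(total, synonymous, nonsynonymous) nucleotide differences, by codon.

    A differing codon pair that translates identically contributes its
    nucleotide differences to the synonymous count, otherwise to the
    nonsynonymous count.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    if len(cds_a) != len(cds_b):
        raise ValidationError("CDS length mismatch")
    if len(cds_a) % 3:
        raise ValidationError("CDS length not divisible by 3")
    n_syn = n_non = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if ca == cb:
            continue
        diffs = sum(x != y for x, y in zip(ca, cb))
        aa_a = "*" if ca in _TABLE.stop_codons else _TABLE.forward_table.get(ca)
        aa_b = "*" if cb in _TABLE.stop_codons else _TABLE.forward_table.get(cb)
        if aa_a is None or aa_b is None:
            raise ValidationError(f"untranslatable codon {ca!r}/{cb!r}")
        if aa_a == aa_b:
            n_syn += diffs
        else:
            n_non += diffs
    return n_syn + n_non, n_syn, n_non


@dataclass
class ParalogPair:
    name_a: str
    name_b: str
    identity: float
    same_contig: bool


def paralog_pairs(peptides: list[tuple[str, str]],
                  identity_min: float = 0.70,
                  contigs: dict[str, str] | None = None) -> list[ParalogPair]:
    """All peptide pairs at or above ``identity_min`` global identity."""
    contigs = contigs or {}
    out = []
    for i in range(len(peptides)):
        for j in range(i + 1, len(peptides)):
            (na, sa), (nb, sb) = peptides[i], peptides[j]
            ident = pairwise_identity(sa, sb)
            if ident >= identity_min:
                same = (
                    na in contigs and nb in contigs
                    and contigs[na] == contigs[nb]
                )
                out.append(ParalogPair(na, nb, ident, same))
    return out
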