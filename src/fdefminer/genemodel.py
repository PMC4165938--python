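"""Core genomic containers: contigs and spliced gene models.

Coordinates are 1-based inclusive throughout (GFF3 convention).  Exons are
stored in ascending genomic order; for minus-strand models the transcription
order is the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import ValidationError

Interval = tuple[int, int]


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(cds: str) -> str:
    """Translate a CDS (standard nuclear code); trailing stop dropped."""
    prot = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    return prot[:-1] if prot.endswith("*") else prot


@dataclass
class GenomicContig:
    """A named nucleotide sequence, optionally carrying planted-truth notes."""

    id: str
    seq: str
    annotations: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """Exon coordinates, strand and contig of one (putative) gene.

    ``exons`` cover the CDS including the stop codon.
    """

    name: str
    contig: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for start, end in self.exons:
            if start < 1 or end < start:
                raise ValidationError(f"bad exon ({start}, {end}) in {self.name}")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValidationError(f"overlapping exons in {self.name}")

    # -- geometry -----------------------------------------------------------

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def exons_transcribed(self) -> list[Interval]:
        """Exons in transcription (5'→3') order."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    def introns(self) -> list[Interval]:
        """Intron intervals in transcription order (genomic coordinates)."""
        gaps = [
            (e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]
        return gaps if self.strand == "+" else gaps[::-1]

    # -- sequence -----------------------------------------------------------

    def cds(self, contig_seq: str) -> str:
        """Spliced coding sequence, 5'→3' (stop codon included)."""
        joined = "".join(contig_seq[s - 1 : e] for s, e in self.exons)
        return joined if self.strand == "+" else revcomp(joined)

    def protein(self, contig_seq: str) -> str:
        return translate(self.cds(contig_seq))

    def upstream_coding_lengths(self) -> list[int]:
        """Coding nucleotides upstream of each intron, transcription order."""
        lengths = [e - s + 1 for s, e in self.exons_transcribed]
        out, acc = [], 0
        for length in lengths[:-1]:
            acc += length
            out.append(acc)
        return out
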