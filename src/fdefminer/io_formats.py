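"""Reading and writing the standard formats the pipeline touches.

FASTA (via Biopython), GFF3 gene models, and the packaged peptide catalog
(a TSV transcription of the published summary tables, 45 + 24 rows).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .errors import FormatError, ValidationError
from .genemodel import GeneModel

DNA_CHARS = set("ACGTUN")
FAMILIES = {"fDEF1", "fDEF2", "fDEF3", "fDEF4", "fDEF6", "fDEF8", "unassigned"}

#: Typographic minus variants normalized to ASCII '-' at parse time.
_MINUS_CHARS = {"‒": "-", "–": "-", "−": "-", "‐": "-"}


@dataclass
class SequenceRecord:
    id: str
    description: str
    seq: str
    moltype: str  # {"dna", "protein"}


def _infer_moltype(seq: str) -> str:
    return "dna" if set(seq) <= DNA_CHARS else "protein"


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file; sequences uppercased, gap characters stripped."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        if not rec.id:
            raise FormatError(f"record with empty header in {path}")
        if not seq:
            raise FormatError(f"empty sequence for record {rec.id!r} in {path}")
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, desc, seq, _infer_moltype(seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records at 60-column wrapping (round-trip-stable with read_fasta)."""
    seqrecords = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(seqrecords)


# -- catalog ----------------------------------------------------------------


@dataclass
class CatalogRecord:
    """One mature peptide row of the packaged catalog."""

    name: str
    accession: str
    family: str
    organism: str
    phylum: str
    size: int
    mw: float
    nc: float
    evidence: str = ""
    strain: str = ""
    subphylum: str = ""
    taxclass: str = ""
    contig: Optional[str] = None
    range: Optional[tuple[int, int]] = None
    table: int = 1

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"{self.name}: unknown family {self.family!r}")
        if self.size < 1:
            raise ValidationError(f"{self.name}: size must be >= 1")
        if self.mw <= 0:
            raise ValidationError(f"{self.name}: mw must be > 0")


def normalize_signed_number(text: str) -> float:
    """Parse a printed signed number, accepting typographic minus signs."""
    text = text.strip()
    for bad, good in _MINUS_CHARS.items():
        text = text.replace(bad, good)
    if text.startswith("+"):
        text = text[1:]
    return float(text)


_CATALOG_COLUMNS = [
    "name", "accession", "evidence", "family", "organism", "strain",
    "phylum", "subphylum", "class", "contig", "range_start", "range_end",
    "size", "mw", "nc", "table",
]


def load_catalog(path: str | Path | None = None) -> list[CatalogRecord]:
    """Load the peptide catalog TSV (the packaged fixture by default)."""
    if path is None:
        path = importlib.resources.files("fdefminer.data") / "catalog_tables.tsv"
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _CATALOG_COLUMNS:
        raise FormatError(f"unexpected catalog header: {list(df.columns)}")
    records = []
    for _, row in df.iterrows():
        name = row["name"]
        try:
            size = int(row["size"])
            mw = normalize_signed_number(row["mw"])
            nc = normalize_signed_number(row["nc"])
            rng = None
            if row["range_start"]:
                rng = (int(row["range_start"]), int(row["range_end"]))
        except ValueError as exc:
            raise FormatError(f"unparseable numeric cell in row {name!r}: {exc}")
        records.append(
            CatalogRecord(
                name=name,
                accession=row["accession"],
                family=row["family"],
                organism=row["organism"],
                phylum=row["phylum"],
                size=size,
                mw=mw,
                nc=nc,
                evidence=row["evidence"],
                strain=row["strain"],
                subphylum=row["subphylum"],
                taxclass=row["class"],
                contig=row["contig"] or None,
                range=rng,
                table=int(row["table"]),
            )
        )
    return records


# -- GFF3 -------------------------------------------------------------------


def write_gff3(gene_models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive, CDS phase set.

    The GFF3 phase column gives the number of bases to skip at the start of
    a CDS part to reach the first complete codon.
    """
    lines = ["##gff-version 3"]
    for gm in gene_models:
        start, end = gm.span
        gid = gm.name
        attrs = f"ID={gid}"
        lines.append(
            "\t".join(
                [gm.contig, "fdefminer", "gene", str(start), str(end), ".",
                 gm.strand, ".", attrs]
            )
        )
        lines.append(
            "\t".join(
                [gm.contig, "fdefminer", "mRNA", str(start), str(end), ".",
                 gm.strand, ".", f"ID={gid}.t1;Parent={gid}"]
            )
        )
        upstream = 0
        for s, e in gm.exons_transcribed:
            lines.append(
                "\t".join(
                    [gm.contig, "fdefminer", "exon", str(s), str(e), ".",
                     gm.strand, ".", f"Parent={gid}.t1"]
                )
            )
            phase_col = (3 - upstream % 3) % 3
            lines.append(
                "\t".join(
                    [gm.contig, "fdefminer", "CDS", str(s), str(e), ".",
                     gm.strand, str(phase_col), f"ID={gid}.cds;Parent={gid}.t1"]
                )
            )
            upstream += e - s + 1
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models back (CDS lines grouped by Parent mRNA)."""
    by_gene: dict[str, dict] = {}
    order: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if len(parts) != 9:
            raise FormatError(f"bad GFF3 line: {raw!r}")
        contig, _, ftype, start, end, _, strand, _, attrs = parts
        if ftype != "CDS":
            continue
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        parent = fields.get("Parent", fields.get("ID", "gene"))
        gene = parent.rsplit(".t1", 1)[0]
        if gene not in by_gene:
            by_gene[gene] = {"contig": contig, "strand": strand, "exons": []}
            order.append(gene)
        by_gene[gene]["exons"].append((int(start), int(end)))
    return [
        GeneModel(name=g, contig=d["contig"], strand=d["strand"], exons=d["exons"])
        for g, d in ((g, by_gene[g]) for g in order)
    ]


def packaged_seed_path() -> Path:
    """Path of the packaged seed/anchor peptide FASTA."""
    return Path(str(importlib.resources.files("fdefminer.data") / "seed_anchors_synthetic.faa"))
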