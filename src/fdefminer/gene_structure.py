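"""Intron phases, intron localization on the precursor, pseudogene flags.

Intron phase is the number of coding nucleotides upstream of the intron
modulo 3 (phase 0: between codons; 1/2: after the first/second base of a
codon).  Intron *region* maps the interrupted codon onto the precursor
segmentation and the CSαβ framework: the α-helix window is taken as
[C2−2, C3] and the c-loop as the open interval (C4, C5) — heuristic windows
from the canonical fold topology, since per-family structures are unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError
from .genemodel import GeneModel
from .motif_scan import CandidateLocus, SeedProfile
from .precursor_annotate import DefensinPrecursor

PSEUDOGENE_REASONS = {"missing_cysteines", "premature_stop", "truncated_exons"}


@dataclass
class IntronRecord:
    gene: str
    ordinal: int  # 1-based, transcription order
    interval: tuple[int, int]  # genomic, 1-based inclusive
    phase: int
    region: str


def intron_phase(gene_model: GeneModel, intron_ordinal: int) -> int:
    """Phase of the ``intron_ordinal``-th intron (1-based, transcription order)."""
    upstream = gene_model.upstream_coding_lengths()
    if not 1 <= intron_ordinal <= len(upstream):
        raise ValidationError(
            f"{gene_model.name}: no intron #{intron_ordinal} "
            f"({len(upstream)} present)"
        )
    return upstream[intron_ordinal - 1] % 3


def interrupted_residue(gene_model: GeneModel, intron_ordinal: int) -> int:
    """1-based precursor residue whose codon the intron precedes/interrupts."""
    upstream = gene_model.upstream_coding_lengths()[intron_ordinal - 1]
    return upstream // 3 + 1


def localize_intron(gene_model: GeneModel,
                    segmentation: Optional[DefensinPrecursor],
                    intron_ordinal: int) -> str:
    """Precursor region hit by an intron.

    Priority: signal and propeptide from the segmentation; then, using the
    first domain's framework (precursor coordinates): α-helix [C2−2, C3],
    c-loop (C4, C5), n-loop (C1, C2−3); anything else is ``c_terminal``.
    """
    if segmentation is None or not segmentation.matures:
        return "unknown"
    r = interrupted_residue(gene_model, intron_ordinal)
    if segmentation.signal and r <= segmentation.signal[1]:
        return "signal"
    for s, e in segmentation.propeptides:
        if s <= r <= e:
            return "propeptide"
    d1s = segmentation.domains[0][0]
    cys = [d1s + p - 1 for p in segmentation.matures[0].cys_positions]
    if cys[1] - 2 <= r <= cys[2]:
        return "alpha_helix"
    if cys[3] < r < cys[4]:
        return "c_loop"
    if cys[0] < r <= cys[1] - 3:
        return "n_loop"
    return "c_terminal"


def intron_records(gene_model: GeneModel,
                   segmentation: Optional[DefensinPrecursor]
                   ) -> list[IntronRecord]:
    out = []
    for k, interval in enumerate(gene_model.introns(), start=1):
        out.append(
            IntronRecord(
                gene=gene_model.name, ordinal=k, interval=interval,
                phase=intron_phase(gene_model, k),
                region=localize_intron(gene_model, segmentation, k),
            )
        )
    return out


def flag_pseudogene(locus: CandidateLocus, profile: SeedProfile,
                    contig_seq: str,
                    protein: Optional[str] = None) -> tuple[bool, Optional[str]]:
    """Pseudogene call for a candidate locus.

    A locus whose spliced completion failed (``locus.model`` is None) is a
    pseudogene; the reason is ``truncated_exons`` when a stop-free coding
    prefix runs into a splice donor shortly after its last
    envelope-consistent cysteine (downstream exons lost), otherwise
    ``missing_cysteines`` when a complete ORF lacks the six-cysteine
    framework, else ``premature_stop``.
    """
    if locus.model is not None:
        prot = protein or locus.model.protein(contig_seq)
        if profile._full_re.search(prot):
            return False, None
        return True, "missing_cysteines"
    prot, had_stop, donor_nearby = _best_orf_evidence(locus, profile, contig_seq)
    if prot is None:
        return True, "missing_cysteines"
    if prot.count("C") < 6:
        if had_stop and donor_nearby and not _long_tail(prot):
            return True, "truncated_exons"
        if not had_stop or _long_tail(prot):
            return True, "missing_cysteines"
        return True, "premature_stop"
    return True, "premature_stop"


def _long_tail(prot: str, min_tail: int = 25) -> bool:
    """Did translation continue well past the last cysteine before stopping?"""
    last_c = prot.rfind("C")
    return last_c >= 0 and len(prot) - last_c - 1 >= min_tail


def _best_orf_evidence(locus: CandidateLocus, profile: SeedProfile,
                       contig_seq: str):
    """Longest ATG-initiated reading in the locus window: its translation up
    to the first stop, whether a stop terminated it, and whether a GT donor
    lies within 30 nt downstream of the last cysteine codon."""
    from .genemodel import revcomp, translate

    L = len(contig_seq)
    s, e = locus.interval
    margin = profile.margin
    if locus.strand == "+":
        lo, hi = max(0, s - 1 - margin), min(L, e + margin)
        window = contig_seq[lo:hi]
    else:
        lo, hi = max(0, L - e - margin), min(L, L - s + 1 + margin)
        window = revcomp(contig_seq)[lo:hi]
    best = None
    import re as _re

    for m in _re.finditer("ATG", window):
        a = m.start()
        prot_full = translate(window[a:])
        stop_idx = prot_full.find("*")
        had_stop = stop_idx >= 0
        prot = prot_full[:stop_idx] if had_stop else prot_full
        if len(prot) < 20:
            continue
        last_c = prot.rfind("C")
        donor_nearby = False
        if last_c >= 0:
            zone = window[a + 3 * (last_c + 1) : a + 3 * (last_c + 1) + 33]
            donor_nearby = "GT" in zone
        cand = (prot.count("C"), len(prot), prot, had_stop, donor_nearby)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        return None, False, False
    return best[2], best[3], best[4]
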