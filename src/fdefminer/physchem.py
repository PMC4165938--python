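"""Physicochemical properties of peptides: average mass and net charge.

Net charge follows the Henderson–Hasselbalch formalism used by the classical
web protein calculators: every ionizable group contributes the fraction of
molecules protonated (basic groups, positive) or deprotonated (acidic groups,
negative) at the given pH.  Cysteines are treated as reduced (ionizable) by
default; disulfide-bonded cysteines can be excluded via ``n_disulfides``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import molecular_weight

from .errors import ValidationError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: pKa values in the Protein Calculator v3.4 family.
_DEFAULT_BASIC = {"n_terminus": 8.0, "K": 10.0, "R": 12.0, "H": 6.5}
_DEFAULT_ACIDIC = {"c_terminus": 3.1, "D": 4.4, "E": 4.4, "C": 8.5, "Y": 10.0}


@dataclass(frozen=True)
class PkaTable:
    """pKa values per ionizable group.

    ``basic`` groups contribute positive charge when protonated;
    ``acidic`` groups contribute negative charge when deprotonated.
    When ``exclude_disulfide_cys`` is set, ``2 * n_disulfides`` cysteines
    are removed from the ionizable pool in :func:`net_charge`.
    """

    basic: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASIC))
    acidic: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ACIDIC))
    exclude_disulfide_cys: bool = True

    def __post_init__(self) -> None:
        for group, pka in {**self.basic, **self.acidic}.items():
            if not 0.0 < pka < 14.0:
                raise ValidationError(f"pKa for {group!r} out of range (0, 14): {pka}")


DEFAULT_PKA = PkaTable()


def _check_residues(peptide: str) -> str:
    peptide = peptide.upper()
    bad = set(peptide) - STANDARD_AA
    if bad:
        raise ValidationError(
            f"nonstandard residue(s) {''.join(sorted(bad))!r} in peptide"
        )
    if not peptide:
        raise ValidationError("empty peptide")
    return peptide


def average_mw(peptide: str) -> float:
    """Average (isotope-weighted) molecular weight in Da.

    Sum of average residue masses plus one water; reduced form (no
    disulfide −2H correction).
    """
    peptide = _check_residues(peptide)
    return float(molecular_weight(peptide, seq_type="protein", monoisotopic=False))


def net_charge(
    peptide: str,
    ph: float = 7.0,
    pka: PkaTable = DEFAULT_PKA,
    n_disulfides: int = 0,
    include_termini: bool = True,
) -> float:
    """Net charge of ``peptide`` at ``ph`` by Henderson–Hasselbalch summation.

    Positive term: ``sum 1 / (1 + 10**(pH - pKa))`` over basic groups.
    Negative term: ``sum 1 / (1 + 10**(pKa - pH))`` over acidic groups.

    ``include_termini=False`` drops the free N-/C-terminus contributions,
    appropriate when scoring an internal segment of a precursor (e.g. the
    acidity test for propeptides).
    """
    peptide = _check_residues(peptide)
    if not 0.0 < ph < 14.0:
        raise ValidationError(f"pH out of range (0, 14): {ph}")
    n_cys = peptide.count("C")
    if n_disulfides < 0 or 2 * n_disulfides > n_cys:
        raise ValidationError(
            f"{n_disulfides} disulfides require {2 * n_disulfides} cysteines, "
            f"peptide has {n_cys}"
        )

    counts = {aa: peptide.count(aa) for aa in STANDARD_AA}
    if pka.exclude_disulfide_cys:
        counts["C"] -= 2 * n_disulfides

    charge = 0.0
    for group, val in pka.basic.items():
        n = 1 if group == "n_terminus" else counts.get(group, 0)
        if group == "n_terminus" and not include_termini:
            n = 0
        charge += n / (1.0 + 10.0 ** (ph - val))
    for group, val in pka.acidic.items():
        n = 1 if group == "c_terminus" else counts.get(group, 0)
        if group == "c_terminus" and not include_termini:
            n = 0
        charge -= n / (1.0 + 10.0 ** (val - ph))
    return charge
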