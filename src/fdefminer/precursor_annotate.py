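"""Segmentation of defensin precursors.

A translated precursor is parsed into signal peptide, optional acidic
propeptide(s) ending in a proprotein-convertase site (K, R, KR or RR), and
one or two mature CSαβ domains, with C-terminal Gly-Arg(-Arg) amidation and
terminal-extension flags.

Signal-peptide prediction is a transparent heuristic (hydrophobic core plus
the (−3,−1) small-residue rule), not a reimplementation of any external
predictor; user-supplied cleavage overrides are accepted where it falls
short.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .cysmotif import find_frameworks, spacing_envelope
from .errors import ValidationError
from .physchem import average_mw, net_charge

Interval = tuple[int, int]  # 1-based inclusive, precursor coordinates

_SMALL = set("AGSCTV")  # allowed at the -3 and -1 signal-cleavage positions
_BASIC = set("KR")


@dataclass
class MaturePeptide:
    """A processed mature defensin."""

    name: str
    sequence: str
    cys_positions: list[int]  # 1-based within the mature sequence
    family: str = "unassigned"
    amidated: bool = False
    tag: str = ""  # "", "N" or "C" for two-domain precursors

    def __post_init__(self) -> None:
        if len(self.cys_positions) != 6:
            raise ValidationError(f"{self.name}: needs 6 framework cysteines")

    @property
    def size(self) -> int:
        return len(self.sequence)

    @property
    def mw(self) -> float:
        return average_mw(self.sequence)

    def nc(self, ph: float = 7.0, n_disulfides: int = 0) -> float:
        return net_charge(self.sequence, ph=ph, n_disulfides=n_disulfides)


@dataclass
class DefensinPrecursor:
    """A segmented precursor; intervals tile the full sequence."""

    sequence: str
    signal: Optional[Interval]
    propeptides: list[Interval]
    domains: list[Interval]  # 1-2 entries; include any trailing R/RR encoding
    domain_tags: list[str]
    amidation: list[bool]
    n_extension: Optional[Interval] = None
    c_extension: Optional[Interval] = None
    matures: list[MaturePeptide] = field(default_factory=list)

    @property
    def architecture(self) -> str:
        if len(self.domains) == 2:
            return "two_domain"
        return "pro_mature" if self.propeptides else "no_pro"


def predict_signal(precursor: str, min_cleave: int = 15,
                   max_search: int = 40) -> Optional[Interval]:
    """Heuristic N-terminal signal peptide, or None.

    Requires a hydrophobic core (≥6 consecutive residues, mean
    Kyte–Doolittle ≥ 1.5) within the first ``max_search`` residues, then
    cleaves after the first position ≥ ``min_cleave`` whose −3 and −1
    residues are small (A/G/S/C/T/V).
    """
    precursor = precursor.upper()
    if not precursor.startswith("M"):
        return None
    head = precursor[:max_search]
    core = False
    for i in range(len(head) - 5):
        window = head[i : i + 6]
        if all(c in KYTE_DOOLITTLE for c in window):
            if sum(KYTE_DOOLITTLE[c] for c in window) / 6 >= 1.5:
                core = True
                break
    if not core:
        return None
    for p in range(min_cleave, min(max_search, len(precursor) - 1) + 1):
        if precursor[p - 1] in _SMALL and precursor[p - 3] in _SMALL:
            return (1, p)
    return None


def detect_propeptide(segment: str) -> tuple[bool, Optional[int]]:
    """Acidity + basic-terminus test for a candidate propeptide.

    True iff the segment's chain net charge at pH 7 is negative and it ends
    in K, R, KR or RR; the returned cleavage position is after the basic
    residue(s), i.e. ``len(segment)``.
    """
    segment = segment.upper()
    if not segment or segment[-1] not in _BASIC:
        return False, None
    if net_charge(segment, ph=7.0, include_termini=False) >= 0:
        return False, None
    return True, len(segment)


def _find_cleavage(inter: str) -> Optional[int]:
    """First acidic-propeptide cleavage within ``inter`` (1-based end), if any.

    Scans basic (K/R) runs left to right; a run of length > 2 is cleaved
    after its first two residues (convertase recognizes mono- and dibasic
    sites only).
    """
    i = 0
    while i < len(inter):
        if inter[i] in _BASIC:
            run_end = i
            while run_end + 1 < len(inter) and inter[run_end + 1] in _BASIC:
                run_end += 1
            q = min(i + 2, run_end + 1)  # ≤2 basics in the cleaved run
            ok, _ = detect_propeptide(inter[:q])
            if ok:
                return q
            i = run_end + 1
        else:
            i += 1
    return None


def detect_amidation(domain_with_tail: str) -> tuple[bool, str]:
    """C-terminal Gly-Arg(-Arg) amidation signal.

    If the sequence ends GR or GRR the arginine(s) are trimmed and the
    glycine retained as the amide-donor record.
    """
    s = domain_with_tail
    if s.endswith("GRR"):
        return True, s[:-2]
    if s.endswith("GR"):
        return True, s[:-1]
    return False, s


def split_domains(after_signal: str,
                  envelope: Optional[list[tuple[int, int]]] = None
                  ) -> list[Interval]:
    """Mature-domain intervals (1-based within ``after_signal``).

    Two domains are emitted when two disjoint six-cysteine frameworks are
    separated by a spacer satisfying the propeptide rule; the N domain ends
    at its sixth framework cysteine.
    """
    if envelope is None:
        envelope = _default_envelope()
    fws = find_frameworks(after_signal, envelope)
    if len(fws) > 2:
        raise ValidationError("more than two cysteine frameworks (unsupported)")
    if len(fws) == 2:
        inter = after_signal[fws[0][5] : fws[1][0] - 1]
        cleave = _find_cleavage(inter)
        if cleave is not None:
            dom1_start = _domain_start(after_signal, fws[0])
            # spacer occupies fws[0][5]+1 .. fws[0][5]+cleave
            return [(dom1_start, fws[0][5]),
                    (fws[0][5] + cleave + 1, len(after_signal))]
    if not fws:
        raise ValidationError("no six-cysteine framework in precursor")
    return [(_domain_start(after_signal, fws[0]), len(after_signal))]


def _domain_start(after_signal: str, framework: list[int]) -> int:
    inter = after_signal[: framework[0] - 1]
    cleave = _find_cleavage(inter)
    return 1 if cleave is None else cleave + 1


_DEFAULT_ENVELOPE: Optional[list[tuple[int, int]]] = None


def _default_envelope() -> list[tuple[int, int]]:
    global _DEFAULT_ENVELOPE
    if _DEFAULT_ENVELOPE is None:
        from .io_formats import packaged_seed_path, read_fasta

        seeds = [r.seq for r in read_fasta(packaged_seed_path())]
        _DEFAULT_ENVELOPE = spacing_envelope(seeds)
    return _DEFAULT_ENVELOPE


def annotate_precursor(precursor: str, name: str = "precursor",
                       envelope: Optional[list[tuple[int, int]]] = None,
                       signal_override: Optional[int] = None,
                       keep_amidation_glycine: bool = True
                       ) -> DefensinPrecursor:
    """Full segmentation of a translated precursor.

    ``signal_override`` forces the signal cleavage position (1-based end of
    the signal) when the heuristic is to be bypassed.
    """
    precursor = precursor.upper()
    if envelope is None:
        envelope = _default_envelope()
    if signal_override is not None:
        signal: Optional[Interval] = (1, signal_override)
    else:
        signal = predict_signal(precursor)
    sig_end = signal[1] if signal else 0
    after = precursor[sig_end:]

    domains_local = split_domains(after, envelope)
    propeptides: list[Interval] = []
    # propeptide before the first domain
    d1s = domains_local[0][0]
    if d1s > 1:
        propeptides.append((sig_end + 1, sig_end + d1s - 1))
    if len(domains_local) == 2:
        spacer = (sig_end + domains_local[0][1] + 1,
                  sig_end + domains_local[1][0] - 1)
        propeptides.append(spacer)

    domains = [(sig_end + s, sig_end + e) for s, e in domains_local]
    tags = ["N", "C"] if len(domains) == 2 else [""]

    matures: list[MaturePeptide] = []
    amid_flags: list[bool] = []
    for k, ((s, e), tag) in enumerate(zip(domains, tags)):
        seq = precursor[s - 1 : e]
        amidated = False
        if e == len(precursor):  # only a C-terminal domain can be amidated
            amidated, trimmed = detect_amidation(seq)
            if amidated:
                seq = trimmed if keep_amidation_glycine else trimmed[:-1]
        cys = [i + 1 for i, c in enumerate(seq) if c == "C"]
        if len(cys) != 6:
            raise ValidationError(
                f"{name}: domain {k + 1} has {len(cys)} cysteines, expected 6"
            )
        amid_flags.append(amidated)
        suffix = tag if tag else ""
        matures.append(
            MaturePeptide(name=name + suffix, sequence=seq, cys_positions=cys,
                          amidated=amidated, tag=tag)
        )

    prec = DefensinPrecursor(
        sequence=precursor, signal=signal, propeptides=propeptides,
        domains=domains, domain_tags=tags, amidation=amid_flags,
        matures=matures,
    )
    _flag_extensions(prec)
    return prec


def _flag_extensions(prec: DefensinPrecursor) -> None:
    """N-terminal (≥15 aa before C1, non-propeptide) and C-terminal
    (≥8 aa after C6, ≥40% R/P/G) extension flags."""
    if not prec.matures:
        return
    first = prec.matures[0]
    d1s = prec.domains[0][0]
    pre_c1 = first.cys_positions[0] - 1  # residues before C1 inside domain 1
    if pre_c1 >= 15:
        prec.n_extension = (d1s, d1s + pre_c1 - 1)
    last = prec.matures[-1]
    tail = last.sequence[last.cys_positions[5] :]
    if len(tail) >= 8:
        rpg = sum(1 for c in tail if c in "RPG") / len(tail)
        if rpg >= 0.40:
            ds, de = prec.domains[-1]
            c6_abs = ds + last.cys_positions[5] - 1
            prec.c_extension = (c6_abs + 1, de)
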