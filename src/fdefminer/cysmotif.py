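"""The six-cysteine CSαβ spacing envelope and framework matching.

The framework is the ordered set of six cysteines forming the three
disulfides of the cysteine-stabilized α-helix/β-sheet fold; the envelope is
the per-gap (C1..C6) range of inter-cysteine spacings spanned by a seed
set, widened by a configurable slack.
"""

from __future__ import annotations

import re

from .errors import ValidationError


def spacing_envelope(seeds: list[str], slack: int = 2) -> list[tuple[int, int]]:
    """Inter-cysteine gap ranges (C1..C6) spanned by the seed set, ± slack."""
    gaps_per_seed = []
    for s in seeds:
        pos = [i for i, c in enumerate(s) if c == "C"]
        if len(pos) != 6:
            raise ValidationError("seed peptide without a six-cysteine framework")
        gaps_per_seed.append([b - a - 1 for a, b in zip(pos, pos[1:])])
    return [
        (max(1, min(g[i] for g in gaps_per_seed) - slack),
         max(g[i] for g in gaps_per_seed) + slack)
        for i in range(5)
    ]


def envelope_regex(envelope: list[tuple[int, int]], n_cys: int = 6) -> re.Pattern:
    parts = ["C"]
    for lo, hi in envelope[: n_cys - 1]:
        parts.append("[^C]{%d,%d}C" % (lo, hi))
    return re.compile("".join(parts))


def matches_envelope(peptide: str, envelope: list[tuple[int, int]]) -> bool:
    return envelope_regex(envelope).search(peptide) is not None


def find_frameworks(peptide: str,
                    envelope: list[tuple[int, int]]) -> list[list[int]]:
    """Disjoint six-cysteine frameworks (1-based positions), left to right."""
    cys = [i + 1 for i, c in enumerate(peptide) if c == "C"]
    frameworks = []
    i = 0
    while i + 6 <= len(cys):
        window = cys[i : i + 6]
        gaps = [b - a - 1 for a, b in zip(window, window[1:])]
        if all(lo <= g <= hi for g, (lo, hi) in zip(gaps, envelope)):
            frameworks.append(window)
            i += 6
        else:
            i += 1
    return frameworks
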