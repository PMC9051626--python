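"""The 23-letter amino-acid alphabet used throughout the package.

HLA-II ligands are represented over the 20 canonical amino acids plus the
three phosphorylated residues pS, pT and pY.  In modified-sequence strings
("mod strings") the phospho residues are written as the lowercase letters
``s``, ``t`` and ``y``; all unmodified residues are uppercase.  The sentinel
``-`` marks positions outside the source protein when a peptide's context is
extended past a terminus; it is not part of the alphabet and matches no
motif position.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino acids, alphabetical; indices 0..19.
AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Phospho residues pS, pT, pY as lowercase letters; indices 20..22.
PHOSPHO = "sty"

#: Full ordered alphabet; the bijection symbol <-> index is fixed.
ALPHABET23 = AA20 + PHOSPHO

#: Out-of-protein sentinel used in context extension.
SENTINEL = "-"

#: Residues that can carry a phosphate group.
PHOSPHORYLATABLE = "STY"

INDEX = {a: i for i, a in enumerate(ALPHABET23)}

#: Unmodified parent residue of each phospho symbol.
PARENT = {"s": "S", "t": "T", "y": "Y"}

#: Field-style display names (pS/pT/pY) for the lowercase symbols.
DISPLAY = {"s": "pS", "t": "pT", "y": "pY"}


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the 23-letter alphabet."""


def encode(seq: str) -> np.ndarray:
    """Map a mod string to an integer index array over the 23-letter alphabet.

    Raises :class:`AlphabetError` naming the offending symbol.
    """
    try:
        return np.array([INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise AlphabetError(f"symbol {exc.args[0]!r} is not in the 23-letter alphabet") from None


def decode(indices) -> str:
    return "".join(ALPHABET23[i] for i in indices)


def to_mod_string(sequence: str, phospho_positions) -> str:
    """Lowercase the phosphorylated positions of an uppercase sequence."""
    chars = list(sequence)
    for i in phospho_positions:
        chars[i] = chars[i].lower()
    return "".join(chars)


def parse_mod_string(mod: str) -> tuple[str, frozenset[int]]:
    """Split a mod string into its uppercase sequence and phospho positions."""
    positions = frozenset(i for i, c in enumerate(mod) if c in PARENT)
    return mod.upper(), positions


def bracket_annotation(mod: str) -> str:
    """Render a mod string with ``[p]`` markers, e.g. ``ASKDPS[p]SR``.

    The marker follows the phosphorylated residue.
    """
    out = []
    for c in mod:
        if c in PARENT:
            out.append(PARENT[c] + "[p]")
        else:
            out.append(c)
    return "".join(out)


def parse_bracket_annotation(text: str) -> str:
    """Inverse of :func:`bracket_annotation`; returns a mod string."""
    chars: list[str] = []
    i = 0
    while i < len(text):
        if text.startswith("[p]", i):
            if not chars or chars[-1] not in PHOSPHORYLATABLE:
                raise ValueError(f"[p] marker at column {i} does not follow S, T or Y")
            chars[-1] = chars[-1].lower()
            i += 3
        else:
            chars.append(text[i])
            i += 1
    return "".join(chars)
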