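"""Minimal HGVS protein-change parsing.

Only simple substitutions of the form ``p.E273K`` / ``p.Glu273Lys`` (with or
without the ``p.`` prefix, optionally parenthesised) are understood; that is
the notation used for hotspot matching. Anything else parses to ``None``.
"""
from __future__ import annotations

import re

THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*", "Sec": "U",
}

_SUB_RE = re.compile(
    r"^(?:p\.)?\(?"
    r"([A-Z][a-z]{2}|[A-Z*])"
    r"(\d+)"
    r"([A-Z][a-z]{2}|[A-Z*])"
    r"\)?$"
)

_ONE_LETTER = set("ACDEFGHIKLMNPQRSTVWY*U")


def _to_one(code: str) -> str | None:
    if len(code) == 1:
        return code if code in _ONE_LETTER else None
    return THREE_TO_ONE.get(code)


def parse_protein_change(text: str) -> tuple[str, int, str] | None:
    """Parse a protein substitution into ``(ref_aa, position, alt_aa)``.

    Three-letter codes are normalized to one-letter. Returns ``None`` for
    empty strings, indel/frameshift notation, or anything unrecognised.
    """
    if not text:
        return None
    m = _SUB_RE.match(text.strip())
    if m is None:
        return None
    ref = _to_one(m.group(1))
    alt = _to_one(m.group(3))
    if ref is None or alt is None:
        return None
    return ref, int(m.group(2)), alt


def normalize_protein_change(text: str) -> str:
    """Canonical one-letter ``p.RefPosAlt`` form, or the stripped input if
    the string is not a simple substitution."""
    parsed = parse_protein_change(text)
    if parsed is None:
        return text.strip()
    ref, pos, alt = parsed
    return f"p.{ref}{pos}{alt}"
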