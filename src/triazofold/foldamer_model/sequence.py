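"""Parser for peptidotriazolamer sequence notation.

A sequence string names an N-cap, a chain of residues joined either by
amide bonds (``-``) or by 1,4-disubstituted 1,2,3-triazole linkages
(``Ψ[4Tz]``, ASCII aliases ``psi[4Tz]`` and ``~[4Tz]``), and a C-cap,
e.g. ``Boc-Ala-ValΨ[4Tz]Phe-LeuΨ[4Tz]Phe-LeuΨ[4Tz]Val-OAll``.
Parenthesised repeats such as ``(AlaΨ[4Tz]Ala)6`` are expanded, the
copies being joined by amide bonds.  A ``d-``/``D-`` prefix marks a
D-configured residue.

The residue on the amino-terminal side of a triazole link contributes its
Cα to ring carbon C4 (kind ``tz4n``); the residue on the carboxy-terminal
side bonds its Cα to ring nitrogen N1 (kind ``tz4c``).  Position indices
count every triazole ring as a position of its own, so the heptamer above
is numbered Ala1, V4n2, (ring 3), F4c4, ... V4c10.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "ResidueSpec",
    "SequenceParseError",
    "SequenceStructureError",
    "parse_residues",
    "N_CAPS",
    "C_CAPS",
]

TZ_MARK = "\x01"  # internal marker for a triazole linkage
D_MARK = "\x02"  # internal marker for a d- chirality prefix

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
THREE_LETTER = set(_ONE_TO_THREE.values())

# N-caps: acyl-type caps provide a carbonyl carbon bonded to residue 1's N.
# The tert-butylsulfinyl cap and its (S)/(R) variants are treated as the
# same generic acyl cap for geometry purposes.
N_CAPS = {
    "Boc": "Boc",
    "Bus": "Bus",
    "(S)-Bus": "Bus",
    "(R)-Bus": "Bus",
    "H": "H",
}
C_CAPS = {"OAll": "OAll", "OBzl": "OBzl", "OH": "OH"}


class SequenceParseError(ValueError):
    """Unknown or malformed token; the message names the offending span."""


class SequenceStructureError(ValueError):
    """Structurally invalid chain, e.g. a dangling triazole link."""


@dataclass(frozen=True)
class ResidueSpec:
    """One amino-acid-derived position of the foldamer chain."""

    name: str  # 3-letter code, e.g. "Ala"
    kind: str  # "amide" | "tz4n" | "tz4c"
    chirality: str  # "L" | "D" | "achiral"
    side_chain: str  # residue name, or "none" for Gly
    position_index: int

    def __post_init__(self):
        if self.kind not in ("amide", "tz4n", "tz4c"):
            raise ValueError(f"unknown residue kind {self.kind!r}")
        if self.chirality not in ("L", "D", "achiral"):
            raise ValueError(f"unknown chirality {self.chirality!r}")
        if (self.chirality == "achiral") != (self.side_chain == "none"):
            raise ValueError("achiral iff side_chain is none (Gly)")

    @property
    def label(self) -> str:
        """Positional label in the style of V4n2 / F4c4 / Ala1."""
        one = {v: k for k, v in _ONE_TO_THREE.items()}.get(self.name, self.name[0])
        if self.kind == "tz4n":
            return f"{one}4n{self.position_index}"
        if self.kind == "tz4c":
            return f"{one}4c{self.position_index}"
        return f"{self.name}{self.position_index}"


def _normalize(text: str) -> str:
    body = text.strip()
    body = body.replace("Ψ[4Tz]", TZ_MARK)  # Ψ
    body = body.replace("ψ[4Tz]", TZ_MARK)  # ψ
    body = re.sub(r"psi\[4Tz\]", TZ_MARK, body, flags=re.IGNORECASE)
    body = body.replace("~[4Tz]", TZ_MARK)
    return body


def _expand_repeats(body: str) -> str:
    def repl(m: re.Match) -> str:
        frag, count = m.group(1), int(m.group(2))
        if count < 1:
            raise SequenceParseError(
                f"repeat count must be >= 1, got {count} in {m.group(0)!r}"
            )
        return "-".join([frag] * count)

    # subscript-style counts like (…)_6_ are also accepted
    body = re.sub(r"\)_(\d+)_", r")\1", body)
    prev = None
    while prev != body:
        prev = body
        body = re.sub(r"\(([^()]+)\)(\d+)", repl, body)
    return body


def _strip_caps(body: str) -> tuple[str, str, str]:
    n_cap = "none"
    c_cap = "none"
    for tok in sorted(N_CAPS, key=len, reverse=True):
        if body.startswith(tok + "-"):
            n_cap = N_CAPS[tok]
            body = body[len(tok) + 1:]
            break
    for tok in sorted(C_CAPS, key=len, reverse=True):
        if body.endswith("-" + tok):
            c_cap = C_CAPS[tok]
            body = body[: -(len(tok) + 1)]
            break
    return body, n_cap, c_cap


def parse_residues(text: str) -> tuple[list[ResidueSpec], int, str, str]:
    """Parse a sequence string.

    Returns ``(residues, n_triazoles, n_cap, c_cap)``.  See the module
    docstring for the grammar.
    """
    if not isinstance(text, str) or not text.strip():
        raise SequenceParseError("empty sequence string")
    body = _normalize(text)
    body = _expand_repeats(body)
    body, n_cap, c_cap = _strip_caps(body)
    if not body:
        raise SequenceParseError(f"no residues found in {text!r}")
    # mark d-/D- chirality prefixes so they survive the '-' split
    body = re.sub(r"(?:^|(?<=[-\x01]))[dD]-(?=[A-Z])", D_MARK, body)
    # a dash directly before/after a triazole token is decorative
    body = re.sub(rf"-?{TZ_MARK}-?", TZ_MARK, body)
    if body.startswith(TZ_MARK) or body.endswith(TZ_MARK):
        raise SequenceStructureError(
            f"dangling Ψ[4Tz] link at a terminus in {text!r}"
        )

    tokens: list[str] = []  # residue names interleaved with separators
    seps: list[str] = []
    chunks = body.split("-")
    res_tokens: list[str] = []
    links_after: list[bool] = []  # link (True) or amide (False) after residue i
    for ci, chunk in enumerate(chunks):
        if not chunk:
            raise SequenceParseError(f"empty token (stray '-') in {text!r}")
        parts = chunk.split(TZ_MARK)
        if any(p == "" for p in parts):
            raise SequenceStructureError(
                f"dangling Ψ[4Tz] link in segment {chunk!r}"
            )
        for pi, part in enumerate(parts):
            res_tokens.append(part)
            is_last_in_chunk = pi == len(parts) - 1
            if not is_last_in_chunk:
                links_after.append(True)
            elif ci != len(chunks) - 1:
                links_after.append(False)
    assert len(links_after) == len(res_tokens) - 1

    residues: list[ResidueSpec] = []
    pos = 1
    for i, tok in enumerate(res_tokens):
        d_prefix = tok.startswith(D_MARK)
        name_tok = tok[1:] if d_prefix else tok
        if name_tok in THREE_LETTER:
            name = name_tok
        elif name_tok in _ONE_TO_THREE:
            name = _ONE_TO_THREE[name_tok]
        else:
            raise SequenceParseError(
                f"unknown residue token {name_tok!r} in {text!r}"
            )
        before = links_after[i - 1] if i > 0 else False
        after = links_after[i] if i < len(links_after) else False
        if before and after:
            raise SequenceStructureError(
                f"residue {name_tok!r} flanked by two Ψ[4Tz] links"
            )
        kind = "tz4n" if after else ("tz4c" if before else "amide")
        if name == "Gly":
            chirality, side = "achiral", "none"
        else:
            chirality, side = ("D" if d_prefix else "L"), name
        residues.append(ResidueSpec(name, kind, chirality, side, pos))
        pos += 2 if after else 1  # a following ring occupies one position

    n_triazoles = sum(links_after)
    return residues, n_triazoles, n_cap, c_cap
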