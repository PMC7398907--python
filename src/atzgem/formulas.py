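"""Elemental formula parsing and molecular-weight arithmetic.

Formulas follow the usual Hill-style grammar (``C8H14ClN5``), with
parenthesised groups (``Ca(OH)2``) and the wildcard tokens ``R``, ``X`` and
``*`` that genome-scale reconstructions use for generic acyl chains and
unspecified groups.  Wildcards parse to ordinary counts so that audits can
recognise and skip the reactions that carry them.
"""

from __future__ import annotations

import re

__all__ = [
    "FormulaError",
    "WILDCARD_TOKENS",
    "parse_formula",
    "has_wildcard",
    "molecular_weight",
    "carbon_nitrogen_counts",
]

#: Tokens that stand for unspecified substructures (generic R-groups etc.).
WILDCARD_TOKENS = frozenset({"R", "X", "*"})

#: Synthetic elements used by generated fixture models; they balance like
#: real elements but have no defined mass.
SYNTHETIC_ELEMENTS = frozenset({"E"})

# IUPAC 2021 standard atomic weights, abridged to the elements that occur in
# small-molecule metabolism and mineral media.
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Na": 22.990, "K": 39.098, "Mg": 24.305,
    "Ca": 40.078, "Mn": 54.938, "Fe": 55.845, "Cu": 63.546, "Zn": 65.38,
    "Co": 58.933, "Mo": 95.95, "Ni": 58.693, "Se": 78.971, "B": 10.81,
    "F": 18.998, "Br": 79.904, "I": 126.904, "Si": 28.085, "W": 183.84,
}

_TOKEN = re.compile(r"([A-Z][a-z]?|\(|\)|\*|\d+)")


class FormulaError(ValueError):
    """Raised when a formula string does not match the element-count grammar."""

    def __init__(self, formula: str, position: int, message: str):
        self.formula = formula
        self.position = position
        super().__init__(f"cannot parse formula {formula!r} at position {position}: {message}")


def _tokenize(formula: str) -> list[tuple[int, str]]:
    tokens: list[tuple[int, str]] = []
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(formula, pos, f"unexpected character {formula[pos]!r}")
        tokens.append((match.start(), match.group(0)))
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(formula, pos, f"unexpected character {formula[pos]!r}")
    return tokens


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``formula`` into a map element -> atom count.

    Wildcard tokens (``R``, ``X``, ``*``) appear in the result under their own
    key; use :func:`has_wildcard` to detect them.  The empty string parses to
    an empty map (unknown composition).

    Raises
    ------
    FormulaError
        If the string contains a token outside the grammar; the error carries
        the offending position.
    """
    tokens = _tokenize(formula)

    def parse_group(i: int, depth: int) -> tuple[dict[str, int], int]:
        counts: dict[str, int] = {}
        while i < len(tokens):
            pos, tok = tokens[i]
            if tok == "(":
                inner, i = parse_group(i + 1, depth + 1)
                mult, i = _read_count(i)
                for el, n in inner.items():
                    counts[el] = counts.get(el, 0) + n * mult
            elif tok == ")":
                if depth == 0:
                    raise FormulaError(formula, pos, "unbalanced ')'")
                return counts, i + 1
            elif tok.isdigit():
                raise FormulaError(formula, pos, "count without a preceding element")
            else:
                el = tok
                if el not in ATOMIC_MASS and el not in WILDCARD_TOKENS \
                        and el not in SYNTHETIC_ELEMENTS:
                    raise FormulaError(formula, pos, f"unknown element {el!r}")
                i += 1
                mult, i = _read_count(i)
                counts[el] = counts.get(el, 0) + mult
        if depth != 0:
            raise FormulaError(formula, len(formula), "unbalanced '('")
        return counts, i

    def _read_count(i: int) -> tuple[int, int]:
        if i < len(tokens) and tokens[i][1].isdigit():
            return int(tokens[i][1]), i + 1
        return 1, i

    counts, _ = parse_group(0, 0)
    return counts


def has_wildcard(formula: str) -> bool:
    """True if ``formula`` is empty or contains a generic-group wildcard."""
    if formula == "":
        return True
    try:
        counts = parse_formula(formula)
    except FormulaError:
        return False
    return any(tok in counts for tok in WILDCARD_TOKENS)


def molecular_weight(formula: str) -> float:
    """Molecular weight in g/mol computed from standard atomic weights.

    Raises :class:`FormulaError` for wildcard or empty formulas, whose mass is
    undefined.
    """
    counts = parse_formula(formula)
    if not counts or any(tok not in ATOMIC_MASS for tok in counts):
        raise FormulaError(
            formula, 0,
            "molecular weight undefined for wildcard/empty/synthetic formula")
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


def carbon_nitrogen_counts(formula: str) -> tuple[int, int]:
    """Carbon and nitrogen atom counts of ``formula`` (the C:N ratio terms)."""
    counts = parse_formula(formula)
    return counts.get("C", 0), counts.get("N", 0)
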