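"""Gene-protein-reaction (GPR) boolean rules.

Grammar: parenthesized infix ``and`` / ``or`` (case-insensitive) over bare
gene-id tokens, e.g. ``(g1 and g2) or g3``.  ``and`` binds tighter than
``or``, matching SBML-FBC practice.
"""

from __future__ import annotations

import re

_TOKEN = re.compile(r"\(|\)|[^\s()]+")

# tree nodes: ("gene", id) | ("and", [children]) | ("or", [children])
GprTree = tuple


def parse_gpr(rule: str) -> GprTree:
    """Parse a GPR rule string into an expression tree.

    Raises ValueError on malformed input (unbalanced parentheses, dangling
    operators, empty rule).
    """
    tokens = _TOKEN.findall(rule)
    if not tokens:
        raise ValueError("empty rule")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        nonlocal pos
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise ValueError("unexpected end of rule")
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise ValueError("unbalanced parentheses")
            pos += 1
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected token {tok!r}")
        pos += 1
        return ("gene", tok)

    tree = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens at {tokens[pos]!r}")
    return tree


def gpr_genes(tree: GprTree) -> set[str]:
    kind = tree[0]
    if kind == "gene":
        return {tree[1]}
    out: set[str] = set()
    for child in tree[1]:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(
    tree: GprTree,
    values: dict[str, float],
    missing: float = 0.0,
    or_op=sum,
    and_op=min,
) -> float:
    """Fold a GPR tree over per-gene values.

    Defaults implement the E-flux aggregation: isozymes (``or``) add their
    expression, enzyme complexes (``and``) are limited by their scarcest
    subunit.  Unmeasured genes contribute ``missing``.
    """
    kind = tree[0]
    if kind == "gene":
        return values.get(tree[1], missing)
    vals = [evaluate_gpr(c, values, missing, or_op, and_op) for c in tree[1]]
    return or_op(vals) if kind == "or" else and_op(vals)


def format_gpr(tree: GprTree) -> str:
    kind = tree[0]
    if kind == "gene":
        return tree[1]
    sep = f" {kind} "
    parts = []
    for child in tree[1]:
        s = format_gpr(child)
        if child[0] in ("and", "or") and child[0] != kind:
            s = f"({s})"
        parts.append(s)
    return sep.join(parts)
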