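"""Gene-protein-reaction (GPR) rules: expression -> enzyme activity -> bounds.

A GPR rule is a boolean expression over gene identifiers with AND / OR.
Activities are evaluated numerically the way constraint-based toolboxes map
expression onto reactions: AND takes the *max* of its children (the
isozyme-complex reading used here), OR takes the *sum* (parallel isozymes
add capacity).  Per-condition sample variances of the mapped activities are
then used as upper bounds on the off-diagonal fluctuation-matrix entries of
the interactions whose superpathways traverse those reactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import InteractionNetwork

__all__ = [
    "GPRRule",
    "GPRParseError",
    "map_expression_to_reaction",
    "activity_variances",
    "bounds_from_variances",
]


class GPRParseError(ValueError):
    """Malformed GPR rule; carries the token position of the failure."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    """(kind, value, char_position) tokens: AND, OR, LPAREN, RPAREN, IDENT."""
    tokens = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            tokens.append(("LPAREN", ch, i))
            i += 1
            continue
        if ch == ")":
            tokens.append(("RPAREN", ch, i))
            i += 1
            continue
        j = i
        while j < len(text) and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low == "and":
            tokens.append(("AND", word, i))
        elif low == "or":
            tokens.append(("OR", word, i))
        else:
            tokens.append(("IDENT", word, i))
        i = j
    return tokens


@dataclass
class _Node:
    op: str                      # "gene", "and", "or"
    gene: str | None = None
    children: tuple = ()

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        return set().union(*(c.genes() for c in self.children))

    def evaluate(self, expression: Mapping[str, float]) -> float:
        if self.op == "gene":
            return float(expression[self.gene])
        vals = [c.evaluate(expression) for c in self.children]
        return max(vals) if self.op == "and" else sum(vals)


class _Parser:
    # grammar: expr := term (OR term)* ; term := factor (AND factor)* ;
    # factor := IDENT | '(' expr ')'
    def __init__(self, tokens, text_len):
        self.tokens = tokens
        self.pos = 0
        self.text_len = text_len

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _char_pos(self):
        t = self._peek()
        return t[2] if t else self.text_len

    def parse(self) -> _Node:
        node = self._expr()
        if self._peek() is not None:
            raise GPRParseError(
                f"unexpected token {self._peek()[1]!r}", self._char_pos()
            )
        return node

    def _expr(self) -> _Node:
        terms = [self._term()]
        while self._peek() and self._peek()[0] == "OR":
            self.pos += 1
            terms.append(self._term())
        return terms[0] if len(terms) == 1 else _Node("or", children=tuple(terms))

    def _term(self) -> _Node:
        factors = [self._factor()]
        while self._peek() and self._peek()[0] == "AND":
            self.pos += 1
            factors.append(self._factor())
        return factors[0] if len(factors) == 1 else _Node("and", children=tuple(factors))

    def _factor(self) -> _Node:
        tok = self._peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule", self._char_pos())
        kind, value, pos = tok
        if kind == "IDENT":
            self.pos += 1
            return _Node("gene", gene=value)
        if kind == "LPAREN":
            self.pos += 1
            node = self._expr()
            closing = self._peek()
            if closing is None or closing[0] != "RPAREN":
                raise GPRParseError("missing closing parenthesis", self._char_pos())
            self.pos += 1
            return node
        raise GPRParseError(f"unexpected token {value!r}", pos)


@dataclass
class GPRRule:
    """Parsed GPR rule for one reaction."""

    reaction_id: str
    text: str
    root: _Node

    @classmethod
    def parse(cls, reaction_id: str, text: str) -> "GPRRule":
        tokens = _tokenize(text)
        if not tokens:
            raise GPRParseError("empty rule", 0)
        return cls(reaction_id, text, _Parser(tokens, len(text)).parse())

    def genes(self) -> set[str]:
        return self.root.genes()

    def evaluate(self, expression: Mapping[str, float]) -> float:
        missing = sorted(self.genes() - set(expression))
        if missing:
            raise KeyError(
                f"rule for {self.reaction_id!r} references genes absent from "
                f"the expression data: {missing}"
            )
        return self.root.evaluate(expression)


def map_expression_to_reaction(
    rule: GPRRule | str, expression: Mapping[str, float]
) -> float:
    """Activity of one reaction: AND -> max of children, OR -> sum."""
    if isinstance(rule, str):
        rule = GPRRule.parse("<anonymous>", rule)
    return rule.evaluate(expression)


def activity_variances(
    rules: Sequence[GPRRule | tuple[str, str]],
    expression_table: pd.DataFrame,
    condition_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Per-reaction, per-condition unbiased variance of mapped activities.

    ``expression_table`` is genes x samples; ``condition_labels`` maps each
    sample (column) to its condition.  Uses the n-1 denominator; every
    condition needs at least two samples.
    """
    parsed = [
        r if isinstance(r, GPRRule) else GPRRule.parse(r[0], r[1]) for r in rules
    ]
    conditions = sorted(set(condition_labels.values()))
    groups = {
        c: [s for s in expression_table.columns if condition_labels.get(s) == c]
        for c in conditions
    }
    for c, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(
                f"condition {c!r} has {len(cols)} samples; need >= 2 for a variance"
            )
    out = {}
    for rule in parsed:
        row = {}
        for c, cols in groups.items():
            acts = [
                rule.evaluate(expression_table[s].to_dict()) for s in cols
            ]
            row[c] = float(np.var(acts, ddof=1))
        out[rule.reaction_id] = row
    table = pd.DataFrame(out).T[conditions]
    table.index.name = "reaction_id"
    return table


def bounds_from_variances(
    interactions: InteractionNetwork,
    table: pd.DataFrame,
    default: float = 0.0,
) -> dict[str, np.ndarray]:
    """Fluctuation upper-bound matrices from enzyme-activity variances.

    For each condition (column of ``table``) and each interaction, the
    bound is the *maximum* variance over the reactions of its superpathway
    (the bound must admit the largest constituent fluctuation).  Reactions
    without a variance entry fall back to ``default`` with a warning.
    Returns condition -> symmetric n x n matrix aligned with the
    interaction network's species order.
    """
    n = interactions.n
    idx = {s: i for i, s in enumerate(interactions.species)}
    out = {}
    for cond in table.columns:
        B = np.zeros((n, n))
        for sp in interactions.superpathways:
            vals = []
            for rid in sp.reactions:
                if rid in table.index:
                    vals.append(float(table.loc[rid, cond]))
                else:
                    warnings.warn(
                        f"no activity variance for reaction {rid!r} "
                        f"(interaction {sp.source}->{sp.target}); using "
                        f"default {default}",
                        stacklevel=2,
                    )
                    vals.append(default)
            if not vals:
                warnings.warn(
                    f"interaction {sp.source}->{sp.target} has no mapped "
                    f"reactions; bound defaults to {default}",
                    stacklevel=2,
                )
                vals = [default]
            i, j = idx[sp.source], idx[sp.target]
            bound = max(vals)
            B[i, j] = max(B[i, j], bound)
            B[j, i] = B[i, j]
        out[str(cond)] = B
    return out
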