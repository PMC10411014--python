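"""Downstream comparative summaries and KEGG module evaluation.

Covers set similarity between core genomes, COG functional-category
distributions, the rank correlation between an orthogroup's min_g threshold
and its prevalence in modern core genomes, three-way genome overlap
breakdowns, orthogroup-to-KO mapping, and a parser/evaluator for KEGG
module definition strings treated as boolean expressions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ancestral import AncestralProfile

__all__ = [
    "jaccard",
    "category_distribution",
    "CorrelationResult",
    "threshold_prevalence_correlation",
    "OverlapBreakdown",
    "overlap_breakdown",
    "ModuleParseError",
    "ModuleDefinition",
    "ModuleEvaluation",
    "parse_module",
    "evaluate_module",
    "map_og_to_ko",
]


# ---------------------------------------------------------------------------
# set summaries


def jaccard(a, b) -> float:
    """|a & b| / |a | b|; two empty sets give 0 with a warning."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        warnings.warn("jaccard of two empty sets is defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def category_distribution(core, annotations: dict[str, str]) -> dict[str, float]:
    """Fraction of core genes per COG category letter.

    Multi-letter annotations are split fractionally (1/L per letter);
    unannotated genes map to "S" (function unknown).
    """
    core = sorted(set(core))
    if not core:
        return {}
    out: dict[str, float] = {}
    w = 1.0 / len(core)
    for gene in core:
        letters = annotations.get(gene) or "S"
        for letter in letters:
            out[letter] = out.get(letter, 0.0) + w / len(letters)
    return out


@dataclass
class CorrelationResult:
    rho: float
    n: int
    ok: bool
    message: str = ""


def threshold_prevalence_correlation(profiles: list[AncestralProfile]) -> CorrelationResult:
    """Spearman rank correlation between min_g and modern prevalence.

    Orthogroups never reconstructed at the root are excluded; mid-ranks for
    ties.  Fewer than 3 usable points, or zero variance in either variable,
    yields a flagged (undefined) result.
    """
    pts = [(p.min_g, p.modern_prevalence) for p in profiles if p.min_g is not None]
    if len(pts) < 3:
        return CorrelationResult(np.nan, len(pts), False, "fewer than 3 orthogroups with finite min_g")
    x = np.array([t[0] for t in pts])
    y = np.array([t[1] for t in pts])
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(np.nan, len(pts), False, "zero variance")
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(rho, len(pts), True)


@dataclass
class OverlapBreakdown:
    """Partition of an external genome's OGs against ancestral/modern cores."""

    in_lbca: set = field(default_factory=set)
    in_modern_only: set = field(default_factory=set)
    in_none: set = field(default_factory=set)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.in_lbca), len(self.in_modern_only), len(self.in_none))


def overlap_breakdown(
    lbca_core, modern_cores: dict[str, set], external_genome
) -> OverlapBreakdown:
    """Partition external OGs into (in ancestral core), (only in some modern
    core), (in no core genome).  Exhaustive and disjoint by construction."""
    lbca = set(lbca_core)
    modern_union: set = set()
    for s in modern_cores.values():
        modern_union |= set(s)
    out = OverlapBreakdown()
    for og in set(external_genome):
        if og in lbca:
            out.in_lbca.add(og)
        elif og in modern_union:
            out.in_modern_only.add(og)
        else:
            out.in_none.add(og)
    assert sum(out.counts) == len(set(external_genome))
    return out


# ---------------------------------------------------------------------------
# KEGG module definitions as boolean expressions
#
# Grammar (precedence high -> low): parentheses, '-' (optional component),
# '+' (AND / complex), ',' (OR), space (top-level step separator; inside
# parentheses a space acts as AND, following KEGG's informal convention).

_KO_RE = re.compile(r"K\d{5}")


class ModuleParseError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class _Ko:
    ko: str

    def evaluate(self, present) -> bool:
        return self.ko in present

    def render(self) -> str:
        return self.ko

    def kos(self) -> set:
        return {self.ko}


@dataclass
class _Or:
    terms: list

    def evaluate(self, present) -> bool:
        return any(t.evaluate(present) for t in self.terms)

    def render(self) -> str:
        return ",".join(t.render() for t in self.terms)

    def kos(self) -> set:
        return set().union(*(t.kos() for t in self.terms))


@dataclass
class _And:
    terms: list

    def evaluate(self, present) -> bool:
        return all(t.evaluate(present) for t in self.terms)

    def render(self) -> str:
        def wrap(t):
            return f"({t.render()})" if isinstance(t, _Or) else t.render()

        return "+".join(wrap(t) for t in self.terms)

    def kos(self) -> set:
        return set().union(*(t.kos() for t in self.terms))


@dataclass
class _Optional:
    """A required core with optional components that never affect activity."""

    core: object
    optionals: list

    def evaluate(self, present) -> bool:
        return self.core.evaluate(present)

    def render(self) -> str:
        parts = [self.core.render()] + [o.render() for o in self.optionals]
        return "-".join(parts)

    def kos(self) -> set:
        return self.core.kos()


class _Parser:
    """Recursive-descent parser over a tokenized definition string."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def _peek(self) -> str | None:
        return self.text[self.pos] if self.pos < len(self.text) else None

    def _error(self, msg: str):
        raise ModuleParseError(msg, self.pos)

    def parse_steps(self) -> list:
        steps = [self.parse_or(top_level=True)]
        while self._peek() == " ":
            while self._peek() == " ":
                self.pos += 1
            if self._peek() is None:
                break
            steps.append(self.parse_or(top_level=True))
        if self._peek() is not None:
            self._error(f"unexpected character {self._peek()!r}")
        return steps

    def parse_or(self, top_level: bool):
        terms = [self.parse_space_and(top_level)]
        while self._peek() == ",":
            self.pos += 1
            terms.append(self.parse_space_and(top_level))
        return terms[0] if len(terms) == 1 else _Or(terms)

    def parse_space_and(self, top_level: bool):
        # inside parentheses a space joins subexpressions as AND
        terms = [self.parse_and()]
        if not top_level:
            while self._peek() == " ":
                save = self.pos
                while self._peek() == " ":
                    self.pos += 1
                if self._peek() in (None, ")", ","):
                    self.pos = save
                    break
                terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else _And(terms)

    def parse_and(self):
        terms = [self.parse_optional()]
        while self._peek() == "+":
            self.pos += 1
            terms.append(self.parse_optional())
        return terms[0] if len(terms) == 1 else _And(terms)

    def parse_optional(self):
        core = self.parse_primary()
        optionals = []
        while self._peek() == "-":
            self.pos += 1
            optionals.append(self.parse_primary())
        return _Optional(core, optionals) if optionals else core

    def parse_primary(self):
        ch = self._peek()
        if ch == "(":
            open_pos = self.pos
            self.pos += 1
            inner = self.parse_or(top_level=False)
            if self._peek() != ")":
                self.pos = open_pos
                self._error("unbalanced parenthesis")
            self.pos += 1
            return inner
        mobj = _KO_RE.match(self.text, self.pos)
        if mobj is None:
            self._error("expected KO identifier (K#####) or '('")
        self.pos = mobj.end()
        return _Ko(mobj.group())


@dataclass
class ModuleDefinition:
    """Parsed KEGG module: an ordered list of per-step boolean expressions."""

    module_id: str
    raw: str
    steps: list = field(repr=False)

    def render(self) -> str:
        return " ".join(s.render() for s in self.steps)

    def kos(self) -> set:
        out: set = set()
        for s in self.steps:
            out |= s.kos()
        return out


@dataclass
class ModuleEvaluation:
    module_id: str
    step_active: list[bool]
    any_active: bool
    completeness: float


def parse_module(definition: str, module_id: str = "") -> ModuleDefinition:
    """Parse a KEGG module definition string into step expressions."""
    if not definition or not definition.strip():
        raise ModuleParseError("empty definition", 0)
    steps = _Parser(definition.strip()).parse_steps()
    return ModuleDefinition(module_id, definition, steps)


def evaluate_module(md: ModuleDefinition, present) -> ModuleEvaluation:
    """Evaluate each step against a set of present KOs.

    A step is active when its expression is satisfied; multi-enzyme (AND)
    terms require all necessary components; optional ('-') components never
    affect activity.
    """
    present = set(present)
    active = [bool(step.evaluate(present)) for step in md.steps]
    return ModuleEvaluation(
        md.module_id,
        active,
        any(active),
        sum(active) / len(active) if active else 0.0,
    )


def map_og_to_ko(annotations: pd.DataFrame) -> dict[str, str]:
    """Modal KO per orthogroup from a (sequence, og, ko) table.

    Ties break toward the lexicographically smallest KO ID.
    """
    if annotations is None or len(annotations) == 0:
        raise ValueError("annotation table is empty")
    need = {"og", "ko"}
    if not need <= set(annotations.columns):
        raise ValueError("annotation table needs columns 'og' and 'ko'")
    counts = annotations.groupby(["og", "ko"], sort=True).size().reset_index(name="n")
    out: dict[str, str] = {}
    for og, grp in counts.groupby("og", sort=True):
        best = grp.sort_values(["n", "ko"], ascending=[False, True]).iloc[0]
        out[str(og)] = str(best["ko"])
    return out
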