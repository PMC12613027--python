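"""Slash-delimited consensus cleavage pattern parsing and matching.

Patterns describe the eight positions P4..P4' around a scissile bond, one
token per position, ``/``-separated, with the bond marked ``|`` (or ``=``,
accepted as a synonym) between the P1 and P1' tokens::

    EG/VIL/x/LF|x/AV/x/VF

Token grammar:

* ``x`` — wildcard, any residue;
* a run of residue letters (``VIL``) — an allowed-set;
* ``x[^RK]``, ``[^RK]`` or ``x(not R or K)`` — an excluded-set.

The canonical registry of low-substrate proteases ships as
``data/protease_registry.tsv`` (columns ``gene``, ``mechanism``,
``pattern_text``); proteases handled by scoring matrices have an empty
pattern cell and the registry enforces exactly one mechanism per gene.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Tuple, Union

from .encoders import AA_ALPHABET, POSITION_LABELS, AnnotatedSequence, window_positions
from .errors import PatternSyntaxError

WILDCARD = "wildcard"
ALLOWED = "allowed"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class PositionConstraint:
    """Constraint on one of the 8 window positions."""

    kind: str  # wildcard | allowed | excluded
    residues: FrozenSet[str] = frozenset()

    def __post_init__(self):
        if self.kind not in (WILDCARD, ALLOWED, EXCLUDED):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.kind != WILDCARD and not self.residues:
            raise ValueError(f"{self.kind} constraint needs a non-empty residue set")

    def accepts(self, residue: str) -> bool:
        if self.kind == WILDCARD:
            return True
        if self.kind == ALLOWED:
            return residue in self.residues
        return residue not in self.residues

    def token(self) -> str:
        if self.kind == WILDCARD:
            return "x"
        body = "".join(sorted(self.residues))
        return body if self.kind == ALLOWED else f"x[^{body}]"


@dataclass(frozen=True)
class CleavagePattern:
    """Parsed 8-position consensus pattern for one protease."""

    protease: str
    positions: Tuple[PositionConstraint, ...]
    source: str

    def __post_init__(self):
        if len(self.positions) != 8:
            raise ValueError("a cleavage pattern has exactly 8 position constraints")

    def matches_window(self, window: str) -> bool:
        return all(c.accepts(r) for c, r in zip(self.positions, window))

    def canonical(self) -> str:
        toks = [c.token() for c in self.positions]
        return "/".join(toks[:4]) + "|" + "/".join(toks[4:])


@dataclass(frozen=True)
class PatternMatch:
    protease: str
    p1: int
    window: str


_EXCLUDED_BRACKET = re.compile(r"^x?\[\^([A-Z]+)\]$")
_EXCLUDED_VERBAL = re.compile(r"^x?\(not ([A-Z][A-Za-z or]*)\)$")
_ALLOWED_RUN = re.compile(r"^[A-Z]+$")


def _parse_token(token: str, label: str) -> PositionConstraint:
    token = token.strip()
    if not token:
        raise PatternSyntaxError(f"empty token at {label}", token=token)
    if token == "x":
        return PositionConstraint(WILDCARD)
    m = _EXCLUDED_BRACKET.match(token)
    if m:
        return PositionConstraint(EXCLUDED, _residue_set(m.group(1), label))
    m = _EXCLUDED_VERBAL.match(token)
    if m:
        letters = [w for w in m.group(1).split() if w != "or"]
        if any(len(w) != 1 for w in letters):
            raise PatternSyntaxError(
                f"bad exclusion list at {label}: {token!r}", token=token)
        return PositionConstraint(EXCLUDED, _residue_set("".join(letters), label))
    if _ALLOWED_RUN.match(token):
        return PositionConstraint(ALLOWED, _residue_set(token, label))
    raise PatternSyntaxError(f"unparseable token at {label}: {token!r}", token=token)


def _residue_set(letters: str, label: str) -> FrozenSet[str]:
    bad = [ch for ch in letters if ch not in AA_ALPHABET]
    if bad:
        raise PatternSyntaxError(
            f"illegal residue letter {bad[0]!r} at {label}", token=letters)
    return frozenset(letters)


def parse_pattern(text: str, protease: str = "") -> CleavagePattern:
    """Parse a slash-delimited consensus pattern.

    ``=`` is accepted as a synonym for the scissile-bond marker ``|``.
    Round-tripping through :meth:`CleavagePattern.canonical` is stable.
    """
    normalised = text.replace("=", "|")
    halves = normalised.split("|")
    if len(halves) != 2:
        raise PatternSyntaxError(
            f"pattern must contain exactly one scissile-bond marker: {text!r}")
    tokens: List[str] = []
    for half in halves:
        tokens.extend(half.split("/"))
    if len(tokens) != 8:
        raise PatternSyntaxError(
            f"pattern must have 8 positions (got {len(tokens)}): {text!r}")
    constraints = tuple(
        _parse_token(tok, POSITION_LABELS[i]) for i, tok in enumerate(tokens))
    return CleavagePattern(protease=protease, positions=constraints, source=text)


def match_pattern(pattern: CleavagePattern,
                  seq: Union[AnnotatedSequence, str]) -> List[PatternMatch]:
    """All full-window P1 positions whose window satisfies the pattern.

    Matches may overlap; results are ordered by ascending ``p1``.
    """
    residues = seq.residues if isinstance(seq, AnnotatedSequence) else seq
    out: List[PatternMatch] = []
    for p1 in window_positions(len(residues)):
        window = residues[p1 - 4:p1 + 4]
        if pattern.matches_window(window):
            out.append(PatternMatch(protease=pattern.protease, p1=p1, window=window))
    return out


@dataclass(frozen=True)
class RegistryEntry:
    gene: str
    mechanism: str  # "pattern" | "pssm"
    pattern: Optional[CleavagePattern]


def load_registry(path=None) -> Dict[str, RegistryEntry]:
    """Load the packaged (or a user-supplied) protease registry.

    Enforces one mechanism per gene: pattern rows must carry a pattern
    string, scoring-matrix rows must not.
    """
    if path is None:
        fh = resources.files("lysocleave.data").joinpath(
            "protease_registry.tsv").open(encoding="utf-8")
    else:
        fh = open(path, encoding="utf-8")
    with fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    registry: Dict[str, RegistryEntry] = {}
    for row in rows:
        gene = row["gene"].strip()
        mechanism = row["mechanism"].strip()
        text = (row.get("pattern_text") or "").strip()
        if mechanism == "pattern":
            if not text:
                raise PatternSyntaxError(f"registry: {gene} marked pattern but has no pattern")
            entry = RegistryEntry(gene, mechanism, parse_pattern(text, protease=gene))
        elif mechanism == "pssm":
            if text:
                raise PatternSyntaxError(
                    f"registry: {gene} marked pssm but carries a pattern string")
            entry = RegistryEntry(gene, mechanism, None)
        else:
            raise PatternSyntaxError(f"registry: unknown mechanism {mechanism!r} for {gene}")
        if gene in registry:
            raise PatternSyntaxError(f"registry: duplicate gene {gene}")
        registry[gene] = entry
    return registry


def pattern_proteases(registry: Optional[Dict[str, RegistryEntry]] = None
                      ) -> Dict[str, CleavagePattern]:
    """Gene → parsed pattern for every pattern-mechanism protease."""
    registry = registry or load_registry()
    return {g: e.pattern for g, e in registry.items() if e.mechanism == "pattern"}
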