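"""Fragment generation from cut sites.

Three digestion modes are provided:

* **complete** — every cut is applied; ``n`` cuts yield ``n + 1``
  fragments that tile the input;
* **partial** — every concatenation of consecutive complete-digest
  segments, ``(n + 1)(n + 2) / 2`` fragments in total (including the
  complete fragments and the undigested sequence);
* **sequential** — proteases act in a user-defined order, each one
  digesting every fragment left by its predecessor; sites whose window
  straddles an earlier cut are unavailable by construction, and fragments
  shorter than a minimum length are dropped from the final output only.

Coordinates are 1-based inclusive. A cut at ``p1`` severs the bond between
residues ``p1`` and ``p1 + 1``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

from .encoders import AA_ALPHABET, AnnotatedSequence
from .errors import ConfigError, MassUndefinedError
from .pattern_engine import CleavagePattern, match_pattern

logger = logging.getLogger(__name__)

DEFAULT_MIN_LENGTH = 4

WATER_AVERAGE = 18.0153
WATER_MONO = 18.0105646863

# average and monoisotopic residue masses (Da), standard IUPAC values
RESIDUE_MASS_AVERAGE: Dict[str, float] = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
RESIDUE_MASS_MONO: Dict[str, float] = {
    "A": 71.03711, "C": 103.00919, "D": 115.02694, "E": 129.04259,
    "F": 147.06841, "G": 57.02146, "H": 137.05891, "I": 113.08406,
    "K": 128.09496, "L": 113.08406, "M": 131.04049, "N": 114.04293,
    "P": 97.05276, "Q": 128.05858, "R": 156.10111, "S": 87.03203,
    "T": 101.04768, "V": 99.06841, "W": 186.07931, "Y": 163.06333,
}


def peptide_mw(sequence: str, monoisotopic: bool = False) -> float:
    """Peptide molecular weight in daltons (average mass by default)."""
    if not sequence:
        raise MassUndefinedError("empty peptide has no molecular weight")
    table = RESIDUE_MASS_MONO if monoisotopic else RESIDUE_MASS_AVERAGE
    water = WATER_MONO if monoisotopic else WATER_AVERAGE
    try:
        return sum(table[ch] for ch in sequence) + water
    except KeyError as exc:
        raise MassUndefinedError(
            f"mass undefined for non-canonical residue {exc.args[0]!r}") from None


def _load_pka_table() -> Dict[str, Tuple[float, int]]:
    path = resources.files("lysocleave.data").joinpath("pka_emboss.tsv")
    with path.open(encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return {r["group"]: (float(r["pka"]), +1 if r["sign"] == "+" else -1)
            for r in rows}


PKA_TABLE: Dict[str, Tuple[float, int]] = _load_pka_table()


def peptide_charge(sequence: str, ph: float,
                   pka: Optional[Dict[str, Tuple[float, int]]] = None) -> float:
    """Net charge of the peptide at the given pH under the pKa table."""
    if not sequence:
        raise MassUndefinedError("empty peptide has no charge")
    bad = set(sequence) - set(AA_ALPHABET)
    if bad:
        raise MassUndefinedError(f"charge undefined for residue {bad.pop()!r}")
    pka = pka or PKA_TABLE
    groups = [("nterm", 1), ("cterm", 1)]
    for ch in sequence:
        if ch in pka:
            groups.append((ch, 1))
    charge = 0.0
    for group, count in groups:
        pk, sign = pka[group]
        if sign > 0:
            charge += count / (1.0 + 10.0 ** (ph - pk))
        else:
            charge -= count / (1.0 + 10.0 ** (pk - ph))
    return charge


def peptide_pi(sequence: str,
               pka: Optional[Dict[str, Tuple[float, int]]] = None,
               tol: float = 0.01) -> float:
    """Isoelectric point by bisection of the net-charge curve (±0.01 pH)."""
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if peptide_charge(sequence, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 2)


@dataclass(frozen=True)
class Fragment:
    """A contiguous peptide with provenance and physicochemical properties."""

    parent_id: str
    start: int  # 1-based inclusive
    end: int
    sequence: str
    producing_steps: Tuple[Tuple[str, int], ...] = ()
    score: Optional[float] = None
    mw: Optional[float] = None
    pi: Optional[float] = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise IndexError(f"bad fragment coordinates [{self.start}, {self.end}]")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError("fragment sequence length disagrees with coordinates")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class Protease(Protocol):
    """Anything that can call cut sites on a sequence fragment."""

    name: str

    def call_sites(self, seq: AnnotatedSequence) -> List[Tuple[int, Optional[float]]]:
        ...


@dataclass(frozen=True)
class PatternProtease:
    """Digestion adapter around a consensus pattern (scoreless sites)."""

    pattern: CleavagePattern

    @property
    def name(self) -> str:
        return self.pattern.protease

    def call_sites(self, seq: AnnotatedSequence) -> List[Tuple[int, Optional[float]]]:
        return [(m.p1, None) for m in match_pattern(self.pattern, seq)]


@dataclass
class DigestPlan:
    """Ordered protease list plus output options for sequential digestion."""

    proteases: Sequence[Protease]
    min_length: int = DEFAULT_MIN_LENGTH
    partial: bool = False

    def __post_init__(self):
        if not self.proteases:
            raise ConfigError("digestion plan needs at least one protease")
        if self.min_length < 1:
            raise ConfigError("min_length must be >= 1")


def _validate_cuts(length: int, p1_positions: Sequence[int]) -> List[int]:
    cuts = sorted(set(int(p) for p in p1_positions))
    if len(cuts) != len(p1_positions):
        logger.warning("duplicate cut positions collapsed")
    for p in cuts:
        if not (1 <= p <= length - 1):
            raise IndexError(f"cut position {p} outside [1, {length - 1}]")
    return cuts


def _make_fragment(seq: AnnotatedSequence, start: int, end: int,
                   events: Tuple[Tuple[str, int], ...] = (),
                   score: Optional[float] = None,
                   with_properties: bool = True) -> Fragment:
    subseq = seq.residues[start - 1:end]
    mw = pi = None
    if with_properties and set(subseq) <= set(AA_ALPHABET):
        mw = round(peptide_mw(subseq), 2)
        pi = peptide_pi(subseq)
    return Fragment(parent_id=seq.id, start=start, end=end, sequence=subseq,
                    producing_steps=events, score=score, mw=mw, pi=pi)


def complete_fragments(seq: AnnotatedSequence,
                       p1_positions: Sequence[int],
                       with_properties: bool = True) -> List[Fragment]:
    """Apply every cut: ``n`` distinct cuts give ``n + 1`` tiling fragments."""
    cuts = _validate_cuts(len(seq), p1_positions)
    bounds = [0] + cuts + [len(seq)]
    return [_make_fragment(seq, bounds[i] + 1, bounds[i + 1],
                           with_properties=with_properties)
            for i in range(len(bounds) - 1)]


def partial_fragments(seq: AnnotatedSequence,
                      p1_positions: Sequence[int],
                      with_properties: bool = True) -> List[Fragment]:
    """Every concatenation of consecutive complete-digest segments.

    ``n`` cuts yield ``(n + 1)(n + 2) / 2`` fragments, ordered by start
    then end; duplicates by coordinates are impossible since the cut list
    is deduplicated.
    """
    cuts = _validate_cuts(len(seq), p1_positions)
    bounds = [0] + cuts + [len(seq)]
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, len(bounds)):
            out.append(_make_fragment(seq, bounds[i] + 1, bounds[j],
                                      with_properties=with_properties))
    return out


def sequential_digest(seq: AnnotatedSequence, plan: DigestPlan,
                      with_properties: bool = True) -> List[Fragment]:
    """Ordered stepwise digestion.

    Each protease digests every fragment produced by the previous step,
    calling sites only on windows fully contained in that fragment; the
    minimum-length filter applies to the final output only, so short
    intermediates stay in the pool for later proteases. Surviving
    fragments are non-overlapping and, together with the discarded short
    ones, tile the input.
    """
    spans: List[Tuple[int, int]] = [(1, len(seq))]
    cut_events: Dict[int, Tuple[str, int, Optional[float]]] = {}
    for protease in plan.proteases:
        next_spans: List[Tuple[int, int]] = []
        for start, end in spans:
            fragment_seq = seq.slice(start, end)
            local_sites = protease.call_sites(fragment_seq)
            abs_cuts = []
            for local_p1, score in local_sites:
                abs_p1 = start - 1 + local_p1
                if abs_p1 >= end:  # defensive: a cut at the fragment end is no cut
                    continue
                abs_cuts.append(abs_p1)
                cut_events.setdefault(abs_p1, (protease.name, abs_p1, score))
            bounds = [start - 1] + sorted(set(abs_cuts)) + [end]
            next_spans.extend((bounds[i] + 1, bounds[i + 1])
                              for i in range(len(bounds) - 1))
        spans = next_spans
    out: List[Fragment] = []
    for start, end in spans:
        if end - start + 1 < plan.min_length:
            continue
        events = []
        scores = []
        for boundary in (start - 1, end):
            if boundary in cut_events:
                name, p1, score = cut_events[boundary]
                events.append((name, p1))
                if score is not None:
                    scores.append(score)
        frag_score = sum(scores) / len(scores) if scores else None
        out.append(_make_fragment(seq, start, end, events=tuple(events),
                                  score=frag_score,
                                  with_properties=with_properties))
    return out
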