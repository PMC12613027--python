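"""Seeded synthetic substrate corpora with planted cleavage specificity.

Sequences are drawn i.i.d. from a background composition (uniform by
default; a Swiss-Prot-like table ships as an alternative); cleavage sites
overwrite 8 residues (P4..P4') with draws from per-position motif
distributions, never overlapping another site's window and never within 4
residues of a terminus. Structural annotation tracks are sampled so that
planted windows carry the motif's secondary-structure class and
accessibility range while the rest of the sequence follows a background.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .encoders import AA_ALPHABET, SS_ALPHABET, WINDOW_OFFSET, WINDOW_SIZE
from .errors import GenerationError
from .training_eval import SubstrateRecord

UNIFORM_BACKGROUND: Dict[str, float] = {aa: 1.0 / 20 for aa in AA_ALPHABET}


def swissprot_background() -> Dict[str, float]:
    """Packaged Swiss-Prot-like residue composition, renormalised to sum 1."""
    path = resources.files("lysocleave.data").joinpath("background_swissprot.tsv")
    with path.open(encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    raw = {r["residue"]: float(r["fraction"]) for r in rows}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


@dataclass(frozen=True)
class MotifSpec:
    """Planted cleavage specificity: 8 positional residue distributions plus
    a structural bias at the site and an expected site density."""

    position_dists: Tuple[Mapping[str, float], ...]
    ss_class: str = "E"
    rsa_range: Tuple[int, int] = (0, 3)
    density: float = 2.0  # expected sites per 100 residues

    def __post_init__(self):
        if len(self.position_dists) != WINDOW_SIZE:
            raise ValueError("a motif needs exactly 8 positional distributions")
        for i, dist in enumerate(self.position_dists):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"positional distribution {i} sums to {total}")
            bad = set(dist) - set(AA_ALPHABET)
            if bad:
                raise ValueError(f"non-canonical residue {bad.pop()!r} in motif")
        if self.ss_class not in SS_ALPHABET:
            raise ValueError(f"unknown secondary-structure class {self.ss_class!r}")
        lo, hi = self.rsa_range
        if not (0 <= lo <= hi <= 9):
            raise ValueError("rsa_range must satisfy 0 <= lo <= hi <= 9")
        if self.density <= 0:
            raise ValueError("site density must be positive")

    def top_residues(self, position: int, k: int = 3) -> List[str]:
        """The k most probable residues at a window position (0=P4 … 3=P1)."""
        dist = self.position_dists[position]
        return [r for r, _ in sorted(dist.items(), key=lambda kv: (-kv[1], kv[0]))[:k]]


def enriched_motif(enrichments: Mapping[int, Mapping[str, float]],
                   ss_class: str = "E",
                   rsa_range: Tuple[int, int] = (0, 3),
                   density: float = 2.0) -> MotifSpec:
    """Build a motif from sparse per-position enrichments.

    ``enrichments`` maps window position (0=P4 … 7=P4') to residue → mass;
    leftover probability is spread uniformly over the remaining residues.
    """
    dists = []
    for p in range(WINDOW_SIZE):
        spec = dict(enrichments.get(p, {}))
        mass = sum(spec.values())
        if mass > 1.0 + 1e-9:
            raise ValueError(f"enrichment mass {mass} at position {p} exceeds 1")
        rest = [aa for aa in AA_ALPHABET if aa not in spec]
        leftover = max(0.0, 1.0 - mass)
        for aa in rest:
            spec[aa] = leftover / len(rest)
        total = sum(spec.values())
        dists.append({aa: v / total for aa, v in spec.items()})
    return MotifSpec(position_dists=tuple(dists), ss_class=ss_class,
                     rsa_range=rsa_range, density=density)


def strong_consensus_motif(consensus: str = "TVCFIKAG",
                           p1_dist: Optional[Mapping[str, float]] = None,
                           strength: float = 0.6,
                           density: float = 2.0) -> MotifSpec:
    """A motif with one dominant residue per window position.

    Each position puts ``strength`` probability mass on its consensus
    residue; the P1 position (index 3) instead uses ``p1_dist`` (default:
    hydrophobic preference F > L > W, total mass ``0.95``). This is the
    recoverable regime: a trained matrix should rank the planted residues
    on top and separate held-out sites cleanly.
    """
    if len(consensus) != WINDOW_SIZE:
        raise ValueError("consensus must be 8 residues")
    p1_dist = dict(p1_dist or {"F": 0.6, "L": 0.25, "W": 0.10})
    enrichments = {p: (p1_dist if p == 3 else {ch: strength})
                   for p, ch in enumerate(consensus)}
    return enriched_motif(enrichments, density=density)


def cathepsin_d_like_motif(strength: float = 0.7, density: float = 2.0) -> MotifSpec:
    """A hydrophobic-P1 motif (F, L, W enriched at P1, C at P2, I/F at P1')."""
    p1 = {"F": 0.5 * strength, "L": 0.3 * strength, "W": 0.2 * strength}
    return enriched_motif({
        2: {"C": 0.4 * strength},
        3: p1,
        4: {"I": 0.35 * strength, "F": 0.35 * strength},
    }, ss_class="E", rsa_range=(0, 3), density=density)


@dataclass(frozen=True)
class SyntheticCorpus:
    substrates: Tuple[SubstrateRecord, ...]
    motif: MotifSpec
    seed: int
    background: Mapping[str, float]
    #: planted ground truth (survives label corruption)
    truth: Mapping[str, Tuple[int, ...]] = field(default=None)

    def __post_init__(self):
        if self.truth is None:
            object.__setattr__(
                self, "truth", {s.id: s.p1_sites for s in self.substrates})


def _sample_dist(rng: random.Random, dist: Mapping[str, float]) -> str:
    items = sorted(dist.items())
    r = rng.random()
    acc = 0.0
    for ch, p in items:
        acc += p
        if r < acc:
            return ch
    return items[-1][0]


def _place_sites(rng: random.Random, length: int, n_sites: int,
                 max_tries: int = 2000) -> List[int]:
    # p1 in [4, L-4]; windows [p1-3, p1+4] must not overlap: |p1_i - p1_j| >= 8
    placed: List[int] = []
    tries = 0
    lo, hi = WINDOW_OFFSET + 1, length - (WINDOW_SIZE - WINDOW_OFFSET)
    while len(placed) < n_sites:
        if tries >= max_tries:
            raise GenerationError(
                f"could not place {n_sites} non-overlapping sites in a "
                f"length-{length} sequence")
        tries += 1
        p1 = rng.randint(lo, hi)
        if all(abs(p1 - q) >= WINDOW_SIZE for q in placed):
            placed.append(p1)
    return sorted(placed)


def generate_corpus(n_substrates: int,
                    length_range: Tuple[int, int],
                    motif: MotifSpec,
                    background: Optional[Mapping[str, float]] = None,
                    seed: int = 0) -> SyntheticCorpus:
    """Generate a seeded corpus of annotated substrates with planted sites."""
    if n_substrates < 1:
        raise GenerationError("need at least one substrate")
    lo, hi = length_range
    if lo < 16 or hi < lo:
        raise GenerationError("substrate lengths must be >= 16 and ordered")
    background = dict(background or UNIFORM_BACKGROUND)
    total = sum(background.values())
    background = {k: v / total for k, v in background.items()}
    rng = random.Random(seed)
    substrates = []
    for i in range(n_substrates):
        length = rng.randint(lo, hi)
        # target number of sites from the density, at least one where possible
        expected = motif.density * length / 100.0
        n_sites = max(1, int(round(expected)))
        lo_p1, hi_p1 = WINDOW_OFFSET + 1, length - (WINDOW_SIZE - WINDOW_OFFSET - 1)
        max_fit = (hi_p1 - lo_p1) // WINDOW_SIZE + 1
        if n_sites > max_fit:
            raise GenerationError(
                f"density {motif.density} asks for {n_sites} non-overlapping "
                f"sites but a length-{length} sequence fits at most {max_fit}")
        sites = _place_sites(rng, length, n_sites)
        residues = [_sample_dist(rng, background) for _ in range(length)]
        ss = [rng.choice(SS_ALPHABET) for _ in range(length)]
        rsa = [str(rng.randint(0, 9)) for _ in range(length)]
        for p1 in sites:
            start = p1 - 1 - WINDOW_OFFSET  # 0-based window start
            for offset in range(WINDOW_SIZE):
                residues[start + offset] = _sample_dist(
                    rng, motif.position_dists[offset])
                ss[start + offset] = motif.ss_class
                rsa[start + offset] = str(rng.randint(*motif.rsa_range))
        substrates.append(SubstrateRecord(
            id=f"syn{i:04d}",
            sequence="".join(residues),
            p1_sites=tuple(sites),
            ss="".join(ss),
            rsa="".join(rsa),
        ))
    return SyntheticCorpus(substrates=tuple(substrates), motif=motif,
                           seed=seed, background=background)


def corrupt_sites(corpus: SyntheticCorpus,
                  drop_fraction: float = 0.0,
                  spurious_fraction: float = 0.0,
                  seed: int = 0) -> SyntheticCorpus:
    """Remove a seeded fraction of true labels and add spurious ones.

    The planted ground truth is retained in ``corpus.truth`` for scoring.
    """
    if not (0 <= drop_fraction < 1) or not (0 <= spurious_fraction < 1):
        raise ValueError("corruption fractions must lie in [0, 1)")
    rng = random.Random(seed)
    all_sites = [(s.id, p1) for s in corpus.substrates for p1 in s.p1_sites]
    n_drop = int(round(drop_fraction * len(all_sites)))
    n_spur = int(round(spurious_fraction * len(all_sites)))
    dropped = set(rng.sample(all_sites, n_drop)) if n_drop else set()
    new_subs = []
    for sub in corpus.substrates:
        sites = [p for p in sub.p1_sites if (sub.id, p) not in dropped]
        new_subs.append((sub, sites))
    # spread spurious labels over random non-site positions
    for _ in range(n_spur):
        sub, sites = new_subs[rng.randrange(len(new_subs))]
        for _ in range(100):
            p1 = rng.randint(1, len(sub.sequence) - 1)
            if p1 not in sites and p1 not in sub.p1_sites:
                sites.append(p1)
                break
    out = tuple(replace(sub, p1_sites=tuple(sorted(sites)))
                for sub, sites in new_subs)
    return SyntheticCorpus(substrates=out, motif=corpus.motif, seed=corpus.seed,
                           background=corpus.background, truth=corpus.truth)
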