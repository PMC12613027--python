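"""Training protocol and evaluation metrics.

Covers redundancy removal (greedy identity clustering), substrate-level
train/test splitting, assembly of labelled window sets (either with every
non-site position as a negative, or under-sampled to a 3:1
negative:positive ratio), model training and confusion-matrix metrics.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio import Align

from . import pssm_model
from .encoders import (
    AnnotatedSequence,
    FeatureTrack,
    encode_tracks,
    extract_window,
    has_full_window,
    window_positions,
)
from .errors import EvaluationError, InsufficientDataError, SplitError
from .pssm_model import FEATURE_SETS, ScoringModel

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.70
SET2_NEGATIVE_RATIO = 3


@dataclass(frozen=True)
class SubstrateRecord:
    """One training substrate: full sequence plus its known P1 sites."""

    id: str
    sequence: str
    p1_sites: Tuple[int, ...]
    ss: Optional[str] = None
    rsa: Optional[str] = None

    def __post_init__(self):
        sites = tuple(sorted(set(self.p1_sites)))
        if sites != tuple(self.p1_sites):
            object.__setattr__(self, "p1_sites", sites)
        for p in self.p1_sites:
            if not (1 <= p <= len(self.sequence) - 1):
                raise IndexError(
                    f"substrate {self.id!r}: site {p} outside [1, {len(self.sequence) - 1}]")

    def to_annotated(self) -> AnnotatedSequence:
        return AnnotatedSequence(id=self.id, residues=self.sequence,
                                 ss=self.ss, rsa=self.rsa)


@dataclass
class LabelledWindowSet:
    """Window bundles (feature → 8-char window) with labels."""

    positives: List[Mapping[str, str]]
    negatives: List[Mapping[str, str]]
    provenance: str  # "set1" | "set2"
    seed: int = 0


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix counts and derived fractions.

    Undefined ratios (zero denominators) are NaN, never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def f1(self) -> float:
        p, s = self.precision, self.sensitivity
        if math.isnan(p) or math.isnan(s) or p + s == 0:
            return float("nan")
        return 2 * p * s / (p + s)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "f1": self.f1,
        }


# -- homology filtering --------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = 0
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def pairwise_identity(a: str, b: str) -> float:
    """Exact matches in a global alignment over the shorter sequence length."""
    if not a or not b:
        return 0.0
    alignment = _aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def homology_filter(substrates: Sequence[SubstrateRecord],
                    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                    ) -> List[SubstrateRecord]:
    """Greedy longest-first clustering; returns one representative per cluster.

    A substrate joins an existing cluster when its identity to the
    representative exceeds the threshold; otherwise it founds a new one.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must lie in (0, 1]")
    ordered = sorted(substrates, key=lambda s: (-len(s.sequence), s.id))
    representatives: List[SubstrateRecord] = []
    for sub in ordered:
        if all(pairwise_identity(sub.sequence, rep.sequence) <= identity_threshold
               for rep in representatives):
            representatives.append(sub)
    return representatives


# -- splitting and window assembly ---------------------------------------

def split_substrates(substrates: Sequence[SubstrateRecord],
                     train_fraction: float = 0.9,
                     seed: int = 0
                     ) -> Tuple[List[SubstrateRecord], List[SubstrateRecord]]:
    """Disjoint substrate-level split; the test set gets
    ``max(1, floor(n * (1 - train_fraction)))`` substrates."""
    if len(substrates) < 2:
        raise SplitError("substrate-level split needs at least 2 substrates")
    if not 0 < train_fraction < 1:
        raise SplitError("train_fraction must lie in (0, 1)")
    rng = random.Random(seed)
    order = list(substrates)
    rng.shuffle(order)
    # guard the floor against float error (e.g. 40 * (1 - 0.9) = 3.999...)
    n_test = max(1, math.floor(len(order) * (1 - train_fraction) + 1e-9))
    return order[n_test:], order[:n_test]


def _window_bundle(tracks: Mapping[str, FeatureTrack], p1: int
                   ) -> Optional[Mapping[str, str]]:
    bundle = {}
    for feat, track in tracks.items():
        window = extract_window(track, p1)
        if window is None:
            return None
        bundle[feat] = window
    return bundle


def build_labelled_sets(substrates: Sequence[SubstrateRecord],
                        mode: str = "set1",
                        seed: int = 0,
                        features: Sequence[str] = ("aa",)
                        ) -> LabelledWindowSet:
    """Assemble positive/negative window bundles from annotated substrates.

    Positives are the annotated P1 sites with full windows (sites too close
    to a terminus are dropped with a warning). ``set1`` keeps every other
    full-window position as a negative; ``set2`` draws a seeded 3:1
    negative:positive sample without replacement.
    """
    if mode not in ("set1", "set2"):
        raise ValueError(f"unknown mode {mode!r}")
    positives: List[Mapping[str, str]] = []
    negatives: List[Mapping[str, str]] = []
    for sub in substrates:
        tracks = encode_tracks(sub.to_annotated(), features)
        site_set = set(sub.p1_sites)
        for p in sub.p1_sites:
            if not has_full_window(p, len(sub.sequence)):
                logger.warning("substrate %s: site %d has no full window; dropped",
                               sub.id, p)
        for p1 in window_positions(len(sub.sequence)):
            bundle = _window_bundle(tracks, p1)
            if bundle is None:
                continue
            (positives if p1 in site_set else negatives).append(bundle)
    if not positives:
        raise InsufficientDataError("no positive full-window site in the corpus")
    if mode == "set2":
        wanted = SET2_NEGATIVE_RATIO * len(positives)
        if wanted < len(negatives):
            rng = random.Random(seed)
            negatives = rng.sample(negatives, wanted)
        else:
            logger.warning("only %d negatives available for a 3:1 ratio of %d",
                           len(negatives), wanted)
    return LabelledWindowSet(positives=positives, negatives=negatives,
                             provenance=mode, seed=seed)


# -- training ------------------------------------------------------------

def train_model(substrates: Sequence[SubstrateRecord],
                protease: str,
                feature_set: str = "aa_only",
                mode: str = "set1",
                weighted: bool = False,
                threshold_criterion: str = "pr_gap",
                seed: int = 0) -> ScoringModel:
    """Train a full scoring model from labelled substrates.

    Builds backgrounds from the complete substrate corpus and one PSSM per
    enabled feature from the positive windows, optionally fits
    per-(feature, position) weights, scores the labelled training windows
    and calibrates the decision threshold.
    """
    features = FEATURE_SETS[feature_set]
    track_corpus: Dict[str, List[FeatureTrack]] = {f: [] for f in features}
    for sub in substrates:
        tracks = encode_tracks(sub.to_annotated(), features)
        for f in features:
            track_corpus[f].append(tracks[f])
    labelled = build_labelled_sets(substrates, mode=mode, seed=seed,
                                   features=features)
    pssms = {}
    backgrounds = {}
    for f in features:
        bg = pssm_model.build_background(track_corpus[f])
        pfm = pssm_model.build_pfm([b[f] for b in labelled.positives], f)
        pssms[f] = pssm_model.pfm_to_pssm(pfm, bg)
        backgrounds[f] = bg
    weights = None
    if weighted:
        weights = pssm_model.fit_weights(labelled.positives, labelled.negatives,
                                         pssms, features, seed=seed)
    model = ScoringModel(protease=protease, feature_set=feature_set,
                         pssms=pssms, backgrounds=backgrounds,
                         weighted=weighted, weights=weights,
                         metadata={
                             "n_substrates": len(substrates),
                             "n_positive_windows": len(labelled.positives),
                             "n_negative_windows": len(labelled.negatives),
                             "training_mode": mode,
                             "threshold_criterion": threshold_criterion,
                             "seed": seed,
                             "version": _package_version(),
                         })
    scored = [(model.score_windows(b)[1], 1) for b in labelled.positives]
    scored += [(model.score_windows(b)[1], 0) for b in labelled.negatives]
    model.threshold = pssm_model.calibrate_threshold(scored, criterion=threshold_criterion)
    return model


def _package_version() -> str:
    from . import __version__
    return __version__


# -- evaluation ----------------------------------------------------------

def evaluate_model(model: ScoringModel, test: LabelledWindowSet) -> Metrics:
    """Confusion-matrix metrics of a fixed-threshold model on a labelled set."""
    if not test.positives and not test.negatives:
        raise EvaluationError("empty test set")
    tp = fp = tn = fn = 0
    for bundle in test.positives:
        _, final = model.score_windows(bundle)
        if final >= model.threshold:
            tp += 1
        else:
            fn += 1
    for bundle in test.negatives:
        _, final = model.score_windows(bundle)
        if final >= model.threshold:
            fp += 1
        else:
            tn += 1
    return Metrics(tp=tp, fp=fp, tn=tn, fn=fn)
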