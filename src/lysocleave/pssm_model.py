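"""Position-specific scoring matrices for cleavage-site prediction.

The pipeline per protease and feature track:

1. background character frequencies over the full substrate corpus;
2. a position frequency matrix (PFM) over the aligned 8-character
   cleavage windows, columns P4..P4';
3. the log2 ratio of positional to background frequency (undefined cells
   — zero counts — are set to the minimum of the defined cells);
4. min-max scaling of that matrix into [0, 1];
5. sliding-window scoring: a candidate site's score is the mean of the 8
   scaled lookups per feature, averaged over features (or a weighted sum
   with per-(feature, position) weights learned from a random forest);
6. a decision threshold calibrated on labelled training scores by a
   precision-recall sweep.

Scores live in [0, 1]; 0 means an unlikely and 1 a likely cleavage site.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .encoders import (
    ALPHABETS,
    WINDOW_SIZE,
    AnnotatedSequence,
    FeatureTrack,
    encode_tracks,
    extract_window,
    window_positions,
)
from .errors import (
    CalibrationError,
    DegenerateTrainingError,
    InsufficientDataError,
    MissingAnnotationError,
    WindowLengthError,
)

logger = logging.getLogger(__name__)

FEATURE_SETS: Dict[str, Tuple[str, ...]] = {
    "aa_only": ("aa",),
    "aa_physical": ("aa", "charge", "hydropathy"),
    "all": ("aa", "charge", "hydropathy", "ss", "rsa"),
}

#: confidence margins relative to the decision threshold (config-overridable)
CONFIDENCE_HIGH_MARGIN = 0.10
CONFIDENCE_LOW_MARGIN = 0.02


@dataclass(frozen=True)
class BackgroundFrequencies:
    feature: str
    freq: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, expected 1")


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    feature: str
    alphabet: str
    matrix: np.ndarray  # len(alphabet) x 8, columns sum to 1
    n_windows: int


@dataclass(frozen=True)
class FeaturePSSM:
    feature: str
    alphabet: str
    raw: np.ndarray     # log2 positional enrichment, len(alphabet) x 8
    scaled: np.ndarray  # min-max scaled into [0, 1]

    def lookup(self, window: str) -> np.ndarray:
        """Scaled scores of the 8 window characters, P4..P4'."""
        if len(window) != WINDOW_SIZE:
            raise WindowLengthError(f"window {window!r} is not {WINDOW_SIZE} characters")
        idx = [self.alphabet.index(ch) for ch in window]
        return self.scaled[idx, np.arange(WINDOW_SIZE)]


@dataclass(frozen=True)
class SiteScore:
    p1: int
    window_aa: str
    per_feature: Mapping[str, float]
    final: float
    positive: bool
    confidence: str  # low | medium | high


@dataclass
class ScoringModel:
    """Per-protease bundle of scaled PSSMs, weights and a threshold."""

    protease: str
    feature_set: str
    pssms: Dict[str, FeaturePSSM]
    backgrounds: Dict[str, BackgroundFrequencies]
    threshold: float = 0.5
    weighted: bool = False
    weights: Optional[Dict[Tuple[str, int], float]] = None
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        expected = set(FEATURE_SETS[self.feature_set])
        if set(self.pssms) != expected:
            raise ValueError(
                f"feature set {self.feature_set!r} expects matrices for "
                f"{sorted(expected)}, got {sorted(self.pssms)}")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.weighted:
            if self.weights is None:
                raise ValueError("weighted model without weights")
            total = sum(self.weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"weights sum to {total}, expected 1")

    @property
    def features(self) -> Tuple[str, ...]:
        return FEATURE_SETS[self.feature_set]

    @property
    def needs_annotations(self) -> bool:
        return "ss" in self.features or "rsa" in self.features

    # -- scoring ---------------------------------------------------------

    def score_windows(self, bundle: Mapping[str, str]) -> Tuple[Dict[str, float], float]:
        """Score one window bundle (feature → 8-char window).

        Returns the per-feature mean scores and the final site score.
        """
        per_feature: Dict[str, float] = {}
        lookups: Dict[str, np.ndarray] = {}
        for feat in self.features:
            lookups[feat] = self.pssms[feat].lookup(bundle[feat])
            per_feature[feat] = float(lookups[feat].mean())
        if self.weighted:
            final = sum(self.weights[(feat, p)] * float(lookups[feat][p])
                        for feat in self.features for p in range(WINDOW_SIZE))
        else:
            final = sum(per_feature.values()) / len(per_feature)
        return per_feature, float(final)

    def _confidence(self, final: float) -> str:
        if final >= min(1.0, self.threshold + CONFIDENCE_HIGH_MARGIN):
            return "high"
        if final < min(1.0, self.threshold + CONFIDENCE_LOW_MARGIN):
            return "low"
        return "medium"

    def score_site(self, seq: AnnotatedSequence, p1: int,
                   tracks: Optional[Mapping[str, FeatureTrack]] = None
                   ) -> Optional[SiteScore]:
        """Score the candidate scissile bond after residue ``p1``.

        Returns ``None`` when the full window does not fit or (under the
        permissive flag) contains a non-canonical character.
        """
        if tracks is None:
            tracks = encode_tracks(seq, self.features)
        bundle = {}
        for feat in self.features:
            window = extract_window(tracks[feat], p1)
            if window is None:
                return None
            if any(ch not in ALPHABETS[feat] for ch in window):
                logger.debug("skipping window at p1=%d of %s: non-canonical character",
                             p1, seq.id)
                return None
            bundle[feat] = window
        per_feature, final = self.score_windows(bundle)
        return SiteScore(
            p1=p1,
            window_aa=bundle["aa"],
            per_feature=per_feature,
            final=final,
            positive=final >= self.threshold,
            confidence=self._confidence(final),
        )

    def scan_sequence(self, seq: AnnotatedSequence) -> List[SiteScore]:
        """Score every full-window candidate site, ascending in ``p1``.

        Sequences shorter than 8 residues yield an empty list.
        """
        if len(seq) < WINDOW_SIZE:
            logger.info("sequence %s shorter than %d residues: no candidate sites",
                        seq.id, WINDOW_SIZE)
            return []
        if self.needs_annotations and not seq.annotated:
            raise MissingAnnotationError(
                f"model {self.protease!r} uses structural features but sequence "
                f"{seq.id!r} has no ss/rsa annotation")
        tracks = encode_tracks(seq, self.features)
        out = []
        for p1 in window_positions(len(seq)):
            site = self.score_site(seq, p1, tracks=tracks)
            if site is not None:
                out.append(site)
        return out

    def call_sites(self, seq: AnnotatedSequence) -> List[Tuple[int, float]]:
        """(p1, score) for every site called positive — digestion interface."""
        return [(s.p1, s.final) for s in self.scan_sequence(seq) if s.positive]

    @property
    def name(self) -> str:
        return self.protease

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        doc = {
            "protease": self.protease,
            "feature_set": self.feature_set,
            "threshold": self.threshold,
            "weighted": self.weighted,
            "weights": None if self.weights is None else [
                {"feature": f, "position": p, "weight": w}
                for (f, p), w in sorted(self.weights.items())
            ],
            "backgrounds": {
                feat: {c: bg.freq[c] for c in sorted(bg.freq)}
                for feat, bg in self.backgrounds.items()
            },
            "pssms": {
                feat: {
                    "alphabet": pssm.alphabet,
                    "raw": [[float(v) for v in row] for row in pssm.raw],
                    "scaled": [[float(v) for v in row] for row in pssm.scaled],
                }
                for feat, pssm in self.pssms.items()
            },
            "metadata": self.metadata,
        }
        return doc

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, ensure_ascii=False)
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "ScoringModel":
        pssms = {
            feat: FeaturePSSM(
                feature=feat,
                alphabet=entry["alphabet"],
                raw=np.array(entry["raw"], dtype=float),
                scaled=np.array(entry["scaled"], dtype=float),
            )
            for feat, entry in doc["pssms"].items()
        }
        backgrounds = {
            feat: BackgroundFrequencies(feature=feat, freq=dict(freqs))
            for feat, freqs in doc["backgrounds"].items()
        }
        weights = None
        if doc.get("weights") is not None:
            weights = {(w["feature"], int(w["position"])): float(w["weight"])
                       for w in doc["weights"]}
        return cls(
            protease=doc["protease"],
            feature_set=doc["feature_set"],
            pssms=pssms,
            backgrounds=backgrounds,
            threshold=float(doc["threshold"]),
            weighted=bool(doc["weighted"]),
            weights=weights,
            metadata=doc.get("metadata", {}),
        )

    @classmethod
    def load(cls, path) -> "ScoringModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# -- matrix construction -------------------------------------------------

def build_background(tracks: Sequence[FeatureTrack]) -> BackgroundFrequencies:
    """Character frequencies over the complete substrate corpus.

    The denominator is the total residue count, so the result is a proper
    probability vector (characters never seen get frequency 0).
    """
    if not tracks:
        raise InsufficientDataError("no tracks supplied for background estimation")
    feature = tracks[0].feature
    alphabet = tracks[0].alphabet
    if any(t.feature != feature for t in tracks):
        raise ValueError("all tracks must share one feature")
    counts = {c: 0 for c in alphabet}
    total = 0
    for t in tracks:
        for ch in t.encoded:
            if ch in counts:
                counts[ch] += 1
                total += 1
    if total == 0:
        raise InsufficientDataError("background corpus is empty")
    return BackgroundFrequencies(feature=feature,
                                 freq={c: counts[c] / total for c in alphabet})


def build_pfm(windows: Sequence[str], feature: str) -> PositionFrequencyMatrix:
    """Positional character frequencies over aligned 8-character windows."""
    if not windows:
        raise InsufficientDataError("no windows supplied for PFM construction")
    alphabet = ALPHABETS[feature]
    for w in windows:
        if len(w) != WINDOW_SIZE:
            raise WindowLengthError(f"window {w!r} is not {WINDOW_SIZE} characters")
    counts = np.zeros((len(alphabet), WINDOW_SIZE), dtype=float)
    index = {c: i for i, c in enumerate(alphabet)}
    for w in windows:
        for p, ch in enumerate(w):
            try:
                counts[index[ch], p] += 1
            except KeyError:
                raise WindowLengthError(
                    f"window {w!r} holds character {ch!r} outside the "
                    f"{feature} alphabet") from None
    return PositionFrequencyMatrix(feature=feature, alphabet=alphabet,
                                   matrix=counts / len(windows),
                                   n_windows=len(windows))


def pfm_to_pssm(pfm: PositionFrequencyMatrix,
                bg: BackgroundFrequencies) -> FeaturePSSM:
    """log2 positional enrichment over background, then min-max scaled.

    Cells with a zero positional or background frequency are undefined and
    set to the minimum over the defined cells. A constant raw matrix scales
    to all zeros.
    """
    if pfm.feature != bg.feature:
        raise ValueError("PFM and background feature mismatch")
    bg_vec = np.array([bg.freq[c] for c in pfm.alphabet], dtype=float)
    defined = (pfm.matrix > 0) & (bg_vec[:, None] > 0)
    if not defined.any():
        raise InsufficientDataError("every PSSM cell is undefined")
    raw = np.empty_like(pfm.matrix)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(pfm.matrix / bg_vec[:, None])
    raw[defined] = ratio[defined]
    raw[~defined] = ratio[defined].min()
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        scaled = (raw - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(raw)
    return FeaturePSSM(feature=pfm.feature, alphabet=pfm.alphabet,
                       raw=raw, scaled=scaled)


def build_feature_pssm(windows: Sequence[str], tracks: Sequence[FeatureTrack],
                       feature: str) -> Tuple[FeaturePSSM, BackgroundFrequencies]:
    """Convenience: background + PFM + PSSM for one feature track."""
    bg = build_background(tracks)
    pfm = build_pfm(windows, feature)
    return pfm_to_pssm(pfm, bg), bg


# -- weighting and calibration ------------------------------------------

def lookup_matrix(pssms: Mapping[str, FeaturePSSM],
                  bundles: Sequence[Mapping[str, str]],
                  features: Sequence[str]) -> np.ndarray:
    """Design matrix of per-(feature, position) scaled lookups, one row per bundle."""
    rows = []
    for bundle in bundles:
        row = np.concatenate([pssms[f].lookup(bundle[f]) for f in features])
        rows.append(row)
    return np.asarray(rows)


def fit_weights(windows_pos: Sequence[Mapping[str, str]],
                windows_neg: Sequence[Mapping[str, str]],
                pssms: Mapping[str, FeaturePSSM],
                features: Sequence[str],
                seed: int = 0,
                n_estimators: int = 200) -> Dict[Tuple[str, int], float]:
    """Random-forest importances over (feature, position) lookups, normalised
    to sum to 1. Deterministic for a fixed seed."""
    from sklearn.ensemble import RandomForestClassifier

    if not windows_pos or not windows_neg:
        raise DegenerateTrainingError("weight fitting needs both classes")
    X = np.vstack([
        lookup_matrix(pssms, windows_pos, features),
        lookup_matrix(pssms, windows_neg, features),
    ])
    y = np.concatenate([np.ones(len(windows_pos)), np.zeros(len(windows_neg))])
    forest = RandomForestClassifier(n_estimators=n_estimators, random_state=seed,
                                    n_jobs=1)
    forest.fit(X, y)
    importances = forest.feature_importances_
    total = importances.sum()
    if total <= 0:  # pathological: no split ever used a feature
        importances = np.full_like(importances, 1.0 / importances.size)
    else:
        importances = importances / total
    keys = [(f, p) for f in features for p in range(WINDOW_SIZE)]
    return {k: float(v) for k, v in zip(keys, importances)}


def _confusion_at(scores: np.ndarray, labels: np.ndarray, t: float):
    pred = scores >= t
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    return tp, fp, fn


def calibrate_threshold(scored: Sequence[Tuple[float, int]],
                        criterion: str = "pr_gap") -> float:
    """Sweep candidate thresholds (unique scores plus midpoints) and return
    the optimum under the chosen criterion.

    ``criterion='pr_gap'`` maximises precision(t) − recall(t); ``'f1'``
    maximises the F1 score. Candidates where precision is undefined (no
    predicted positives) are skipped; ties break toward the smaller t.
    """
    if criterion not in ("pr_gap", "f1"):
        raise ValueError(f"unknown criterion {criterion!r}")
    scores = np.array([s for s, _ in scored], dtype=float)
    labels = np.array([l for _, l in scored], dtype=int)
    if len(set(labels.tolist())) < 2:
        raise CalibrationError("threshold calibration needs both classes")
    uniq = np.unique(scores)
    candidates = list(uniq)
    candidates.extend((uniq[:-1] + uniq[1:]) / 2.0)
    candidates = sorted(candidates)
    best_t, best_obj = None, -math.inf
    for t in candidates:
        tp, fp, fn = _confusion_at(scores, labels, t)
        if tp + fp == 0:
            continue
        precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn else float("nan")
        if criterion == "pr_gap":
            obj = precision - recall
        else:
            obj = (2 * precision * recall / (precision + recall)
                   if precision + recall > 0 else 0.0)
        if obj > best_obj + 1e-12:
            best_obj, best_t = obj, t
    if best_t is None:
        raise CalibrationError("no feasible threshold candidate")
    return float(min(1.0, max(0.0, best_t)))
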