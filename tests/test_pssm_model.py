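import math
import random

import numpy as np
import pytest

from lysocleave.encoders import (
    AA_ALPHABET,
    CHARGE_ALPHABET,
    AnnotatedSequence,
    FeatureTrack,
)
from lysocleave.errors import (
    CalibrationError,
    DegenerateTrainingError,
    InsufficientDataError,
    WindowLengthError,
)
from lysocleave.pssm_model import (
    BackgroundFrequencies,
    FeaturePSSM,
    ScoringModel,
    build_background,
    build_pfm,
    calibrate_threshold,
    fit_weights,
    pfm_to_pssm,
)
from tests.conftest import random_protein


def aa_track(encoded):
    return FeatureTrack("aa", AA_ALPHABET, encoded)


def brute_force_raw_pssm(windows, corpus, alphabet):
    """Independent oracle: count, divide, log2, backfill with the minimum."""
    total = sum(len(s) for s in corpus)
    bg = {c: sum(s.count(c) for s in corpus) / total for c in alphabet}
    n = len(windows)
    raw = {}
    defined = []
    for c in alphabet:
        for p in range(8):
            count = sum(1 for w in windows if w[p] == c)
            if count > 0 and bg[c] > 0:
                raw[(c, p)] = math.log2((count / n) / bg[c])
                defined.append(raw[(c, p)])
    fill = min(defined)
    for c in alphabet:
        for p in range(8):
            raw.setdefault((c, p), fill)
    return raw


class TestBackground:
    def test_single_character(self):
        bg = build_background([aa_track("AAAA")])
        assert bg.freq["A"] == 1.0
        assert bg.freq["C"] == 0.0

    def test_hand_counts(self):
        bg = build_background([aa_track("ACDA"), aa_track("CA")])
        assert bg.freq["A"] == pytest.approx(0.5)
        assert bg.freq["C"] == pytest.approx(1 / 3)
        assert bg.freq["D"] == pytest.approx(1 / 6)

    def test_charge_track(self):
        bg = build_background([FeatureTrack("charge", CHARGE_ALPHABET, "-+NN")])
        assert bg.freq["-"] == pytest.approx(0.25)
        assert bg.freq["+"] == pytest.approx(0.25)
        assert bg.freq["N"] == pytest.approx(0.5)

    def test_frequencies_sum_to_one(self, rng):
        tracks = [aa_track(random_protein(rng, 30)) for _ in range(5)]
        bg = build_background(tracks)
        assert sum(bg.freq.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_corpus(self):
        with pytest.raises(InsufficientDataError):
            build_background([])


class TestPFM:
    def test_single_window_is_one_hot(self):
        pfm = build_pfm(["TVVLFKKF"], "aa")
        idx = {c: i for i, c in enumerate(pfm.alphabet)}
        for p, ch in enumerate("TVVLFKKF"):
            assert pfm.matrix[idx[ch], p] == 1.0
        assert pfm.matrix.sum() == pytest.approx(8.0)

    def test_two_windows(self):
        pfm = build_pfm(["AAAAAAAA", "CAAAAAAA"], "aa")
        idx = {c: i for i, c in enumerate(pfm.alphabet)}
        assert pfm.matrix[idx["A"], 0] == 0.5
        assert pfm.matrix[idx["C"], 0] == 0.5
        assert all(pfm.matrix[idx["A"], p] == 1.0 for p in range(1, 8))

    def test_column_sums(self, rng):
        windows = [random_protein(rng, 8) for _ in range(17)]
        pfm = build_pfm(windows, "aa")
        np.testing.assert_allclose(pfm.matrix.sum(axis=0), np.ones(8), atol=1e-9)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            build_pfm([], "aa")
        with pytest.raises(WindowLengthError):
            build_pfm(["SHORT"], "aa")


class TestPSSM:
    def test_flat_pfm_equals_background_gives_zero_scaled(self):
        # every character equally likely everywhere: raw = log2(1) = 0
        windows = [(c * 8) for c in AA_ALPHABET]
        corpus = [aa_track("".join(AA_ALPHABET))]
        bg = build_background(corpus)
        pfm = build_pfm(windows, "aa")
        pssm = pfm_to_pssm(pfm, bg)
        np.testing.assert_allclose(pssm.raw, 0.0, atol=1e-12)
        np.testing.assert_allclose(pssm.scaled, 0.0)  # constant matrix rule

    def test_simple_enrichment(self):
        # bg(A) = 0.25 and pfm[A][P1] = 0.5 -> raw = log2(2) = 1
        corpus = [aa_track("ACDE")]
        windows = ["ACDEACDE", "AADECDEA"]
        bg = build_background(corpus)
        pfm = build_pfm(windows, "aa")
        pssm = pfm_to_pssm(pfm, bg)
        a = pssm.alphabet.index("A")
        assert pfm.matrix[a, 0] == 1.0
        assert pssm.raw[a, 1] == pytest.approx(1.0)  # 0.5 / 0.25

    def test_scaling_is_min_max(self, rng):
        windows = [random_protein(rng, 8) for _ in range(12)]
        corpus = [aa_track(random_protein(rng, 40)) for _ in range(4)]
        pssm = pfm_to_pssm(build_pfm(windows, "aa"), build_background(corpus))
        lo, hi = pssm.raw.min(), pssm.raw.max()
        np.testing.assert_allclose(pssm.scaled, (pssm.raw - lo) / (hi - lo))
        assert pssm.scaled.min() == 0.0
        assert pssm.scaled.max() == 1.0

    def test_scaled_affine_example(self):
        # any raw cell x maps to (x - min)/(max - min); with min -2 and max 3
        # that is (x + 2)/5, so x = 0 lands on 0.4
        raw = np.zeros((20, 8))
        raw[0, 0], raw[1, 0], raw[2, 0] = -2.0, 3.0, 0.0
        scaled = (raw - raw.min()) / (raw.max() - raw.min())
        assert scaled[0, 0] == 0.0
        assert scaled[1, 0] == 1.0
        assert scaled[2, 0] == pytest.approx(0.4)

    def test_oracle_equivalence_micro_corpora(self, rng):
        for _ in range(25):
            corpus_seqs = [random_protein(rng, rng.randint(10, 40))
                           for _ in range(rng.randint(1, 5))]
            windows = [random_protein(rng, 8) for _ in range(rng.randint(1, 20))]
            bg = build_background([aa_track(s) for s in corpus_seqs])
            pssm = pfm_to_pssm(build_pfm(windows, "aa"), bg)
            oracle = brute_force_raw_pssm(windows, corpus_seqs, AA_ALPHABET)
            for i, c in enumerate(pssm.alphabet):
                for p in range(8):
                    assert pssm.raw[i, p] == pytest.approx(oracle[(c, p)], abs=1e-12)
            assert pssm.scaled.min() >= 0.0 and pssm.scaled.max() <= 1.0

    def test_permutation_invariance(self, rng):
        windows = [random_protein(rng, 8) for _ in range(15)]
        shuffled = list(windows)
        rng.shuffle(shuffled)
        a = build_pfm(windows, "aa").matrix
        b = build_pfm(shuffled, "aa").matrix
        np.testing.assert_array_equal(a, b)

    def test_adding_window_increases_p1_frequency(self):
        windows = ["AAAAAAAA"] * 3
        before = build_pfm(windows, "aa")
        after = build_pfm(windows + ["AAACAAAA"], "aa")
        c = before.alphabet.index("C")
        assert after.matrix[c, 3] > before.matrix[c, 3]


def constant_model(value: float, threshold: float = 0.5) -> ScoringModel:
    scaled = np.full((20, 8), value, dtype=float)
    pssm = FeaturePSSM("aa", AA_ALPHABET, raw=scaled.copy(), scaled=scaled)
    bg = BackgroundFrequencies("aa", {c: 1 / 20 for c in AA_ALPHABET})
    return ScoringModel(protease="test", feature_set="aa_only",
                        pssms={"aa": pssm}, backgrounds={"aa": bg},
                        threshold=threshold)


class TestScoring:
    def test_all_lookups_one_gives_final_one(self):
        model = constant_model(1.0)
        seq = AnnotatedSequence("s", "ACDEFGHIKL")
        site = model.score_site(seq, 5)
        assert site.final == pytest.approx(1.0)
        assert site.positive

    def test_half_and_half_mean(self):
        scaled = np.zeros((20, 8))
        scaled[:, :4] = 1.0  # first four window positions score 1, rest 0
        pssm = FeaturePSSM("aa", AA_ALPHABET, raw=scaled.copy(), scaled=scaled)
        bg = BackgroundFrequencies("aa", {c: 1 / 20 for c in AA_ALPHABET})
        model = ScoringModel(protease="t", feature_set="aa_only",
                             pssms={"aa": pssm}, backgrounds={"aa": bg})
        site = model.score_site(AnnotatedSequence("s", "ACDEFGHIKL"), 5)
        assert site.final == pytest.approx(0.5)

    def test_degenerate_weight_on_single_position(self):
        scaled = np.zeros((20, 8))
        scaled[AA_ALPHABET.index("E"), 3] = 0.75  # only (aa, P1) lookup of E
        pssm = FeaturePSSM("aa", AA_ALPHABET, raw=scaled.copy(), scaled=scaled)
        bg = BackgroundFrequencies("aa", {c: 1 / 20 for c in AA_ALPHABET})
        weights = {("aa", p): 0.0 for p in range(8)}
        weights[("aa", 3)] = 1.0
        model = ScoringModel(protease="t", feature_set="aa_only",
                             pssms={"aa": pssm}, backgrounds={"aa": bg},
                             weighted=True, weights=weights)
        # window ACDEFGHI at p1=5 has E at P1
        site = model.score_site(AnnotatedSequence("s", "AACDEFGHIL"), 5)
        assert site.window_aa[3] == "E"
        assert site.final == pytest.approx(0.75)

    def test_scan_counts(self):
        model = constant_model(0.3)
        assert len(model.scan_sequence(AnnotatedSequence("s", "ACDEFGHI"))) == 1
        assert len(model.scan_sequence(AnnotatedSequence("s", "A" * 20))) == 13
        assert model.scan_sequence(AnnotatedSequence("s", "ACDEFGH")) == []

    def test_scan_ascending_and_deterministic(self, rng):
        model = constant_model(0.3)
        seq = AnnotatedSequence("s", random_protein(rng, 50))
        sites = model.scan_sequence(seq)
        assert [s.p1 for s in sites] == list(range(4, 47))
        again = model.scan_sequence(seq)
        assert [(s.p1, s.final) for s in sites] == [(s.p1, s.final) for s in again]

    def test_permissive_windows_skipped(self):
        model = constant_model(0.9)
        seq = AnnotatedSequence("s", "ACDEXGHIKLMNPQRS", permissive=True)
        sites = model.scan_sequence(seq)
        # p1 = 4..8 have X inside their window and are skipped
        assert [s.p1 for s in sites] == list(range(9, 13))

    def test_score_in_unit_interval(self, rng):
        windows = [random_protein(rng, 8) for _ in range(30)]
        corpus = [aa_track(random_protein(rng, 60))]
        pssm = pfm_to_pssm(build_pfm(windows, "aa"), build_background(corpus))
        bg = build_background(corpus)
        model = ScoringModel(protease="t", feature_set="aa_only",
                             pssms={"aa": pssm}, backgrounds={"aa": bg})
        for site in model.scan_sequence(AnnotatedSequence("s", random_protein(rng, 80))):
            assert 0.0 <= site.final <= 1.0
            assert all(0.0 <= v <= 1.0 for v in site.per_feature.values())

    def test_missing_annotation_error(self):
        from lysocleave.errors import MissingAnnotationError

        scaled = np.zeros((3, 8))
        ss_pssm = FeaturePSSM("ss", "CEH", raw=scaled.copy(), scaled=scaled)
        model = constant_model(0.5)
        pssms = dict(model.pssms)
        pssms["ss"] = ss_pssm
        pssms["rsa"] = FeaturePSSM("rsa", "0123456789",
                                   raw=np.zeros((10, 8)), scaled=np.zeros((10, 8)))
        pssms["charge"] = FeaturePSSM("charge", "+N-",
                                      raw=np.zeros((3, 8)), scaled=np.zeros((3, 8)))
        pssms["hydropathy"] = FeaturePSSM("hydropathy", "ζMΦ",
                                          raw=np.zeros((3, 8)), scaled=np.zeros((3, 8)))
        bgs = dict(model.backgrounds)
        for f, alpha in (("ss", "CEH"), ("rsa", "0123456789"),
                         ("charge", "+N-"), ("hydropathy", "ζMΦ")):
            bgs[f] = BackgroundFrequencies(f, {c: 1 / len(alpha) for c in alpha})
        full = ScoringModel(protease="t", feature_set="all", pssms=pssms,
                            backgrounds=bgs)
        with pytest.raises(MissingAnnotationError):
            full.scan_sequence(AnnotatedSequence("s", "ACDEFGHIKL"))


class TestWeights:
    def _separable_fixture(self, rng):
        """Only the (aa, P1) lookup separates the classes."""
        scaled = np.tile(np.linspace(0, 1, 20)[:, None], (1, 8))
        pssm = FeaturePSSM("aa", AA_ALPHABET, raw=scaled.copy(), scaled=scaled)
        # positives have a high-scoring P1 character, negatives a low one;
        # all other positions are the same random noise in both classes
        pos, neg = [], []
        for _ in range(60):
            base = list(random_protein(rng, 8))
            pos_w = list(base)
            neg_w = list(base)
            pos_w[3] = "Y"  # scaled index 19 -> lookup 1.0
            neg_w[3] = "A"  # scaled index 0  -> lookup 0.0
            pos.append({"aa": "".join(pos_w)})
            neg.append({"aa": "".join(neg_w)})
        return pssm, pos, neg

    def test_importance_concentrates_on_informative_position(self, rng):
        pssm, pos, neg = self._separable_fixture(rng)
        weights = fit_weights(pos, neg, {"aa": pssm}, ("aa",), seed=0)
        top = max(weights, key=weights.get)
        assert top == ("aa", 3)
        assert weights[("aa", 3)] > 0.5

    def test_weights_sum_to_one(self, rng):
        pssm, pos, neg = self._separable_fixture(rng)
        weights = fit_weights(pos, neg, {"aa": pssm}, ("aa",), seed=0)
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_for_fixed_seed(self, rng):
        pssm, pos, neg = self._separable_fixture(rng)
        w1 = fit_weights(pos, neg, {"aa": pssm}, ("aa",), seed=3)
        w2 = fit_weights(pos, neg, {"aa": pssm}, ("aa",), seed=3)
        assert w1 == w2

    def test_single_class_error(self, rng):
        pssm, pos, _ = self._separable_fixture(rng)
        with pytest.raises(DegenerateTrainingError):
            fit_weights(pos, [], {"aa": pssm}, ("aa",), seed=0)


def threshold_oracle(scored, criterion):
    """Enumerate every candidate and its objective independently."""
    scores = sorted({s for s, _ in scored})
    candidates = list(scores)
    candidates += [(a + b) / 2 for a, b in zip(scores, scores[1:])]
    best_t, best_obj = None, -math.inf
    for t in sorted(candidates):
        tp = sum(1 for s, y in scored if s >= t and y == 1)
        fp = sum(1 for s, y in scored if s >= t and y == 0)
        fn = sum(1 for s, y in scored if s < t and y == 1)
        if tp + fp == 0:
            continue
        precision = tp / (tp + fp)
        recall = tp / (tp + fn) if tp + fn else float("nan")
        if criterion == "pr_gap":
            obj = precision - recall
        else:
            obj = (2 * precision * recall / (precision + recall)
                   if precision + recall else 0.0)
        if obj > best_obj + 1e-12:
            best_obj, best_t = obj, t
    return best_t


class TestCalibration:
    def test_separable_f1_returns_first_midpoint(self):
        scored = [(0.9, 1)] * 5 + [(0.1, 0)] * 5
        t = calibrate_threshold(scored, criterion="f1")
        assert t == pytest.approx(0.5)  # midpoint of 0.1 and 0.9

    def test_paper_criterion_matches_enumeration(self, rng):
        for _ in range(30):
            scored = [(rng.random(), rng.randint(0, 1)) for _ in range(40)]
            labels = {y for _, y in scored}
            if len(labels) < 2:
                continue
            for criterion in ("pr_gap", "f1"):
                assert calibrate_threshold(scored, criterion) == \
                    pytest.approx(threshold_oracle(scored, criterion))

    def test_threshold_within_score_range(self, rng):
        scored = [(rng.random(), rng.randint(0, 1)) for _ in range(50)]
        if len({y for _, y in scored}) < 2:
            scored += [(0.5, 0), (0.6, 1)]
        for criterion in ("pr_gap", "f1"):
            t = calibrate_threshold(scored, criterion)
            lo = min(s for s, _ in scored)
            hi = max(s for s, _ in scored)
            assert lo <= t <= hi

    def test_single_class_error(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold([(0.4, 1), (0.9, 1)])


class TestSerialization:
    def _model(self, rng):
        windows = [random_protein(rng, 8) for _ in range(20)]
        corpus = [aa_track(random_protein(rng, 50))]
        bg = build_background(corpus)
        pssm = pfm_to_pssm(build_pfm(windows, "aa"), bg)
        return ScoringModel(protease="demo", feature_set="aa_only",
                            pssms={"aa": pssm}, backgrounds={"aa": bg},
                            threshold=0.61,
                            metadata={"n_windows": 20, "seed": 0})

    def test_round_trip_scores_identically(self, rng, tmp_path):
        model = self._model(rng)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = ScoringModel.load(path)
        seq = AnnotatedSequence("s", random_protein(rng, 60))
        original = [(s.p1, s.final) for s in model.scan_sequence(seq)]
        reloaded = [(s.p1, s.final) for s in loaded.scan_sequence(seq)]
        assert original == reloaded

    def test_round_trip_is_byte_stable(self, rng, tmp_path):
        model = self._model(rng)
        first = tmp_path / "a.json"
        second = tmp_path / "b.json"
        model.save(first)
        ScoringModel.load(first).save(second)
        assert first.read_bytes() == second.read_bytes()
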