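"""SiteGA discriminant: LPD feature extraction, Fisher LDA with exact LOO,
and the genetic algorithm over feature sets."""

import math

import numpy as np
import pytest

from tfbsbench.pwm import UnscorableWindowError
from tfbsbench.seqio import encode, reverse_complement
from tfbsbench.simulate import MarkovChain
from tfbsbench.sitega import (
    GAParams,
    LpdFeature,
    evolve_feature_set,
    extract_feature,
    feature_matrix,
    fit_discriminant,
    loo_cc,
    read_sitega,
    score_sitega,
    write_sitega,
    _lda,
)

UNIFORM = MarkovChain(0, np.full(4, 0.25))


def random_seqs(n, width, seed):
    rng = np.random.default_rng(seed)
    return [UNIFORM.generate(width, rng) for _ in range(n)]


class TestExtractFeature:
    def test_hand_count(self):
        # window [0,3) of ACGTA holds dinucleotides AC, CG -> AC freq 1/2
        assert extract_feature("ACGTA", LpdFeature(0, 3, "AC")) == 0.5

    def test_absent_dinucleotide(self):
        assert extract_feature("ACGTA", LpdFeature(0, 5, "TT")) == 0.0

    def test_saturated_window(self):
        assert extract_feature("AAAAA", LpdFeature(0, 5, "AA")) == 1.0

    def test_window_outside_sequence(self):
        with pytest.raises(ValueError, match="outside"):
            extract_feature("ACGT", LpdFeature(2, 6, "AC"))

    def test_feature_matrix_matches_scalar_path(self):
        seqs = random_seqs(20, 15, 0)
        feats = [LpdFeature(0, 5, "AC"), LpdFeature(3, 11, "TT"),
                 LpdFeature(10, 15, "GG")]
        X = feature_matrix(seqs, feats)
        for i, s in enumerate(seqs):
            for k, f in enumerate(feats):
                assert X[i, k] == pytest.approx(extract_feature(s, f))

    def test_invalid_feature_rejected(self):
        with pytest.raises(ValueError):
            LpdFeature(3, 4, "AC")  # window shorter than a dinucleotide
        with pytest.raises(ValueError):
            LpdFeature(0, 4, "AX")


class TestDiscriminant:
    def test_perfectly_separating_feature(self):
        sites = ["AATTAA"] * 10
        background = ["ACGCGC"] * 10
        feats = [LpdFeature(0, 6, "TT")]
        w, b = fit_discriminant(feats, sites, background)
        Xs = feature_matrix(sites, feats) @ w + b
        Xb = feature_matrix(background, feats) @ w + b
        assert (Xs > 0).all() and (Xb < 0).all()

    def test_duplication_preserves_decision(self):
        sites = random_seqs(20, 12, 1)
        background = random_seqs(20, 12, 2)
        feats = [LpdFeature(0, 6, "AA"), LpdFeature(4, 12, "GT")]
        w1, b1 = fit_discriminant(feats, sites, background)
        w2, b2 = fit_discriminant(feats, sites * 2, background * 2)
        cos = w1 @ w2 / (np.linalg.norm(w1) * np.linalg.norm(w2))
        assert cos == pytest.approx(1.0, abs=1e-6)
        X = feature_matrix(sites + background, feats)
        assert np.array_equal(X @ w1 + b1 > 0, X @ w2 + b2 > 0)

    def test_null_distributions_give_no_signal(self):
        feats = [LpdFeature(0, 8, "AC"), LpdFeature(5, 14, "TG"),
                 LpdFeature(10, 20, "GG")]
        ccs = []
        for seed in range(20):
            seqs = random_seqs(60, 20, seed)
            X = feature_matrix(seqs, feats)
            y = np.r_[np.ones(30), np.zeros(30)]
            ccs.append(loo_cc(X, y))
        assert abs(np.mean(ccs)) < 0.2


class TestLooCC:
    def brute_loo_cc(self, X, y, ridge=1e-3):
        """Independent oracle: refit the discriminant without each sample."""
        # fix the ridge scale from the full scatter, as the fast path does
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        S = (X[y == 0] - mu0).T @ (X[y == 0] - mu0) + \
            (X[y == 1] - mu1).T @ (X[y == 1] - mu1)
        lam = ridge * max(np.trace(S) / X.shape[1], 1e-12)
        preds = []
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            Xi, yi = X[keep], y[keep]
            m0, m1 = Xi[yi == 0].mean(0), Xi[yi == 1].mean(0)
            Si = (Xi[yi == 0] - m0).T @ (Xi[yi == 0] - m0) + \
                 (Xi[yi == 1] - m1).T @ (Xi[yi == 1] - m1)
            w = np.linalg.solve(Si + lam * np.eye(X.shape[1]), m1 - m0)
            preds.append(X[i] @ w - w @ (m0 + m1) / 2 > 0)
        preds = np.array(preds)
        tp = np.sum(preds & (y == 1)); fn = np.sum(~preds & (y == 1))
        fp = np.sum(preds & (y == 0)); tn = np.sum(~preds & (y == 0))
        d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        return (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_refits(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((60, 5))
        y = np.r_[np.ones(30), np.zeros(30)]
        X[y == 1] += rng.normal(0.1, 0.05, size=(30, 5))
        assert loo_cc(X, y) == pytest.approx(self.brute_loo_cc(X, y))

    def test_requires_minimum_class_sizes(self):
        X = np.random.default_rng(0).random((4, 2))
        with pytest.raises(ValueError):
            loo_cc(X, np.array([1, 1, 0, 0]))


class TestGeneticAlgorithm:
    def planted_data(self, seed, n=60, width=20):
        """Sites carry TT at positions 6-7 with probability 0.9."""
        rng = np.random.default_rng(seed)
        sites = []
        for _ in range(n):
            s = list(UNIFORM.generate(width, rng))
            if rng.random() < 0.9:
                s[6:8] = "TT"
            sites.append("".join(s))
        background = [UNIFORM.generate(width, rng) for _ in range(n)]
        return sites, background

    def test_planted_window_recovered(self):
        hits = 0
        for seed in range(10):
            sites, background = self.planted_data(seed)
            model = evolve_feature_set(
                sites, background, K=5,
                ga_params=GAParams(population=20, generations=15), seed=seed)
            if any(f.dinuc == "TT" and f.start < 8 and f.end > 6
                   for f in model.features):
                hits += 1
        assert hits >= 8

    def test_zero_generations_returns_best_initial(self):
        sites, background = self.planted_data(3)
        model = evolve_feature_set(
            sites, background, K=4,
            ga_params=GAParams(population=15, generations=0), seed=4)
        assert len(model.fitness_trace) == 1
        assert model.fitness == model.fitness_trace[0]

    def test_best_ever_fitness_nondecreasing(self):
        sites, background = self.planted_data(5)
        model = evolve_feature_set(
            sites, background, K=4,
            ga_params=GAParams(population=15, generations=10), seed=6)
        trace = model.fitness_trace
        assert all(a <= b for a, b in zip(trace, trace[1:]))
        assert model.fitness == trace[-1] >= trace[0]

    def test_too_many_features_rejected(self):
        sites = random_seqs(10, 4, 7)
        background = random_seqs(10, 4, 8)
        with pytest.raises(ValueError, match="possible features"):
            evolve_feature_set(sites, background, K=10_000,
                               ga_params=GAParams(population=5, generations=0))

    def test_deterministic_under_seed(self):
        sites, background = self.planted_data(8, n=30)
        kw = dict(K=4, ga_params=GAParams(population=10, generations=5))
        a = evolve_feature_set(sites, background, seed=9, **kw)
        b = evolve_feature_set(sites, background, seed=9, **kw)
        assert a.features == b.features and a.fitness == b.fitness


@pytest.fixture(scope="module")
def scoring_model():
    rng = np.random.default_rng(10)
    sites = ["".join(rng.choice(list("ACGT"), size=16)) for _ in range(40)]
    background = ["".join(rng.choice(list("ACGT"), size=16))
                  for _ in range(40)]
    return evolve_feature_set(
        sites, background, K=4,
        ga_params=GAParams(population=10, generations=5), seed=11)


class TestScoreSitega:
    @pytest.fixture
    def model(self, scoring_model):
        return scoring_model

    def test_feature_by_feature_oracle(self, model):
        rng = np.random.default_rng(12)
        for _ in range(10):
            w = "".join(rng.choice(list("ACGT"), size=model.width))
            raw = sum(wt * extract_feature(w, f)
                      for wt, f in zip(model.weights, model.features)) \
                + model.intercept
            expected = np.clip((raw - model.s_min) /
                               (model.s_max - model.s_min), 0, 1)
            assert score_sitega(model, w) == pytest.approx(float(expected))

    def test_strand_symmetry(self, model):
        rng = np.random.default_rng(13)
        w = "".join(rng.choice(list("ACGT"), size=model.width))
        assert score_sitega(model, w, "-") == pytest.approx(
            score_sitega(model, reverse_complement(w)))

    def test_scores_clamped_to_unit_interval(self, model):
        rng = np.random.default_rng(14)
        codes = rng.integers(0, 4, size=(200, model.width))
        s = model.score_windows(codes)
        assert s.min() >= 0 and s.max() <= 1

    def test_ambiguous_base_unscorable(self, model):
        with pytest.raises(UnscorableWindowError):
            score_sitega(model, "N" * model.width)

    def test_serialization_roundtrip(self, model, tmp_path):
        write_sitega(model, tmp_path / "m.txt")
        back = read_sitega(tmp_path / "m.txt")
        rng = np.random.default_rng(15)
        codes = rng.integers(0, 4, size=(50, model.width))
        assert np.allclose(model.score_windows(codes),
                           back.score_windows(codes))
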