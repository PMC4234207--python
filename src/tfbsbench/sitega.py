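"""SiteGA-style binding-site model.

A window is scored by a Fisher linear discriminant over *locally positioned
dinucleotide frequencies* (LPD features): the frequency of one dinucleotide
inside one sub-window of the site.  The feature set is selected by a
genetic algorithm whose fitness is the leave-one-out correlation
coefficient of the discriminant separating training sites from background
sequences.  This family of features lets the model pick up dependencies
between distant site positions that additive PWMs cannot represent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pwm import DINUCLEOTIDES
from .seqio import encode, reverse_complement

__all__ = [
    "LpdFeature",
    "SiteGAModel",
    "GAParams",
    "extract_feature",
    "fit_discriminant",
    "evolve_feature_set",
    "score_sitega",
    "write_sitega",
    "read_sitega",
    "loo_cc",
]

logger = logging.getLogger(__name__)

_DINUC_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


@dataclass(frozen=True)
class LpdFeature:
    """Frequency of `dinuc` within the half-open window [start, end).

    The value is the count of the dinucleotide at positions
    start..end-2 divided by (end - start - 1), hence in [0, 1].
    """

    start: int
    end: int
    dinuc: str

    def __post_init__(self) -> None:
        if self.end - self.start < 2:
            raise ValueError("feature window must span >= 2 positions")
        if self.start < 0:
            raise ValueError("feature window start must be >= 0")
        if self.dinuc not in _DINUC_INDEX:
            raise ValueError(f"unknown dinucleotide {self.dinuc!r}")


def extract_feature(seq: str, feature: LpdFeature) -> float:
    """Windowed dinucleotide frequency of one sequence."""
    if feature.end > len(seq):
        raise ValueError("feature window outside sequence")
    window = seq[feature.start:feature.end]
    count = sum(
        window[i:i + 2] == feature.dinuc for i in range(len(window) - 1)
    )
    return count / (feature.end - feature.start - 1)


def _dicode_cumsum(seqs: Sequence[str]) -> np.ndarray:
    """(n, 16, W) tensor: CS[i, d, p] = # of dinucleotide d starting before
    position p in sequence i.  Ambiguous-letter pairs count for nothing."""
    n = len(seqs)
    W = len(seqs[0])
    cs = np.zeros((n, 16, W), dtype=np.float64)
    for i, s in enumerate(seqs):
        codes = encode(s)
        di = codes[:-1] * 4 + codes[1:]
        ok = (codes[:-1] < 4) & (codes[1:] < 4)
        onehot = np.zeros((16, W - 1))
        onehot[di[ok], np.nonzero(ok)[0]] = 1.0
        cs[i, :, 1:] = np.cumsum(onehot, axis=1)
    return cs


def _feature_matrix_from_cs(cs: np.ndarray, features: Sequence[LpdFeature]) -> np.ndarray:
    cols = []
    for f in features:
        d = _DINUC_INDEX[f.dinuc]
        cols.append((cs[:, d, f.end - 1] - cs[:, d, f.start]) / (f.end - f.start - 1))
    return np.stack(cols, axis=1)


def feature_matrix(seqs: Sequence[str], features: Sequence[LpdFeature]) -> np.ndarray:
    """(n, K) matrix of LPD feature values."""
    return _feature_matrix_from_cs(_dicode_cumsum(seqs), features)


# ---------------------------------------------------------------------------
# Fisher linear discriminant with exact leave-one-out scoring
# ---------------------------------------------------------------------------

def _lda(X: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, float, float]:
    """Fisher LDA: w ~ (S + lam*I)^-1 (mu1 - mu0), intercept at the midpoint
    of projected class means, oriented so the positive class projects
    higher.  Returns (w, intercept, lam_used)."""
    X0, X1 = X[y == 0], X[y == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("need at least 2 sequences per class")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    K = X.shape[1]
    scale = max(np.trace(S) / K, 1e-12)
    lam = ridge * scale
    d = mu1 - mu0
    for _ in range(8):
        A = S + lam * np.eye(K)
        try:
            w = np.linalg.solve(A, d)
            if np.isfinite(w).all():
                break
        except np.linalg.LinAlgError:
            pass
        lam = max(lam * 100, 1e-10 * scale)
        logger.info("singular pooled scatter; raising ridge to %g", lam)
    intercept = -float(w @ (mu0 + mu1) / 2)
    if w @ d < 0:  # orientation guard (cannot trigger for SPD A)
        w, intercept = -w, -intercept
    return w, intercept, lam


def fit_discriminant(
    features: Sequence[LpdFeature],
    site_seqs: Sequence[str],
    background_seqs: Sequence[str],
    ridge: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Fit the Fisher discriminant on LPD features; returns (weights,
    intercept) with sites projecting higher than background."""
    X = feature_matrix(list(site_seqs) + list(background_seqs), features)
    y = np.r_[np.ones(len(site_seqs)), np.zeros(len(background_seqs))]
    w, b, _ = _lda(X, y, ridge)
    return w, b


def _mcc(tp: float, fn: float, fp: float, tn: float) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def loo_cc(X: np.ndarray, y: np.ndarray, ridge: float = 1e-3) -> float:
    """Exact leave-one-out correlation coefficient of the Fisher LDA.

    Each sample is scored by the discriminant trained without it; the
    refits are computed in closed form with Sherman-Morrison downdates of
    the regularized pooled scatter, so the cost is O(n K^2) overall.
    """
    y = np.asarray(y)
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 3 or n1 < 3:
        raise ValueError("need at least 3 samples per class for LOO")
    mu0 = X[y == 0].mean(axis=0)
    mu1 = X[y == 1].mean(axis=0)
    mu = np.where((y == 1)[:, None], mu1, mu0)
    U = X - mu
    S = U[y == 0].T @ U[y == 0] + U[y == 1].T @ U[y == 1]
    K = X.shape[1]
    scale = max(np.trace(S) / K, 1e-12)
    lam = ridge * scale
    A = S + lam * np.eye(K)
    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        Ainv = np.linalg.inv(S + (lam * 1e4 + 1e-8 * scale) * np.eye(K))

    d = mu1 - mu0
    m = (mu0 + mu1) / 2
    nc = np.where(y == 1, n1, n0).astype(float)
    c = nc / (nc - 1)
    e = np.where(y == 1, -1.0 / (n1 - 1), 1.0 / (n0 - 1))

    G = U @ Ainv                      # rows a_i = Ainv @ u_i
    s = np.einsum("ij,ij->i", U, G)   # u_i' Ainv u_i
    delta = np.maximum(1.0 - c * s, 1e-12)
    g = Ainv @ d
    Z = X - m + U * (1.0 / (2 * (nc - 1)))[:, None]
    gz = Z @ g
    az = np.einsum("ij,ij->i", G, Z)
    ad = G @ d
    # t_i = (Ainv d_i)'z_i + c_i (a_i'd_i)(a_i'z_i)/delta_i,  d_i = d + e_i u_i
    t = gz + e * az + c * (ad + e * s) * az / delta

    pred = t > 0
    tp = float(np.sum(pred & (y == 1)))
    fn = float(np.sum(~pred & (y == 1)))
    fp = float(np.sum(pred & (y == 0)))
    tn = float(np.sum(~pred & (y == 0)))
    return _mcc(tp, fn, fp, tn)


# ---------------------------------------------------------------------------
# Genetic algorithm over feature sets
# ---------------------------------------------------------------------------

@dataclass
class GAParams:
    """Genetic-algorithm hyperparameters (desk-scale defaults)."""

    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.7
    mutation_rate: float = 0.1
    elitism: int = 2
    tournament: int = 3
    min_window: int = 2
    max_window: int = 8
    ridge: float = 1e-3


@dataclass
class SiteGAModel:
    """Trained SiteGA model: K LPD features + linear discriminant, with a
    min-max rescaling of the training-time score range (5% margin each
    side, clamped to [0, 1])."""

    width: int
    features: list[LpdFeature]
    weights: np.ndarray
    intercept: float
    s_min: float
    s_max: float
    fitness: float = float("nan")
    fitness_trace: list[float] = field(default_factory=list)
    model_id: str = "sitega"

    def raw_score_seqs(self, seqs: Sequence[str]) -> np.ndarray:
        X = feature_matrix(seqs, self.features)
        return X @ self.weights + self.intercept

    def score_windows(self, codes: np.ndarray) -> np.ndarray:
        """Rescaled [0,1] scores for (n, width) ACGT code windows."""
        n, W = codes.shape
        di = codes[:, :-1] * 4 + codes[:, 1:]
        X = np.empty((n, len(self.features)))
        for k, f in enumerate(self.features):
            seg = di[:, f.start:f.end - 1]
            X[:, k] = (seg == _DINUC_INDEX[f.dinuc]).sum(axis=1) / (f.end - f.start - 1)
        raw = X @ self.weights + self.intercept
        return np.clip((raw - self.s_min) / (self.s_max - self.s_min), 0.0, 1.0)


def _random_feature(rng: np.random.Generator, width: int, p: GAParams) -> LpdFeature:
    wlen = int(rng.integers(p.min_window, min(p.max_window, width) + 1))
    start = int(rng.integers(0, width - wlen + 1))
    return LpdFeature(start, start + wlen, DINUCLEOTIDES[rng.integers(0, 16)])


def _mutate_feature(f: LpdFeature, rng: np.random.Generator, width: int,
                    p: GAParams) -> LpdFeature:
    if rng.random() < 0.5:  # jitter window bounds by +-2
        start = int(np.clip(f.start + rng.integers(-2, 3), 0, width - p.min_window))
        end = int(np.clip(f.end + rng.integers(-2, 3),
                          start + p.min_window, min(start + p.max_window, width)))
        return LpdFeature(start, end, f.dinuc)
    return LpdFeature(f.start, f.end, DINUCLEOTIDES[rng.integers(0, 16)])


def _repair(feats: list[LpdFeature], rng: np.random.Generator, width: int,
            p: GAParams) -> tuple[LpdFeature, ...]:
    seen = set()
    out = []
    for f in feats:
        while f in seen:
            f = _random_feature(rng, width, p)
        seen.add(f)
        out.append(f)
    return tuple(sorted(out, key=lambda f: (f.start, f.end, f.dinuc)))


def evolve_feature_set(
    site_seqs: Sequence[str],
    background_seqs: Sequence[str],
    K: int = 20,
    ga_params: GAParams | None = None,
    seed: int | np.random.Generator = 0,
) -> SiteGAModel:
    """Select K LPD features by a genetic algorithm and fit the final model.

    Individuals are K-sets of features; fitness is the leave-one-out CC of
    the Fisher discriminant separating sites from background.  Crossover is
    a uniform feature exchange, mutation re-draws window bounds (+-2) or
    the dinucleotide, duplicates are repaired by re-draw, and the best
    individual ever seen is returned (elitism keeps it in the population).
    """
    p = ga_params or GAParams()
    width = len(site_seqs[0])
    if any(len(s) != width for s in site_seqs):
        raise ValueError("site sequences must share one width")
    n_possible = 16 * sum(width - w + 1 for w in
                          range(p.min_window, min(p.max_window, width) + 1))
    if K > n_possible:
        raise ValueError(f"K={K} exceeds the {n_possible} possible features")
    rng = np.random.default_rng(seed)

    seqs = list(site_seqs) + list(background_seqs)
    y = np.r_[np.ones(len(site_seqs)), np.zeros(len(background_seqs))]
    cs = _dicode_cumsum(seqs)

    cache: dict[tuple[LpdFeature, ...], float] = {}

    def fitness(ind: tuple[LpdFeature, ...]) -> float:
        if ind not in cache:
            X = _feature_matrix_from_cs(cs, ind)
            cache[ind] = loo_cc(X, y, p.ridge)
        return cache[ind]

    pop = [_repair([_random_feature(rng, width, p) for _ in range(K)],
                   rng, width, p) for _ in range(p.population)]
    best_ind, best_fit = None, -np.inf
    trace: list[float] = []

    def tournament() -> tuple[LpdFeature, ...]:
        picks = [pop[rng.integers(0, len(pop))] for _ in range(p.tournament)]
        return max(picks, key=fitness)

    for gen in range(p.generations + 1):
        for ind in pop:
            f = fitness(ind)
            if f > best_fit:
                best_ind, best_fit = ind, f
        trace.append(best_fit)
        if gen == p.generations:
            break
        ranked = sorted(pop, key=fitness, reverse=True)
        nxt = ranked[:p.elitism]
        while len(nxt) < p.population:
            pa, pb = tournament(), tournament()
            if rng.random() < p.crossover_rate:
                mask = rng.random(K) < 0.5
                child = [pa[i] if mask[i] else pb[i] for i in range(K)]
            else:
                child = list(pa)
            child = [
                _mutate_feature(f, rng, width, p) if rng.random() < p.mutation_rate
                else f
                for f in child
            ]
            nxt.append(_repair(child, rng, width, p))
        pop = nxt

    features = list(best_ind)
    X = _feature_matrix_from_cs(cs, best_ind)
    w, b, _ = _lda(X, y, p.ridge)
    raw = X @ w + b
    lo, hi = float(raw.min()), float(raw.max())
    margin = 0.05 * (hi - lo)
    return SiteGAModel(
        width=width, features=features, weights=w, intercept=b,
        s_min=lo - margin, s_max=hi + margin,
        fitness=best_fit, fitness_trace=trace,
    )


def score_sitega(model: SiteGAModel, window: str, strand: str = "+") -> float:
    """Rescaled [0, 1] score of one window; '-' scores the reverse
    complement.  Ambiguous letters make the window unscorable."""
    from .pwm import UnscorableWindowError

    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    if len(window) != model.width:
        raise ValueError("window length != model width")
    codes = encode(window)
    if (codes > 3).any():
        raise UnscorableWindowError(f"ambiguous base in window {window!r}")
    return float(model.score_windows(codes[None, :])[0])


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------

def write_sitega(model: SiteGAModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#sitega width {model.width} K {len(model.features)}\n")
        for f, w in zip(model.features, model.weights):
            fh.write(f"{f.start} {f.end} {f.dinuc} {w:.12g}\n")
        fh.write(f"intercept {model.intercept:.12g}\n")
        fh.write(f"s_min {model.s_min:.12g}\n")
        fh.write(f"s_max {model.s_max:.12g}\n")


def read_sitega(path: str | Path) -> SiteGAModel:
    with open(path) as fh:
        header = fh.readline().split()
        if header[:1] != ["#sitega"]:
            raise ValueError(f"{path}: not a SiteGA model file")
        width = int(header[header.index("width") + 1])
        K = int(header[header.index("K") + 1])
        features, weights = [], []
        for _ in range(K):
            s, e, d, w = fh.readline().split()
            features.append(LpdFeature(int(s), int(e), d))
            weights.append(float(w))
        intercept = float(fh.readline().split()[1])
        s_min = float(fh.readline().split()[1])
        s_max = float(fh.readline().split()[1])
    return SiteGAModel(width, features, np.array(weights), intercept,
                       s_min, s_max)
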