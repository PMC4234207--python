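"""Model evaluation and comparison.

Markov-shuffled background construction (per-peak chains, length
preserved), peak-level ROC curves and AUC, the Matthews correlation
coefficient at a calibrated threshold, pairwise model-combination
categories (overlapping / single-model / non-overlapping detections), and
the chi-square test comparing the observed fraction of jointly detected
peaks with non-overlapping sites against its tenfold-shuffle expectation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .scan import ScanHit, hits_overlap, scan_peak
from .seqio import Peak
from .simulate import fit_markov

__all__ = [
    "ConfusionCounts",
    "CombinationSummary",
    "ChanceOverlapResult",
    "make_shuffled_background",
    "roc_curve",
    "roc_from_scores",
    "correlation_coefficient",
    "combination_analysis",
    "chance_overlap_test",
    "chi2_2x2",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN over real peaks recognized/missed; FP/TN over shuffled peaks."""

    TP: int
    FN: int
    FP: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.FP, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


def make_shuffled_background(
    peaks: Sequence[Peak],
    order: int = 1,
    n_fold: int = 10,
    seed: int = 0,
) -> list[list[Peak]]:
    """Per fold, per peak: one same-length sequence from a Markov chain
    fitted to that peak alone (length and composition preserved)."""
    if order not in (0, 1):
        raise ValueError(f"unsupported order {order}")
    if n_fold < 1:
        raise ValueError("n_fold must be >= 1")
    for p in peaks:
        if len(p.seq) < order + 1:
            raise ValueError(f"peak {p.id} shorter than order+1")
    chains = [fit_markov([p.seq], order) for p in peaks]
    rng = np.random.default_rng(seed)
    folds = []
    for f in range(n_fold):
        fold = [
            Peak(id=f"{p.id}_shuf{f}", seq=chain.generate(len(p.seq), rng),
                 height=p.height)
            for p, chain in zip(peaks, chains)
        ]
        folds.append(fold)
    return folds


def roc_from_scores(real_scores: np.ndarray,
                    bg_scores: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC from per-peak best scores: sweep thresholds over the union of
    observed scores; each point is (FP rate, TP rate) with 'recognized'
    meaning score >= threshold.  AUC by the trapezoid rule."""
    real = np.asarray(real_scores, dtype=float)
    bg = np.asarray(bg_scores, dtype=float)
    if real.size == 0 or bg.size == 0:
        raise ValueError("both score sets must be non-empty")
    thresholds = np.unique(np.concatenate([real[~np.isnan(real)],
                                           bg[~np.isnan(bg)]]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float(np.mean(real >= t))
        fpr = float(np.mean(bg >= t))
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    pts = np.array(sorted(set(pts)))
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


def roc_curve(real_peaks: Sequence[Peak], background_peaks: Sequence[Peak],
              model) -> tuple[np.ndarray, float]:
    """Peak-level ROC: TP rate = fraction of recognized real peaks, FP rate
    = fraction of recognized shuffled peaks, swept over best-score
    thresholds."""
    from .scan import best_scores

    return roc_from_scores(best_scores(real_peaks, model),
                           best_scores(background_peaks, model))


def correlation_coefficient(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; zero marginals yield a flagged 0."""
    tp, fn, fp, tn = counts.TP, counts.FN, counts.FP, counts.TN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("zero marginal in confusion table; CC undefined, "
                      "returning 0")
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


@dataclass
class CombinationSummary:
    """Pairwise model-combination categories over a peak set.

    a: peaks with >= 1 cross-model overlapping hit pair; b/c: peaks with
    hits from only model 1 / only model 2; d: hits from both models but no
    overlapping pair; neither: no hits at all.  `cluster_fraction` is the
    fraction of detected peaks carrying >= 2 distinct sites (cross-model
    overlapping predictions merged into one site).
    """

    a: int
    b: int
    c: int
    d: int
    neither: int
    n_sites_model_1: int
    n_sites_model_2: int
    cluster_fraction: float
    per_peak_sites: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d + self.neither


def _merged_site_count(h1: list[ScanHit], h2: list[ScanHit],
                       L1: int, L2: int) -> int:
    """Count distinct sites: connected components of the cross-model hit
    overlap graph (same-model hits never overlap after pruning)."""
    nodes = [(h, L1) for h in h1] + [(h, L2) for h in h2]
    n = len(nodes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(h1)):
        for j in range(len(h1), n):
            if hits_overlap(nodes[i][0], nodes[j][0], nodes[i][1], nodes[j][1]):
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def combination_analysis(
    peaks: Sequence[Peak],
    hits_model_1: Sequence[ScanHit],
    hits_model_2: Sequence[ScanHit],
    model_len_1: int | None = None,
    model_len_2: int | None = None,
) -> CombinationSummary:
    """Assign every peak to exactly one category (a takes precedence over d
    whenever any cross-model overlapping pair exists)."""
    ids = {p.id for p in peaks}
    for h in list(hits_model_1) + list(hits_model_2):
        if h.peak_id not in ids:
            raise ValueError(f"hit references unknown peak {h.peak_id!r}")
    L1 = model_len_1
    L2 = model_len_2
    by1: dict[str, list[ScanHit]] = {}
    by2: dict[str, list[ScanHit]] = {}
    for h in hits_model_1:
        by1.setdefault(h.peak_id, []).append(h)
    for h in hits_model_2:
        by2.setdefault(h.peak_id, []).append(h)

    a = b = c = d = neither = 0
    per_peak_sites: dict[str, int] = {}
    detected_multi = detected = 0
    for p in peaks:
        h1, h2 = by1.get(p.id, []), by2.get(p.id, [])
        if not h1 and not h2:
            neither += 1
            continue
        if h1 and not h2:
            b += 1
        elif h2 and not h1:
            c += 1
        else:
            overlap = any(
                hits_overlap(x, y, L1, L2) for x in h1 for y in h2
            )
            if overlap:
                a += 1
            else:
                d += 1
        n_sites = _merged_site_count(h1, h2, L1, L2)
        per_peak_sites[p.id] = n_sites
        detected += 1
        if n_sites >= 2:
            detected_multi += 1
    return CombinationSummary(
        a=a, b=b, c=c, d=d, neither=neither,
        n_sites_model_1=len(list(hits_model_1)),
        n_sites_model_2=len(list(hits_model_2)),
        cluster_fraction=detected_multi / detected if detected else float("nan"),
        per_peak_sites=per_peak_sites,
    )


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Chi-square test on a 2x2 contingency table, 1 df, no continuity
    correction; a zero marginal yields (0, 1)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, 1.0
    chi2, p, _, _ = chi2_contingency(table, correction=False)
    return float(chi2), float(p)


@dataclass
class ChanceOverlapResult:
    observed_frac: float
    expected_frac: float
    chi2: float
    p: float
    table: np.ndarray  # [[d_real, a_real], [d_shuf, a_shuf]]
    defined: bool = True


def _scan_pair(peaks: Sequence[Peak], model_1, model_2,
               thr_1: float, thr_2: float) -> tuple[list[ScanHit], list[ScanHit]]:
    h1: list[ScanHit] = []
    h2: list[ScanHit] = []
    for p in peaks:
        h1.extend(scan_peak(model_1, p, threshold=thr_1).hits)
        h2.extend(scan_peak(model_2, p, threshold=thr_2).hits)
    return h1, h2


def chance_overlap_test(
    peaks: Sequence[Peak],
    model_1,
    model_2,
    thresholds: tuple[float, float],
    n_fold: int = 10,
    seed: int = 0,
) -> ChanceOverlapResult:
    """Observed vs shuffle-expected fraction of jointly detected peaks with
    only non-overlapping sites, d/(a+d).

    Expected counts pool all folds of per-peak order-1 Markov shuffles;
    the chi-square uses the raw 2x2 table [[d, a], [d', a']] with 1 df and
    no continuity correction.
    """
    thr_1, thr_2 = thresholds
    h1, h2 = _scan_pair(peaks, model_1, model_2, thr_1, thr_2)
    obs = combination_analysis(peaks, h1, h2, model_1.width, model_2.width)

    folds = make_shuffled_background(peaks, order=1, n_fold=n_fold, seed=seed)
    d_shuf = a_shuf = 0
    for fold in folds:
        g1, g2 = _scan_pair(fold, model_1, model_2, thr_1, thr_2)
        s = combination_analysis(fold, g1, g2, model_1.width, model_2.width)
        d_shuf += s.d
        a_shuf += s.a
    table = np.array([[obs.d, obs.a], [d_shuf, a_shuf]], dtype=float)
    if obs.a + obs.d == 0 or a_shuf + d_shuf == 0:
        warnings.warn("no peaks detected by both models in one of the sets; "
                      "chance-overlap test undefined")
        return ChanceOverlapResult(float("nan"), float("nan"), float("nan"),
                                   float("nan"), table, defined=False)
    observed = obs.d / (obs.a + obs.d)
    expected = d_shuf / (a_shuf + d_shuf)
    chi2, p = chi2_2x2(table)
    return ChanceOverlapResult(observed, expected, float(chi2), float(p), table)
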