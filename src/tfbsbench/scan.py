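"""Apply trained models to peak sets.

Both-strand sliding-window scoring, hit extraction at a threshold (strict
inequality: the calibrated threshold value itself belongs to a non-site),
greedy non-overlap pruning of same-model hits, per-peak summaries, and
hit-overlap utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import Peak, encode

__all__ = [
    "ScanHit",
    "ScanResult",
    "scan_peak",
    "recognized_fraction",
    "best_scores",
    "hits_overlap",
    "write_hits_bed",
    "write_hits_tsv",
]

_RC = np.array([3, 2, 1, 0, 4], dtype=np.int8)


@dataclass(frozen=True)
class ScanHit:
    peak_id: str
    start: int
    strand: str
    model_id: str
    score: float


@dataclass
class ScanResult:
    """Full scan of one peak: per-start window scores on both strands
    (NaN where the window is unscorable), the best score over the whole
    locus, and threshold-passing hits after non-overlap pruning."""

    peak_id: str
    width: int
    scores_fwd: np.ndarray
    scores_rev: np.ndarray
    best_score: float  # NaN when no window is scorable
    hits: list[ScanHit] = field(default_factory=list)
    too_short: bool = False


def _prune_hits(raw: list[tuple[float, int, str]], L: int,
                peak_id: str, model_id: str) -> list[ScanHit]:
    """Greedy best-score-first pruning so same-model hits never overlap.
    Ties break to the leftmost start, then '+' strand."""
    order = sorted(raw, key=lambda h: (-h[0], h[1], 0 if h[2] == "+" else 1))
    taken: list[tuple[int, int]] = []
    hits = []
    for score, start, strand in order:
        if all(start + L <= s or e <= start for s, e in taken):
            taken.append((start, start + L))
            hits.append(ScanHit(peak_id, start, strand, model_id, float(score)))
    hits.sort(key=lambda h: h.start)
    return hits


def scan_peak(model, peak: Peak, threshold: float | None = None,
              prune: bool = True) -> ScanResult:
    """Score every ACGT-only window of the peak on both strands.

    When `threshold` is given, hits are windows with score strictly above
    it; overlapping same-model hits are pruned greedily best-score-first.
    A peak shorter than the model yields an empty, flagged result.
    """
    L = model.width
    mid = getattr(model, "model_id", "model")
    if len(peak.seq) < L:
        empty = np.empty(0)
        return ScanResult(peak.id, L, empty, empty, float("nan"),
                          too_short=True)
    codes = encode(peak.seq)
    fwd = np.lib.stride_tricks.sliding_window_view(codes, L)
    rc = _RC[codes][::-1]
    rev = np.lib.stride_tricks.sliding_window_view(rc, L)[::-1]

    def strand_scores(wins: np.ndarray) -> np.ndarray:
        out = np.full(wins.shape[0], np.nan)
        ok = (wins < 4).all(axis=1)
        if ok.any():
            out[ok] = model.score_windows(wins[ok].astype(np.int64))
        return out

    sf, sr = strand_scores(fwd), strand_scores(rev)
    stacked = np.concatenate([sf, sr])
    best = float(np.nanmax(stacked)) if not np.all(np.isnan(stacked)) else float("nan")

    hits: list[ScanHit] = []
    if threshold is not None:
        raw = [(float(s), int(p), "+") for p, s in enumerate(sf)
               if s > threshold] + \
              [(float(s), int(p), "-") for p, s in enumerate(sr)
               if s > threshold]
        hits = _prune_hits(raw, L, peak.id, mid) if prune else [
            ScanHit(peak.id, p, st, mid, s) for s, p, st in
            sorted(raw, key=lambda h: h[1])
        ]
    return ScanResult(peak.id, L, sf, sr, best, hits)


def best_scores(peaks: Sequence[Peak], model) -> np.ndarray:
    """Best full-scan score per peak (NaN for unscorable peaks)."""
    return np.array([scan_peak(model, p).best_score for p in peaks])


def recognized_fraction(peaks: Sequence[Peak], model, threshold: float) -> float:
    """Fraction of peaks with at least one hit strictly above threshold."""
    if not peaks:
        raise ValueError("empty peak set")
    bests = best_scores(peaks, model)
    return float(np.mean(bests > threshold))  # NaN > t is False


def hits_overlap(hit_a: ScanHit, hit_b: ScanHit,
                 model_len_a: int, model_len_b: int) -> bool:
    """True iff the two hits share >= 1 bp (half-open, strand-agnostic)."""
    if hit_a.peak_id != hit_b.peak_id:
        raise ValueError("hits on different peaks cannot overlap")
    return hit_a.start < hit_b.start + model_len_b and \
        hit_b.start < hit_a.start + model_len_a


def write_hits_bed(hits: Sequence[ScanHit], L: int, path: str | Path) -> None:
    """BED6: name=model_id, score=rescaled*1000 as an integer."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.peak_id}\t{h.start}\t{h.start + L}\t{h.model_id}\t"
                     f"{int(round(h.score * 1000))}\t{h.strand}\n")


def write_hits_tsv(hits: Sequence[ScanHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tstart\tstrand\tmodel_id\tscore\n")
        for h in hits:
            fh.write(f"{h.peak_id}\t{h.start}\t{h.strand}\t{h.model_id}\t"
                     f"{h.score:.10g}\n")
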