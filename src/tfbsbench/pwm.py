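"""Position weight matrix models trained on curated site alignments.

Mononucleotide PWMs (with leave-one-out matrix-length optimization, the
"optimized PWM") and dinucleotide PWMs over the 16-letter adjacent-pair
alphabet.  Raw log-odds scores are min-max rescaled to a common [0, 1]
scale so models of different kinds share a threshold axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import Peak, encode, reverse_complement

__all__ = [
    "AlignedSiteSet",
    "MonoPWM",
    "DiPWM",
    "UnscorableWindowError",
    "build_mono_pwm",
    "build_di_pwm",
    "score_window",
    "rescale_score",
    "optimize_length",
    "write_matrix",
    "read_matrix",
    "DINUCLEOTIDES",
]

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]


class UnscorableWindowError(ValueError):
    """Window contains a letter outside ACGT; scanners skip such windows."""


@dataclass
class AlignedSiteSet:
    """Fixed-width alignment of confirmed binding sites.

    ``core_offset``/``core_len`` locate the degenerate core pattern the
    sites were anchored on (e.g. TRTTTRYH for FoxA).
    """

    seqs: list[str]
    core_offset: int = 0
    core_len: int = 0

    def __post_init__(self) -> None:
        if not self.seqs:
            raise ValueError("empty site set")
        w = len(self.seqs[0])
        if any(len(s) != w for s in self.seqs):
            raise ValueError("all site sequences must have equal width")
        self.seqs = [s.upper() for s in self.seqs]
        for s in self.seqs:
            if set(s) - set("ACGT"):
                raise ValueError(f"site {s!r} contains non-ACGT letters")
        if self.core_offset < 0 or self.core_offset + self.core_len > w:
            raise ValueError("core does not fit within the alignment width")

    @property
    def width(self) -> int:
        return len(self.seqs[0])

    def __len__(self) -> int:
        return len(self.seqs)

    def subalignment(self, start: int, length: int) -> "AlignedSiteSet":
        if start < 0 or start + length > self.width:
            raise ValueError("subalignment outside alignment")
        core_start = min(max(self.core_offset - start, 0), length)
        core_end = min(max(self.core_offset + self.core_len - start, 0), length)
        return AlignedSiteSet(
            [s[start:start + length] for s in self.seqs],
            core_offset=core_start,
            core_len=core_end - core_start,
        )


def _codes_matrix(seqs: Sequence[str]) -> np.ndarray:
    return np.stack([encode(s) for s in seqs])


def _dinuc_codes(codes: np.ndarray) -> np.ndarray:
    """Map (n, L) letter codes to (n, L-1) dinucleotide codes 0..15."""
    return codes[..., :-1] * 4 + codes[..., 1:]


class _PWMBase:
    """Shared scoring machinery for mono and dinucleotide matrices."""

    weights: np.ndarray  # (cols, alphabet)
    q: np.ndarray
    s_min: float
    s_max: float
    model_id: str

    def _window_symbols(self, codes: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def width(self) -> int:
        raise NotImplementedError

    def score_codes_raw(self, codes: np.ndarray) -> np.ndarray:
        """Raw additive score for (n, width) ACGT codes."""
        sym = self._window_symbols(codes)
        cols = np.arange(sym.shape[-1])
        return self.weights[cols, sym].sum(axis=-1)

    def score_windows(self, codes: np.ndarray) -> np.ndarray:
        """Rescaled [0, 1] scores for (n, width) ACGT codes."""
        raw = self.score_codes_raw(codes)
        return (raw - self.s_min) / (self.s_max - self.s_min)


@dataclass
class MonoPWM(_PWMBase):
    """Log-odds matrix over single nucleotides; additive window scoring."""

    weights: np.ndarray  # (L, 4)
    q: np.ndarray
    s_min: float = field(init=False)
    s_max: float = field(init=False)
    model_id: str = "mono_pwm"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.s_min = float(self.weights.min(axis=1).sum())
        self.s_max = float(self.weights.max(axis=1).sum())
        if not self.s_min < self.s_max:
            raise ValueError("degenerate matrix: s_min == s_max")

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    def _window_symbols(self, codes: np.ndarray) -> np.ndarray:
        return codes


@dataclass
class DiPWM(_PWMBase):
    """Log-odds matrix over the 16 adjacent-dinucleotide letters."""

    weights: np.ndarray  # (L-1, 16)
    q: np.ndarray  # (16,)
    s_min: float = field(init=False)
    s_max: float = field(init=False)
    model_id: str = "di_pwm"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.s_min = float(self.weights.min(axis=1).sum())
        self.s_max = float(self.weights.max(axis=1).sum())
        if not self.s_min < self.s_max:
            raise ValueError("degenerate matrix: s_min == s_max")

    @property
    def width(self) -> int:
        return self.weights.shape[0] + 1

    def _window_symbols(self, codes: np.ndarray) -> np.ndarray:
        return _dinuc_codes(codes)


def _pwm_from_counts(counts: np.ndarray, q: np.ndarray, pseudocount: float,
                     total: float, kind: str) -> MonoPWM | DiPWM:
    f = (counts + pseudocount * q) / (total + pseudocount)
    w = np.log(f / q)
    return MonoPWM(w, q) if kind == "mono" else DiPWM(w, q)


def build_mono_pwm(sites: AlignedSiteSet | Sequence[str],
                   q: np.ndarray | None = None,
                   pseudocount: float = 1.0) -> MonoPWM:
    """f_ja = (n_ja + pseudocount*q_a) / (N + pseudocount); w = ln(f/q)."""
    seqs = sites.seqs if isinstance(sites, AlignedSiteSet) else list(sites)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sites")
    codes = _codes_matrix(seqs)
    if codes.shape[1] == 0:
        raise ValueError("zero-width sites")
    q = np.full(4, 0.25) if q is None else np.asarray(q, dtype=float)
    if q.min() <= 0 or abs(q.sum() - 1) > 1e-9:
        raise ValueError("background q must be positive and sum to 1")
    L = codes.shape[1]
    counts = np.zeros((L, 4))
    for j in range(L):
        counts[j] = np.bincount(codes[:, j], minlength=4)
    return _pwm_from_counts(counts, q, pseudocount, len(seqs), "mono")


def build_di_pwm(sites: AlignedSiteSet | Sequence[str],
                 Q: np.ndarray | None = None,
                 pseudocount: float = 1.0) -> DiPWM:
    """As build_mono_pwm over adjacent-dinucleotide counts (16 letters)."""
    seqs = sites.seqs if isinstance(sites, AlignedSiteSet) else list(sites)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sites")
    codes = _dinuc_codes(_codes_matrix(seqs))
    if codes.shape[1] == 0:
        raise ValueError("sites too short for dinucleotide counts")
    Q = np.full(16, 1 / 16) if Q is None else np.asarray(Q, dtype=float)
    if Q.min() <= 0 or abs(Q.sum() - 1) > 1e-9:
        raise ValueError("background Q must be positive and sum to 1")
    C = codes.shape[1]
    counts = np.zeros((C, 16))
    for j in range(C):
        counts[j] = np.bincount(codes[:, j], minlength=16)
    return _pwm_from_counts(counts, Q, pseudocount, len(seqs), "di")


def score_window(model, window: str, strand: str = "+") -> float:
    """Raw additive score of one fixed-length window ('-' scores the
    reverse complement).  Raises UnscorableWindowError on non-ACGT."""
    if strand == "-":
        window = reverse_complement(window)
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    if len(window) != model.width:
        raise ValueError(f"window length {len(window)} != model width {model.width}")
    codes = encode(window)
    if (codes > 3).any():
        raise UnscorableWindowError(f"ambiguous base in window {window!r}")
    return float(model.score_codes_raw(codes[None, :])[0])


def rescale_score(model, raw: float) -> float:
    """Min-max rescale a raw score to [0, 1]."""
    if not (model.s_min - 1e-9 <= raw <= model.s_max + 1e-9):
        raise ValueError(f"raw score {raw} outside [{model.s_min}, {model.s_max}]")
    return float(np.clip((raw - model.s_min) / (model.s_max - model.s_min), 0, 1))


# ---------------------------------------------------------------------------
# Matrix-length optimization (leave-one-out false-positive minimization)
# ---------------------------------------------------------------------------

def _length_window(sites: AlignedSiteSet, length: int) -> int:
    """Start of the length-`length` window centered on the alignment core."""
    if length > sites.width:
        raise ValueError(f"candidate length {length} exceeds width {sites.width}")
    center = sites.core_offset + sites.core_len / 2.0
    start = int(round(center - length / 2.0))
    return int(np.clip(start, 0, sites.width - length))


def _background_window_codes(background_peaks: Sequence[Peak], L: int) -> np.ndarray:
    """All ACGT-only windows (both strands) of length L from the peaks."""
    chunks = []
    for p in background_peaks:
        codes = encode(p.seq)
        if codes.size < L:
            continue
        for arr in (codes, (3 - codes[::-1]) % 5):
            win = np.lib.stride_tricks.sliding_window_view(arr, L)
            ok = (win < 4).all(axis=1)
            if ok.any():
                chunks.append(win[ok])
    if not chunks:
        raise ValueError("no scorable background windows")
    return np.concatenate(chunks)


def _loo_scores(sub: AlignedSiteSet, q: np.ndarray, pseudocount: float,
                kind: str) -> np.ndarray:
    """Rescaled score of each site under the model trained without it."""
    codes = _codes_matrix(sub.seqs)
    sym = codes if kind == "mono" else _dinuc_codes(codes)
    m = 4 if kind == "mono" else 16
    C = sym.shape[1]
    counts = np.zeros((C, m))
    for j in range(C):
        counts[j] = np.bincount(sym[:, j], minlength=m)
    qv = q if kind == "mono" else None
    if qv is None:
        qv = np.full(16, 1 / 16)
    N = len(sub.seqs)
    out = np.empty(N)
    cols = np.arange(C)
    for i in range(N):
        c = counts.copy()
        c[cols, sym[i]] -= 1
        model = _pwm_from_counts(c, qv, pseudocount, N - 1, kind)
        raw = model.weights[cols, sym[i]].sum()
        out[i] = (raw - model.s_min) / (model.s_max - model.s_min)
    return out


def _tp_threshold(held_out_scores: np.ndarray, tp_anchor: float) -> float:
    """Largest threshold passing at least `tp_anchor` of held-out scores."""
    desc = np.sort(held_out_scores)[::-1]
    k = int(math.ceil(tp_anchor * desc.size)) - 1
    return float(desc[max(k, 0)])


def optimize_length(
    sites: AlignedSiteSet,
    background_peaks: Sequence[Peak],
    candidate_lengths: Sequence[int],
    tp_anchor: float = 0.9,
    q: np.ndarray | None = None,
    pseudocount: float = 1.0,
    kind: str = "mono",
) -> tuple[int, pd.DataFrame]:
    """Pick the matrix length minimizing the background false-positive rate.

    For each candidate length (a window centered on the alignment core) a
    leave-one-out pass scores every held-out site under the matrix trained
    on the others; the threshold is set so at least `tp_anchor` of held-out
    sites pass, and the FP rate is the fraction of background windows
    passing under the full-data matrix.  Ties go to the shorter matrix.
    """
    if not candidate_lengths:
        raise ValueError("no candidate lengths")
    if not 0 < tp_anchor <= 1:
        raise ValueError("tp_anchor must be in (0, 1]")
    q4 = np.full(4, 0.25) if q is None else np.asarray(q, dtype=float)
    rows = []
    for L in sorted(set(candidate_lengths)):
        start = _length_window(sites, L)
        sub = sites.subalignment(start, L)
        loo = _loo_scores(sub, q4, pseudocount, kind)
        thr = _tp_threshold(loo, tp_anchor)
        model = (build_mono_pwm(sub, q4, pseudocount) if kind == "mono"
                 else build_di_pwm(sub, None, pseudocount))
        bg = _background_window_codes(background_peaks, L)
        fp = float((model.score_windows(bg) >= thr).mean())
        rows.append({"length": L, "start": start, "threshold": thr,
                     "tp_rate": float((loo >= thr).mean()), "fp_rate": fp})
    table = pd.DataFrame(rows)
    best = table.sort_values(["fp_rate", "length"]).iloc[0]
    return int(best["length"]), table


# ---------------------------------------------------------------------------
# Plain-text matrix format
# ---------------------------------------------------------------------------

def write_matrix(model: MonoPWM | DiPWM, path: str | Path) -> None:
    kind = "mono" if isinstance(model, MonoPWM) else "di"
    with open(path, "w") as fh:
        bg = " ".join(f"{x:.10g}" for x in model.q)
        fh.write(f"#type {kind} length {model.width} background {bg}\n")
        for row in model.weights:
            fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def read_matrix(path: str | Path) -> MonoPWM | DiPWM:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 4 or header[0] != "#type":
            raise ValueError(f"{path}: bad matrix header")
        kind = header[1]
        bg = np.array([float(x) for x in header[header.index("background") + 1:]])
        rows = [[float(x) for x in line.split()] for line in fh if line.strip()]
    weights = np.array(rows)
    if kind == "mono":
        return MonoPWM(weights, bg)
    if kind == "di":
        return DiPWM(weights, bg)
    raise ValueError(f"{path}: unknown matrix type {kind!r}")
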