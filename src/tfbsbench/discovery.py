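"""De-novo motif discovery in peak sets.

Greedy gapless multiple local alignment maximizing the Kullback Discrete
Information Content (KDIC, mononucleotide alphabet) or its dinucleotide
counterpart KDDIC (16 letters), with multi-start bootstrapping and optional
peak-shape positional weighting.  One occurrence per selected peak; a peak
is dropped when its best occurrence lowers the objective.  Emits a
MonoPWM / DiPWM built from the occurrence columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pwm import AlignedSiteSet, DiPWM, MonoPWM, _pwm_from_counts, optimize_length
from .seqio import Peak, encode, reverse_complement

__all__ = [
    "Occurrence",
    "DiscoveryResult",
    "kdic",
    "kddic",
    "greedy_discover",
    "optimize_discovered_length",
    "write_occurrences",
    "consensus_summary",
]


@dataclass(frozen=True)
class Occurrence:
    peak_id: str
    offset: int
    strand: str


@dataclass
class DiscoveryResult:
    """Best alignment over all starts.

    ``objective`` is the KDIC/KDDIC (nats) of the final occurrence set;
    ``search_objective`` is the size-weighted form N*KDIC the greedy search
    maximizes (a pure KL sum is independent of alignment size, so it would
    reward shrinking the alignment to a few near-identical windows);
    ``trace`` holds the per-sweep search objective of each start.
    """

    occurrences: list[Occurrence]
    L: int
    mode: str
    objective: float
    matrix: MonoPWM | DiPWM
    trace: list[list[float]] = field(default_factory=list)
    search_objective: float = float("nan")


def _site_string(peak: Peak, occ: Occurrence, L: int) -> str:
    s = peak.seq[occ.offset:occ.offset + L]
    return s if occ.strand == "+" else reverse_complement(s)


def _counts_from_occurrences(
    occurrences: Sequence[Occurrence],
    peaks_by_id: dict[str, Peak],
    L: int,
    mode: str,
    weights: Sequence[float] | None,
) -> tuple[np.ndarray, float]:
    m = 4 if mode == "mono" else 16
    C = L if mode == "mono" else L - 1
    counts = np.zeros((C, m))
    total = 0.0
    if weights is None:
        weights = np.ones(len(occurrences))
    for occ, w in zip(occurrences, weights):
        peak = peaks_by_id[occ.peak_id]
        if occ.offset < 0 or occ.offset + L > len(peak.seq):
            raise ValueError(f"occurrence out of bounds in peak {occ.peak_id}")
        codes = encode(_site_string(peak, occ, L))
        if (codes > 3).any():
            raise ValueError(f"ambiguous base in occurrence {occ}")
        sym = codes if mode == "mono" else codes[:-1] * 4 + codes[1:]
        counts[np.arange(C), sym] += w
        total += w
    return counts, total


def _kdic_from_counts(counts: np.ndarray, total: float, q: np.ndarray,
                      pseudocount: float) -> float:
    f = (counts + pseudocount * q) / (total + pseudocount)
    return float(np.sum(f * np.log(f / q)))


def kdic(
    occurrences: Sequence[Occurrence],
    peaks: Sequence[Peak],
    L: int,
    q: np.ndarray | None = None,
    pseudocount: float = 1.0,
    weights: Sequence[float] | None = None,
) -> float:
    """Sum over columns of sum_a f_ja ln(f_ja / q_a) (nats), with f from
    pseudocounted occurrence columns.  Non-negative by Gibbs' inequality."""
    if len(occurrences) < 2:
        raise ValueError("need at least 2 occurrences")
    q = np.full(4, 0.25) if q is None else np.asarray(q, dtype=float)
    by_id = {p.id: p for p in peaks}
    counts, total = _counts_from_occurrences(occurrences, by_id, L, "mono", weights)
    return _kdic_from_counts(counts, total, q, pseudocount)


def kddic(
    occurrences: Sequence[Occurrence],
    peaks: Sequence[Peak],
    L: int,
    Q: np.ndarray | None = None,
    pseudocount: float = 1.0,
    weights: Sequence[float] | None = None,
) -> float:
    """KDIC over the (L-1) adjacent-dinucleotide columns, 16 letters."""
    if len(occurrences) < 2:
        raise ValueError("need at least 2 occurrences")
    Q = np.full(16, 1 / 16) if Q is None else np.asarray(Q, dtype=float)
    by_id = {p.id: p for p in peaks}
    counts, total = _counts_from_occurrences(occurrences, by_id, L, "di", weights)
    return _kdic_from_counts(counts, total, Q, pseudocount)


class _PeakCandidates:
    """Precomputed candidate occurrences of one peak: symbol codes per
    candidate, ordered '+' offsets ascending then '-' offsets ascending
    (ties in the objective therefore resolve to the smallest offset on the
    forward strand first)."""

    def __init__(self, peak: Peak, L: int, mode: str, use_shape: bool) -> None:
        self.peak = peak
        codes = encode(peak.seq)
        n_pos = len(peak.seq) - L + 1
        fwd = np.lib.stride_tricks.sliding_window_view(codes, L)
        rc = np.array([3, 2, 1, 0, 4], dtype=np.int8)[codes][::-1]
        rev_view = np.lib.stride_tricks.sliding_window_view(rc, L)
        rev = rev_view[::-1]  # rev[p] = rc window for forward start p
        windows = np.concatenate([fwd, rev])
        meta = [(p, "+") for p in range(n_pos)] + [(p, "-") for p in range(n_pos)]
        ok = (windows < 4).all(axis=1)
        self.meta = [m for m, k in zip(meta, ok) if k]
        self.index = {m: i for i, m in enumerate(self.meta)}
        win = windows[ok].astype(np.int64)
        self.sym = win if mode == "mono" else win[:, :-1] * 4 + win[:, 1:]
        if use_shape and peak.profile is not None:
            prof = np.asarray(peak.profile, dtype=float)
            prof = prof / prof.max() if prof.max() > 0 else np.ones_like(prof)
            mid = np.array([p + L // 2 for p, _ in self.meta])
            self.w = prof[mid]
        else:
            self.w = np.ones(len(self.meta))

    def shifted(self, k: int, delta: int) -> int | None:
        """Candidate index for the occurrence shifted by `delta` along its
        own (stranded) site coordinates; None when it falls off the peak or
        hits an unscorable window."""
        p, strand = self.meta[k]
        newp = p + delta if strand == "+" else p - delta
        return self.index.get((newp, strand))

    def __len__(self) -> int:
        return len(self.meta)


def _candidate_objectives(cands: _PeakCandidates, counts: np.ndarray,
                          total: float, q: np.ndarray, pc: float) -> np.ndarray:
    """Objective of the alignment with each candidate swapped in.

    Uses a per-(column, symbol) table when all candidate weights are equal,
    otherwise a full per-candidate tensor (needed for shape weighting).
    """
    C, m = counts.shape
    base = counts + pc * q
    if np.all(cands.w == cands.w[0]):
        w = cands.w[0]
        denom = total + w + pc
        tbl = np.broadcast_to(base[:, None, :], (C, m, m)).copy()
        tbl[:, np.arange(m), np.arange(m)] += w
        tbl /= denom
        col_obj = np.sum(tbl * np.log(tbl / q), axis=2)  # (C, m)
        return col_obj[np.arange(C), cands.sym].sum(axis=1)
    denom = (total + cands.w + pc)[:, None, None]
    f = base[None, :, :] / denom
    add = (cands.w / (total + cands.w + pc))[:, None]
    rows = np.arange(C)
    obj = np.empty(len(cands))
    # adjust only the chosen-symbol entries per candidate
    fl = np.log(f / q) * f
    tot = fl.sum(axis=(1, 2))
    chosen = f[np.arange(len(cands))[:, None], rows, cands.sym]
    new = chosen + add
    qv = q[cands.sym]
    obj = tot - (chosen * np.log(chosen / qv)).sum(axis=1) \
        + (new * np.log(new / qv)).sum(axis=1)
    return obj


def greedy_discover(
    peaks: Sequence[Peak],
    L: int,
    mode: str = "mono",
    n_starts: int = 10,
    bootstrap_frac: float = 0.5,
    use_shape: bool = False,
    seed: int = 0,
    pseudocount: float = 1.0,
    q: np.ndarray | None = None,
    max_sweeps: int = 100,
) -> DiscoveryResult:
    """Greedy multiple local alignment maximizing KDIC (mono) or KDDIC (di).

    Each start seeds the alignment with random occurrences in a bootstrap
    subsample of peaks, then sweeps: for every peak, the (offset, strand)
    maximizing the objective with that occurrence swapped in is chosen, or
    the peak is dropped when every candidate lowers the objective; sweeps
    stop at convergence or `max_sweeps`.  The best result over starts is
    returned; deterministic under `seed`.
    """
    if mode not in ("mono", "di"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    min_len = min(len(p.seq) for p in peaks)
    if L > min_len:
        raise ValueError(f"motif length {L} exceeds shortest peak ({min_len})")
    m = 4 if mode == "mono" else 16
    C = L if mode == "mono" else L - 1
    qv = (np.full(4, 0.25) if mode == "mono" else np.full(16, 1 / 16)) \
        if q is None else np.asarray(q, dtype=float)

    cands = [_PeakCandidates(p, L, mode, use_shape) for p in peaks]
    n = len(peaks)
    best: tuple[float, list[int]] | None = None
    traces: list[list[float]] = []

    for start in range(n_starts):
        rng = np.random.default_rng([seed, start])
        n_boot = min(n, max(2, int(round(bootstrap_frac * n))))
        chosen = rng.choice(n, size=n_boot, replace=False)
        occ = np.full(n, -1, dtype=np.int64)
        counts = np.zeros((C, m))
        total = 0.0
        for i in chosen:
            if len(cands[i]) == 0:
                continue
            k = int(rng.integers(0, len(cands[i])))
            occ[i] = k
            counts[np.arange(C), cands[i].sym[k]] += cands[i].w[k]
            total += cands[i].w[k]
        def state_counts(occ_vec: np.ndarray) -> tuple[np.ndarray, float]:
            cc = np.zeros((C, m))
            tt = 0.0
            for i in range(n):
                if occ_vec[i] >= 0:
                    cc[np.arange(C), cands[i].sym[occ_vec[i]]] += cands[i].w[occ_vec[i]]
                    tt += cands[i].w[occ_vec[i]]
            return cc, tt

        def search_obj(cc: np.ndarray, tt: float) -> float:
            return tt * _kdic_from_counts(cc, tt, qv, pseudocount)

        trace = [search_obj(counts, total)]
        sweeps_left = max_sweeps
        while sweeps_left > 0:
            # greedy occurrence sweeps to convergence
            while sweeps_left > 0:
                sweeps_left -= 1
                changed = False
                for i in range(n):
                    if len(cands[i]) == 0:
                        continue
                    if occ[i] >= 0:
                        k_old = occ[i]
                        counts[np.arange(C), cands[i].sym[k_old]] -= cands[i].w[k_old]
                        total -= cands[i].w[k_old]
                    obj_wo = search_obj(counts, total)
                    objs = (total + cands[i].w) * _candidate_objectives(
                        cands[i], counts, total, qv, pseudocount)
                    k_new = int(np.argmax(objs))
                    if objs[k_new] > obj_wo + 1e-12:
                        counts[np.arange(C), cands[i].sym[k_new]] += cands[i].w[k_new]
                        total += cands[i].w[k_new]
                    else:
                        k_new = -1
                    if k_new != occ[i]:
                        changed = True
                    occ[i] = k_new
                trace.append(search_obj(counts, total))
                if not changed:
                    break
            # phase-shift move: slide the whole alignment register, which
            # greedy per-peak swaps cannot do once a shifted phase locks in
            cur_obj = search_obj(counts, total)
            best_shift, best_obj = None, cur_obj
            for delta in (-2, -1, 1, 2):
                shifted = occ.copy()
                for i in range(n):
                    if shifted[i] >= 0:
                        k2 = cands[i].shifted(shifted[i], delta)
                        shifted[i] = -1 if k2 is None else k2
                cc, tt = state_counts(shifted)
                if tt < 1:
                    continue
                obj2 = search_obj(cc, tt)
                if obj2 > best_obj + 1e-12:
                    best_shift, best_obj = shifted, obj2
            if best_shift is None:
                break
            occ = best_shift
            counts, total = state_counts(occ)
            trace.append(best_obj)
        traces.append(trace)
        obj = trace[-1]
        if best is None or obj > best[0]:
            best = (obj, occ.copy())

    obj, occ = best
    occurrences = []
    weights = []
    for i in range(n):
        if occ[i] >= 0:
            p, strand = cands[i].meta[occ[i]]
            occurrences.append(Occurrence(peaks[i].id, p, strand))
            weights.append(float(cands[i].w[occ[i]]))
    by_id = {p.id: p for p in peaks}
    counts, total = _counts_from_occurrences(occurrences, by_id, L, mode, weights)
    matrix = _pwm_from_counts(counts, qv, pseudocount, total, mode)
    objective = _kdic_from_counts(counts, total, qv, pseudocount)
    return DiscoveryResult(occurrences, L, mode, objective, matrix, traces,
                           search_objective=obj)


def optimize_discovered_length(
    peaks: Sequence[Peak],
    L_range: Sequence[int],
    mode: str = "mono",
    seed: int = 0,
    background_peaks: Sequence[Peak] | None = None,
    tp_anchor: float = 0.9,
    **discover_kwargs,
) -> tuple[DiscoveryResult, "pd.DataFrame"]:
    """Run discovery per candidate length and keep the length whose
    discovered occurrence set gives the lowest held-out background FP rate
    at the fixed TP anchor (same leave-one-out scheme as the matrix-length
    optimization of pattern-matching PWMs).  Ties go to the shorter length.
    """
    import pandas as pd

    if not L_range:
        raise ValueError("empty L_range")
    if background_peaks is None:
        from .benchmark import make_shuffled_background
        background_peaks = make_shuffled_background(peaks, order=1, n_fold=1,
                                                    seed=seed)[0]
    rows = []
    results = {}
    for L in sorted(set(L_range)):
        res = greedy_discover(peaks, L, mode=mode, seed=seed, **discover_kwargs)
        results[L] = res
        sites = AlignedSiteSet(
            [_site_string({p.id: p for p in peaks}[o.peak_id], o, L)
             for o in res.occurrences],
            core_offset=0, core_len=L,
        )
        _, table = optimize_length(sites, background_peaks, [L],
                                   tp_anchor=tp_anchor, kind=mode)
        fp = float(table["fp_rate"].iloc[0])
        rows.append({"length": L, "objective": res.objective, "fp_rate": fp})
    table = pd.DataFrame(rows)
    best_L = int(table.sort_values(["fp_rate", "length"]).iloc[0]["length"])
    return results[best_L], table


def write_occurrences(result: DiscoveryResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\toffset\tstrand\n")
        for o in result.occurrences:
            fh.write(f"{o.peak_id}\t{o.offset}\t{o.strand}\n")


def consensus_summary(result: DiscoveryResult, peaks: Sequence[Peak]) -> str:
    """Text logo stand-in: consensus string plus per-column information
    content (nats) of the discovered alignment."""
    by_id = {p.id: p for p in peaks}
    sites = [_site_string(by_id[o.peak_id], o, result.L)
             for o in result.occurrences]
    codes = np.stack([encode(s) for s in sites])
    lines = []
    consensus = []
    q = np.full(4, 0.25)
    for j in range(result.L):
        cnt = np.bincount(codes[:, j], minlength=4)[:4].astype(float)
        f = (cnt + 0.25) / (cnt.sum() + 1.0)
        ic = float(np.sum(f * np.log(f / q)))
        base = "ACGT"[int(cnt.argmax())]
        consensus.append(base)
        lines.append(f"{j}\t{base}\t{ic:.4f}")
    return "consensus\t" + "".join(consensus) + "\npos\tbase\tic_nats\n" + \
        "\n".join(lines) + "\n"
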