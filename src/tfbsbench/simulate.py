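"""Synthetic-data generators with known ground truth.

Everything the pipeline consumes can be generated here: Markov-chain
background peaks with implanted motif instances (optionally homotypic
clusters, with coverage heights), aligned training-site sets drawn from a
ground-truth motif, and noisy EMSA-style competition curves with known
relative affinities.

The default ground-truth motif is FoxA-like: a TRTTTRYH degenerate core
(0.85 of the column mass on the consensus-compatible letters) with two
mildly informative flanking columns on each side.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import IUPAC_SETS, Peak, decode, encode, reverse_complement

__all__ = [
    "MarkovChain",
    "GroundTruthMotif",
    "SyntheticPeakSet",
    "SyntheticEMSAPanel",
    "fit_markov",
    "generate_background",
    "implant_sites",
    "generate_training_sites",
    "simulate_emsa_panel",
    "default_foxa_motif",
    "subtype_motif_pair",
    "first_order_dependent_motif",
    "distant_dependent_sites",
    "motif_affinity",
    "make_emsa_oligos",
    "write_truth_tsv",
    "write_emsa_tsv",
]

_ACGT = "ACGT"


@dataclass
class MarkovChain:
    """Order-0 or order-1 nucleotide chain with add-one-smoothed estimates.

    For order 1, ``trans[i, j] = P(next = j | current = i)`` and ``initial``
    holds the marginal letter distribution used for the first position.
    """

    order: int
    initial: np.ndarray
    trans: np.ndarray | None = None  # (4, 4), order 1 only

    def generate(self, length: int, rng: np.random.Generator) -> str:
        codes = np.empty(length, dtype=np.int8)
        codes[0] = rng.choice(4, p=self.initial)
        if self.order == 0:
            if length > 1:
                codes[1:] = rng.choice(4, size=length - 1, p=self.initial)
        else:
            # Draw all uniforms at once; walk the chain with cumulative rows.
            cum = np.cumsum(self.trans, axis=1)
            u = rng.random(length - 1)
            for i in range(1, length):
                codes[i] = np.searchsorted(cum[codes[i - 1]], u[i - 1])
        return decode(codes)


def fit_markov(seqs: Sequence[str], order: int) -> MarkovChain:
    """Fit an order-0/1 chain with add-one smoothing; ambiguous letters are
    skipped."""
    if order not in (0, 1):
        raise ValueError(f"unsupported order {order}")
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("empty input")
    base = np.ones(4)
    trans = np.ones((4, 4))
    for s in seqs:
        codes = encode(s)
        valid = codes < 4
        base += np.bincount(codes[valid], minlength=5)[:4]
        if order == 1:
            a, b = codes[:-1], codes[1:]
            ok = (a < 4) & (b < 4)
            np.add.at(trans, (a[ok], b[ok]), 1)
    initial = base / base.sum()
    if order == 0:
        return MarkovChain(0, initial)
    return MarkovChain(1, initial, trans / trans.sum(axis=1, keepdims=True))


def generate_background(
    model: MarkovChain,
    n: int,
    length: int,
    seed: int | np.random.Generator,
    min_height: float = 15.0,
    nbinom_n: float = 5.0,
    nbinom_p: float = 0.5,
) -> list[Peak]:
    """Draw `n` background peaks of fixed `length` from the chain.

    Heights follow a shifted negative binomial: ``min_height + NB(n, p)``,
    emulating coverage filters (>= 15 mouse-style, >= 10 human-style).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    heights = min_height + rng.negative_binomial(nbinom_n, nbinom_p, size=n)
    return [
        Peak(id=f"peak{i:05d}", seq=model.generate(length, rng),
             height=float(heights[i]))
        for i in range(n)
    ]


@dataclass
class GroundTruthMotif:
    """Column-probability model of a binding site, optionally with
    first-order dependence between adjacent positions.

    ``column_probs`` is (L, 4).  When ``transitions`` is given (shape
    (L-1, 4, 4) with rows P(x[j+1] | x[j])), sites are sampled from the
    inhomogeneous first-order chain instead of independent columns.
    """

    column_probs: np.ndarray
    core_offset: int = 0
    core_consensus: str = "TRTTTRYH"
    transitions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.column_probs = np.asarray(self.column_probs, dtype=float)
        if not np.allclose(self.column_probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif columns must each sum to 1")
        core = self.core_consensus
        end = self.core_offset + len(core)
        if self.core_offset < 0 or end > self.length:
            raise ValueError("core consensus does not fit in the motif")
        for j, letter in enumerate(core):
            col = self.column_probs[self.core_offset + j]
            allowed = [i for i, b in enumerate(_ACGT) if b in IUPAC_SETS[letter]]
            if col[allowed].sum() < 0.5:
                raise ValueError(
                    f"column {self.core_offset + j} incompatible with core "
                    f"letter {letter}"
                )
        if self.transitions is not None:
            self.transitions = np.asarray(self.transitions, dtype=float)
            if self.transitions.shape != (self.length - 1, 4, 4):
                raise ValueError("transitions must have shape (L-1, 4, 4)")
            if not np.allclose(self.transitions.sum(axis=2), 1.0, atol=1e-9):
                raise ValueError("transition rows must sum to 1")

    @property
    def length(self) -> int:
        return self.column_probs.shape[0]

    def sample(self, rng: np.random.Generator) -> str:
        L = self.length
        codes = np.empty(L, dtype=np.int8)
        codes[0] = rng.choice(4, p=self.column_probs[0])
        for j in range(1, L):
            if self.transitions is not None:
                p = self.transitions[j - 1, codes[j - 1]]
            else:
                p = self.column_probs[j]
            codes[j] = rng.choice(4, p=p)
        return decode(codes)

    def consensus(self) -> str:
        return "".join(_ACGT[i] for i in self.column_probs.argmax(axis=1))


def _core_column(letter: str, mass: float = 0.85) -> np.ndarray:
    """Column with `mass` split over the IUPAC-compatible letters."""
    allowed = [i for i, b in enumerate(_ACGT) if b in IUPAC_SETS[letter]]
    col = np.full(4, (1 - mass) / (4 - len(allowed))) if len(allowed) < 4 \
        else np.full(4, 0.25)
    for i in allowed:
        col[i] = mass / len(allowed)
    return col


def default_foxa_motif(core_mass: float = 0.85, flank_mass: float = 0.4) -> GroundTruthMotif:
    """12-column FoxA-like motif: TRTTTRYH core flanked by 2 mildly
    informative columns each side (favoured letters TG...|...CA)."""
    core = "TRTTTRYH"
    flank5, flank3 = "TG", "CA"
    cols = []
    for b in flank5:
        col = np.full(4, (1 - flank_mass) / 3)
        col[_ACGT.index(b)] = flank_mass
        cols.append(col)
    cols += [_core_column(c, core_mass) for c in core]
    for b in flank3:
        col = np.full(4, (1 - flank_mass) / 3)
        col[_ACGT.index(b)] = flank_mass
        cols.append(col)
    return GroundTruthMotif(np.array(cols), core_offset=2, core_consensus=core)


def subtype_motif_pair(core_mass: float = 0.97, flank_fav: float = 0.5,
                       flank_anti: float = 0.02) -> tuple[GroundTruthMotif,
                                                          GroundTruthMotif]:
    """Two binding-site subtypes sharing a sharp TRTTTRYH core but with
    swapped flank preferences: each subtype's favoured flank letters are
    strongly disfavoured (probability `flank_anti`) in the other subtype.

    A model trained on one subtype rejects the other subtype's sites while
    both models still co-localize on chance core matches in background
    sequence — the ingredients of heterogeneous homotypic site clusters.
    """
    fav_a = ("TG", "CA")  # 5' and 3' flank consensus of subtype A
    fav_b = ("CA", "TG")

    def flank_col(fav: str, anti: str) -> np.ndarray:
        rest = (1 - flank_fav - flank_anti) / 2
        col = np.full(4, rest)
        col[_ACGT.index(fav)] = flank_fav
        col[_ACGT.index(anti)] = flank_anti
        return col

    def build(fav: tuple[str, str], anti: tuple[str, str]) -> GroundTruthMotif:
        cols = [flank_col(a, b) for a, b in zip(fav[0], anti[0])]
        cols += [_core_column(c, core_mass) for c in "TRTTTRYH"]
        cols += [flank_col(a, b) for a, b in zip(fav[1], anti[1])]
        return GroundTruthMotif(np.array(cols), core_offset=2)

    return build(fav_a, fav_b), build(fav_b, fav_a)


def first_order_dependent_motif(L: int = 12, stay: float = 0.7) -> GroundTruthMotif:
    """Motif with uniform single-letter columns but strong adjacent-position
    dependence: P(next = current) = `stay`, the rest split evenly.

    Mononucleotide statistics carry no signal; dinucleotide statistics do.
    """
    cols = np.full((L, 4), 0.25)
    t = np.full((4, 4), (1 - stay) / 3)
    np.fill_diagonal(t, stay)
    trans = np.broadcast_to(t, (L - 1, 4, 4)).copy()
    return GroundTruthMotif(cols, core_offset=0, core_consensus="N" * L,
                            transitions=trans)


def distant_dependent_sites(n: int, width: int, rng: np.random.Generator,
                            pos_a: int = 2, pos_b: int | None = None) -> list[str]:
    """Sites whose only signal is a long-range dependence: the dinucleotides
    at two distant windows are the same doubled letter (AA/CC/GG/TT drawn
    uniformly), all other positions i.i.d. uniform.  Every mononucleotide
    column is marginally uniform, so a PWM sees nothing.
    """
    if pos_b is None:
        pos_b = width - 4
    if not (0 <= pos_a and pos_a + 2 <= pos_b and pos_b + 2 <= width):
        raise ValueError("dependent windows must be disjoint and inside the site")
    out = []
    for _ in range(n):
        codes = rng.integers(0, 4, size=width).astype(np.int8)
        letter = rng.integers(0, 4)
        codes[pos_a:pos_a + 2] = letter
        codes[pos_b:pos_b + 2] = letter
        out.append(decode(codes))
    return out


@dataclass
class SyntheticPeakSet:
    """Peaks plus per-peak implant ground truth: (start, strand, site)."""

    peaks: list[Peak]
    truth: dict[str, list[tuple[int, str, str]]]

    def verify(self) -> None:
        """Check every recorded site occurs verbatim where recorded."""
        by_id = {p.id: p for p in self.peaks}
        for pid, entries in self.truth.items():
            for start, strand, site in entries:
                observed = by_id[pid].seq[start:start + len(site)]
                if strand == "-":
                    observed = reverse_complement(observed)
                if observed != site:
                    raise AssertionError(
                        f"truth mismatch at {pid}:{start}{strand}"
                    )


def implant_sites(
    peaks: Sequence[Peak],
    motif: GroundTruthMotif,
    sites_per_peak_dist: dict[int, float] | int,
    seed: int | np.random.Generator,
    max_tries: int = 200,
) -> SyntheticPeakSet:
    """Implant motif-drawn sites into peaks, uniformly placed without
    overlap, strand uniform; ground truth recorded per peak."""
    rng = np.random.default_rng(seed)
    L = motif.length
    if isinstance(sites_per_peak_dist, int):
        dist = {sites_per_peak_dist: 1.0}
    else:
        dist = dict(sites_per_peak_dist)
    ks = sorted(dist)
    probs = np.array([dist[k] for k in ks], dtype=float)
    probs /= probs.sum()

    new_peaks: list[Peak] = []
    truth: dict[str, list[tuple[int, str, str]]] = {}
    for p in peaks:
        if L > len(p.seq):
            raise ValueError(f"motif longer than peak {p.id}")
        k = int(np.asarray(ks)[rng.choice(len(ks), p=probs)])
        placed: list[int] = []
        for _ in range(k):
            for _try in range(max_tries):
                start = int(rng.integers(0, len(p.seq) - L + 1))
                if all(abs(start - s) >= L for s in placed):
                    placed.append(start)
                    break
            else:
                raise ValueError(
                    f"cannot place {k} non-overlapping sites in peak {p.id}"
                )
        seq = list(p.seq)
        entries = []
        for start in sorted(placed):
            site = motif.sample(rng)
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else reverse_complement(site)
            seq[start:start + L] = inserted
            entries.append((start, strand, site))
        new_peaks.append(Peak(id=p.id, seq="".join(seq), height=p.height,
                              chrom=p.chrom, start=p.start, end=p.end,
                              profile=p.profile))
        truth[p.id] = entries
    return SyntheticPeakSet(new_peaks, truth)


def generate_training_sites(
    motif: GroundTruthMotif,
    n: int,
    flank_len: int,
    seed: int | np.random.Generator,
    background: MarkovChain | None = None,
):
    """Draw `n` aligned training sites: motif-drawn cores with chain-drawn
    flanks, emulating a curated binding-site alignment anchored on the
    degenerate core pattern.  Returns an AlignedSiteSet."""
    from .pwm import AlignedSiteSet  # local import avoids a cycle

    if n < 2:
        raise ValueError("need at least 2 training sites")
    rng = np.random.default_rng(seed)
    if background is None:
        background = MarkovChain(0, np.full(4, 0.25))
    seqs = []
    for _ in range(n):
        left = background.generate(flank_len, rng) if flank_len else ""
        right = background.generate(flank_len, rng) if flank_len else ""
        seqs.append(left + motif.sample(rng) + right)
    return AlignedSiteSet(
        seqs=seqs,
        core_offset=flank_len + motif.core_offset,
        core_len=len(motif.core_consensus),
    )


# ---------------------------------------------------------------------------
# EMSA competition-curve simulator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEMSAPanel:
    """Competition oligo panel with known relative affinities.

    ``oligos`` holds (id, seq, true_relative_affinity); exactly one oligo is
    the self-competition control with affinity 1.
    """

    oligos: list[tuple[str, str, float]]
    control_id: str

    def __post_init__(self) -> None:
        ids = [o[0] for o in self.oligos]
        if ids.count(self.control_id) != 1:
            raise ValueError("exactly one control oligo required")
        affs = {o[0]: o[2] for o in self.oligos}
        if abs(affs[self.control_id] - 1.0) > 1e-12:
            raise ValueError("control affinity must be 1")


# Control slope scale: chosen so band intensity stays positive for
# affinities up to ~1.5 at the largest default concentration (20 ng).
_EMSA_S0 = 0.2
_EMSA_I0 = 100.0


def simulate_emsa_panel(
    oligos_with_affinity: Sequence[tuple[str, float]] | SyntheticEMSAPanel,
    concentrations: Sequence[float] = (2.0, 5.0, 20.0),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[dict]:
    """Simulate competition curves I(c) = I0 * (1 - A * s0 * ln c) * eps.

    The intensity is linear in ln(concentration) with slope proportional to
    the true relative affinity A, so the downstream slope-ratio estimator
    (competitor slope / control slope) recovers A exactly at zero noise.
    ``eps`` is lognormal(0, noise_sd), independent per measurement.

    Returns one dict per oligo: id, concentrations, intensities,
    true_affinity.
    """
    if len(concentrations) < 2:
        raise ValueError("need at least 2 concentrations")
    conc = np.asarray(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(oligos_with_affinity, SyntheticEMSAPanel):
        pairs = [(oid, a) for oid, _seq, a in oligos_with_affinity.oligos]
    else:
        pairs = list(oligos_with_affinity)
    rng = np.random.default_rng(seed)
    curves = []
    for oid, aff in pairs:
        base = _EMSA_I0 * (1.0 - aff * _EMSA_S0 * np.log(conc))
        eps = np.exp(rng.normal(0.0, noise_sd, size=conc.size)) \
            if noise_sd > 0 else np.ones_like(conc)
        curves.append({
            "oligo_id": oid,
            "concentrations": conc.copy(),
            "intensities": base * eps,
            "true_affinity": aff,
        })
    return curves


def motif_affinity(motif: GroundTruthMotif, seq: str,
                   temperature: float = 3.0) -> float:
    """Relative binding affinity of a sequence under the additive-energy
    model: A = exp((s_best - s_consensus) / T), where s is the motif
    log-odds score of the best window on either strand.  The consensus
    scores A = 1; every mismatch lowers A multiplicatively."""
    w = np.log(motif.column_probs / 0.25)
    s_max = float(w.max(axis=1).sum())
    L = motif.length
    best = -np.inf
    for s in (seq, reverse_complement(seq)):
        codes = encode(s)
        if codes.size < L:
            raise ValueError("sequence shorter than the motif")
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        ok = (win < 4).all(axis=1)
        if ok.any():
            raw = w[np.arange(L), win[ok]].sum(axis=1)
            best = max(best, float(raw.max()))
    return float(np.exp((best - s_max) / temperature))


def make_emsa_oligos(
    motif: GroundTruthMotif,
    rng: np.random.Generator,
    n_nonsite: int = 6,
    n_weak: int = 5,
    n_strong: int = 4,
    flank_len: int = 9,
    control_id: str = "TTR_control",
    temperature: float = 3.0,
    max_tries: int = 2000,
) -> SyntheticEMSAPanel:
    """Build a competition panel around a ground-truth motif.

    Each oligo's true relative affinity is *determined by its sequence*
    through the additive-energy model of :func:`motif_affinity` (a random
    oligo that happens to contain a strong site is a strong binder, as in
    the physical assay).  Oligos are rejection-sampled per class so the
    panel spans the affinity bins: strong > 0.8, weak in [0.3, 0.7],
    non-site < 0.2.  The control is the perfect consensus site, affinity
    exactly 1.
    """
    bg = MarkovChain(0, np.full(4, 0.25))
    L = motif.length

    def with_flanks(core: str) -> str:
        return bg.generate(flank_len, rng) + core + bg.generate(flank_len, rng)

    def mismatched(site: str, k: int) -> str:
        codes = encode(site).copy()
        pos = rng.choice(L, size=k, replace=False)
        for j in pos:
            codes[j] = (codes[j] + 1 + rng.integers(0, 3)) % 4
        return decode(codes)

    def sample_in(lo: float, hi: float, proposal) -> tuple[str, float]:
        for _ in range(max_tries):
            seq = proposal()
            a = motif_affinity(motif, seq, temperature)
            if lo < a < hi:
                return seq, a
        raise RuntimeError(
            f"could not sample an oligo with affinity in ({lo}, {hi})"
        )

    consensus = motif.consensus()
    oligos: list[tuple[str, str, float]] = [
        (control_id, with_flanks(consensus), 1.0)
    ]
    for i in range(n_strong):
        seq, a = sample_in(0.8, 1.0 + 1e-9,
                           lambda: with_flanks(motif.sample(rng)))
        oligos.append((f"strong{i}", seq, a))
    for i in range(n_weak):
        seq, a = sample_in(0.3, 0.7,
                           lambda: with_flanks(mismatched(consensus,
                                                          1 + rng.integers(0, 2))))
        oligos.append((f"weak{i}", seq, a))
    for i in range(n_nonsite):
        seq, a = sample_in(0.0, 0.2,
                           lambda: bg.generate(L + 2 * flank_len, rng))
        oligos.append((f"nonsite{i}", seq, a))
    return SyntheticEMSAPanel(oligos, control_id)


# ---------------------------------------------------------------------------
# Plain-text writers (FASTA/BED writers live in seqio)
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: dict[str, list[tuple[int, str, str]]],
                    path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tstart\tstrand\tsite\n")
        for pid, entries in truth.items():
            for start, strand, site in entries:
                fh.write(f"{pid}\t{start}\t{strand}\t{site}\n")


def write_emsa_tsv(curves: Sequence[dict], path: str | Path,
                   control_id: str | None = None) -> None:
    """Long-format TSV: oligo_id, conc_ng, intensity, is_control."""
    with open(path, "w") as fh:
        fh.write("oligo_id\tconc_ng\tintensity\tis_control\n")
        for cur in curves:
            is_ctrl = int(cur["oligo_id"] == control_id)
            for c, i in zip(cur["concentrations"], cur["intensities"]):
                fh.write(f"{cur['oligo_id']}\t{c:g}\t{i:.6f}\t{is_ctrl}\n")
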