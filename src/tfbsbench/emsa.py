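"""EMSA competition-curve calibration.

Turns band-intensity curves into EMSA scores (competitor slope of intensity
vs ln(concentration), normalized to the self-competition control), bins
oligos into non-site / weak / strong affinity classes (<0.25 / 0.25-0.75 /
>0.75), and derives per-model recognition thresholds as the highest model
score among non-site oligos — a site passes only with a strictly greater
score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EMSARecord",
    "CalibratedThreshold",
    "fit_slope",
    "emsa_score",
    "classify_affinity",
    "derive_threshold",
    "sensitivity_of_bin_edge",
    "read_emsa_tsv",
    "write_emsa_records",
    "records_from_curves",
    "NONSITE_EDGE",
    "STRONG_EDGE",
]

# Affinity-class bin edges: the non-site edge corresponds to the technical
# error of the assay multiplied by 1.5.
NONSITE_EDGE = 0.25
STRONG_EDGE = 0.75


@dataclass
class EMSARecord:
    """One competitor oligo's concentration-intensity curve with the fitted
    slope, normalized EMSA score and affinity class."""

    oligo_id: str
    concentrations: np.ndarray
    intensities: np.ndarray
    slope: float = field(default=float("nan"))
    emsa_score: float = field(default=float("nan"))
    affinity_class: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.concentrations.size != self.intensities.size:
            raise ValueError("concentrations and intensities differ in length")
        if self.concentrations.size < 2:
            raise ValueError("need at least 2 measurements")


def fit_slope(record: EMSARecord) -> float:
    """OLS slope of intensity against ln(concentration)."""
    if (record.concentrations <= 0).any():
        raise ValueError(f"{record.oligo_id}: non-positive concentration")
    x = np.log(record.concentrations)
    if np.ptp(x) == 0:
        raise ValueError(f"{record.oligo_id}: zero variance in ln(concentration)")
    res = stats.linregress(x, record.intensities)
    return float(res.slope)


def emsa_score(record: EMSARecord, control_record: EMSARecord) -> float:
    """Slope ratio competitor/control; negative ratios clamp to 0 with a
    warning (a positive competitor slope is measurement noise)."""
    s = fit_slope(record)
    s0 = fit_slope(control_record)
    if s0 == 0:
        raise ValueError("control slope is zero; cannot normalize")
    ratio = s / s0
    if ratio < 0:
        warnings.warn(
            f"{record.oligo_id}: negative slope ratio {ratio:.3g} clamped to 0"
        )
        ratio = 0.0
    record.slope = s
    record.emsa_score = float(ratio)
    record.affinity_class = classify_affinity(ratio)
    return float(ratio)


def classify_affinity(score: float,
                      nonsite_edge: float = NONSITE_EDGE,
                      strong_edge: float = STRONG_EDGE) -> str:
    """<edge -> non-site (strict); [edge, strong_edge] -> weak; > -> strong."""
    if score < 0:
        raise ValueError("EMSA score must be >= 0")
    if score < nonsite_edge:
        return "non-site"
    if score <= strong_edge:
        return "weak"
    return "strong"


@dataclass
class CalibratedThreshold:
    """Per-model recognition threshold: the maximum model score among
    non-site oligos; sites pass only with a strictly greater score."""

    model_id: str
    threshold: float
    provenance: list[str]


def derive_threshold(
    model_id: str,
    oligo_scores: Sequence[tuple[EMSARecord, float]],
    nonsite_edge: float = NONSITE_EDGE,
) -> CalibratedThreshold:
    """`oligo_scores` pairs each EMSA record (with emsa_score set) with the
    model's score of that oligo sequence."""
    nonsites = [(r, s) for r, s in oligo_scores
                if r.emsa_score < nonsite_edge]
    if not nonsites:
        raise ValueError(
            "no non-site oligos in the panel; threshold calibration "
            "requires at least one (redesign the panel)"
        )
    best = max(nonsites, key=lambda rs: rs[1])
    return CalibratedThreshold(
        model_id=model_id,
        threshold=float(best[1]),
        provenance=[r.oligo_id for r, _ in nonsites],
    )


def sensitivity_of_bin_edge(
    oligo_scores: Sequence[tuple[EMSARecord, float]],
    model,
    real_peaks,
    background_peaks,
    edges: Sequence[float] = (0.17, 0.25, 0.34),
) -> dict[float, float | None]:
    """Re-derive the threshold for each candidate non-site bin edge and
    report the benchmark CC at that threshold (None when an edge leaves no
    non-site oligos)."""
    from .benchmark import ConfusionCounts, correlation_coefficient
    from .scan import best_scores

    real = best_scores(real_peaks, model)
    bg = best_scores(background_peaks, model)
    out: dict[float, float | None] = {}
    for edge in edges:
        if not 0 < edge < 1:
            raise ValueError("edges must lie in (0, 1)")
        try:
            thr = derive_threshold(model.model_id, oligo_scores, edge).threshold
        except ValueError:
            out[edge] = None
            continue
        tp = int(np.sum(real > thr))
        fp = int(np.sum(bg > thr))
        counts = ConfusionCounts(tp, real.size - tp, fp, bg.size - fp)
        out[edge] = correlation_coefficient(counts)
    return out


# ---------------------------------------------------------------------------
# TSV I/O (long format: oligo_id, conc_ng, intensity[, is_control])
# ---------------------------------------------------------------------------

def read_emsa_tsv(path: str | Path,
                  control_id: str | None = None) -> tuple[list[EMSARecord], EMSARecord]:
    """Read a long-format EMSA TSV; the control is flagged by an
    `is_control` column or named via `control_id`."""
    df = pd.read_csv(path, sep="\t")
    if control_id is None:
        if "is_control" not in df.columns:
            raise ValueError("control oligo unknown: no is_control column "
                             "and no control id given")
        ctrl_ids = df.loc[df["is_control"] == 1, "oligo_id"].unique()
        if len(ctrl_ids) != 1:
            raise ValueError("exactly one control oligo required")
        control_id = str(ctrl_ids[0])
    records = []
    control = None
    for oid, grp in df.groupby("oligo_id", sort=False):
        rec = EMSARecord(str(oid), grp["conc_ng"].to_numpy(),
                         grp["intensity"].to_numpy())
        if str(oid) == control_id:
            control = rec
        else:
            records.append(rec)
    if control is None:
        raise ValueError(f"control oligo {control_id!r} not found")
    return records, control


def records_from_curves(curves: Sequence[dict],
                        control_id: str) -> tuple[list[EMSARecord], EMSARecord]:
    """Adapt simulate.simulate_emsa_panel output to EMSARecords."""
    records, control = [], None
    for cur in curves:
        rec = EMSARecord(cur["oligo_id"], cur["concentrations"],
                         cur["intensities"])
        if cur["oligo_id"] == control_id:
            control = rec
        else:
            records.append(rec)
    if control is None:
        raise ValueError(f"control {control_id!r} missing from curves")
    return records, control


def write_emsa_records(records: Sequence[EMSARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("oligo_id\temsa_score\taffinity_class\n")
        for r in records:
            fh.write(f"{r.oligo_id}\t{r.emsa_score:.6g}\t{r.affinity_class}\n")
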