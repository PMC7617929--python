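"""Flow-cytometry gating of nodule contents: bacteria vs. bacteroids.

Events below the fluorescence threshold are "unlabelled" (debris, plant
material) and excluded from counts.  The remaining labelled events are split
by an explicit linear boundary in the (forward scatter, side scatter) plane:
a·FSC + b·SSC ≥ c classifies an event as a bacteroid, since bacteroids are
larger (FSC) and more granular (SSC) than undifferentiated bacteria; equality
deterministically goes to the bacteroid side.  Per-sample absolute abundances
scale the counts by dilution, analysed-volume fraction and nodule mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GateConfig", "apply_gates", "take_reasonable",
           "summarize_nodule_sample", "midline_gate", "NodulePopSummary"]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("fsc", "ssc", "fl")


@dataclass(frozen=True)
class GateConfig:
    """Fluorescence threshold plus the scatter-plane boundary
    a·fsc + b·ssc >= c ⇒ bacteroid."""

    fl_threshold: float
    a: float
    b: float
    c: float
    labels: tuple = ("bacteria", "bacteroid")

    def __post_init__(self) -> None:
        if self.a == 0 and self.b == 0:
            raise ValueError("boundary: (a, b) must not be (0, 0)")
        if self.a < 0 or self.b < 0:
            raise ValueError(
                "boundary: a and b must be >= 0 so the bacteroid side is the "
                "larger-FSC, larger-SSC side"
            )


def midline_gate(bacteria_mean, bacteroid_mean, fl_threshold: float) -> GateConfig:
    """Boundary = perpendicular bisector of the two class means in scatter
    space (a convenience for synthetic mixtures with known centres)."""
    bm = np.asarray(bacteria_mean, dtype=float)
    dm = np.asarray(bacteroid_mean, dtype=float)
    direction = dm - bm
    mid = 0.5 * (bm + dm)
    return GateConfig(fl_threshold=fl_threshold, a=float(direction[0]),
                      b=float(direction[1]), c=float(direction @ mid))


def apply_gates(events: pd.DataFrame, config: GateConfig) -> pd.DataFrame:
    """Label every event bacteria / bacteroid / unlabelled.

    Malformed rows (missing, non-finite or negative channels) are rejected
    with their row numbers.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns {missing}")
    vals = events.loc[:, list(REQUIRED_COLUMNS)].to_numpy(dtype=float)
    bad = ~np.isfinite(vals).all(axis=1) | (vals < 0).any(axis=1)
    if bad.any():
        rows = events.index[bad].tolist()[:20]
        raise ValueError(f"malformed event rows (non-finite or negative): {rows}")
    labelled = vals[:, 2] >= config.fl_threshold
    score = config.a * vals[:, 0] + config.b * vals[:, 1]
    out = events.copy()
    lab = np.where(score >= config.c, config.labels[1], config.labels[0])
    out["label"] = np.where(labelled, lab, "unlabelled")
    return out


def take_reasonable(events: pd.DataFrame, n: int = 5000) -> pd.DataFrame:
    """Acquisition rule: read events until ``n`` pass finiteness checks, then
    stop; warn if the table is exhausted first."""
    vals = events.loc[:, list(REQUIRED_COLUMNS)].to_numpy(dtype=float)
    ok = np.isfinite(vals).all(axis=1) & (vals >= 0).all(axis=1)
    good = events[ok]
    if len(good) < n:
        log.warning("only %d reasonable events available (wanted %d)", len(good), n)
        return good
    return good.iloc[:n]


@dataclass
class NodulePopSummary:
    sample_id: str
    n_labelled: int
    n_bacteria: int
    n_bacteroids: int
    bacteria_per_gram: float
    bacteroids_per_gram: float
    proportion_bacteria: float


def summarize_nodule_sample(labelled: pd.DataFrame, dilution_factor: float,
                            analysed_volume: float, nodule_mass_g: float,
                            resuspension_volume: float = 1.0,
                            sample_id: str = "") -> NodulePopSummary:
    """Counts → cells per gram of nodule.

    cells/g(class) = count x dilution x (resuspension volume / analysed
    volume) / nodule mass.  Volumes share any unit; mass in grams.
    """
    if dilution_factor < 1:
        raise ValueError("dilution_factor: must be >= 1")
    if analysed_volume <= 0 or resuspension_volume <= 0:
        raise ValueError("volumes must be > 0")
    if nodule_mass_g <= 0:
        raise ValueError("nodule_mass_g: must be > 0")
    counts = labelled["label"].value_counts()
    n_bac = int(counts.get("bacteria", 0))
    n_boid = int(counts.get("bacteroid", 0))
    n_lab = n_bac + n_boid
    if n_lab == 0:
        log.warning("sample %s: zero labelled events", sample_id or "<unnamed>")
    scale = dilution_factor * (resuspension_volume / analysed_volume) / nodule_mass_g
    return NodulePopSummary(
        sample_id=sample_id,
        n_labelled=n_lab,
        n_bacteria=n_bac,
        n_bacteroids=n_boid,
        bacteria_per_gram=n_bac * scale,
        bacteroids_per_gram=n_boid * scale,
        proportion_bacteria=n_bac / n_lab if n_lab else float("nan"),
    )
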