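"""Virtual re-segmentation of simulated tumors and validation metrics.

A simulated density field is converted back into imaging terms by
thresholding total cell density with the scenario's own windows: voxels
with p+q inside the closed interval I_c count as enhancing, those inside
I_e as edematous.  Volumes are compared as voxel counts — the primary
readout — via the relative change

    Delta = (V_1 - V_0) / V_0,

and an ensemble is summarized by the scenario whose simulated volume is
closest to the observed one, with relative error R_best.  Spatial accuracy
uses two set overlap scores between a simulated mask S and the observed
mask R: containment C = |S∩R|/|R| (how much of the real tumor the
simulation covers) and agreement A = |S∩R|/|S∪R| (Jaccard-type; penalizes
over-prediction as well).  A perfect, perfectly co-registered simulation
gives A = C = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import StudyPair
from .params import ModelParameters
from .pde import StateFields

__all__ = [
    "OverlapScores",
    "IntervalReport",
    "classify_state",
    "relative_change",
    "best_scenario",
    "overlap_scores",
    "threshold_summary",
    "evaluate_interval",
    "DEFAULT_THRESHOLDS",
]

#: default growth/shrinkage thresholds (fractions) for cohort summaries
DEFAULT_THRESHOLDS = (
    -0.50, -0.25, -0.20, -0.15, -0.10, 0.10, 0.15, 0.20, 0.25, 0.50, 1.00,
)


def classify_state(
    state: StateFields, params: ModelParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Virtual segmentation: (enhancing, edema) masks from total density.

    Both windows are closed intervals; disjointness of the returned masks
    is guaranteed by I_e < I_c.
    """
    u = state.total
    p1c, p2c = params.I_c
    p1e, p2e = params.I_e
    enhancing = (u >= p1c) & (u <= p2c)
    edema = (u >= p1e) & (u <= p2e)
    return enhancing, edema


def relative_change(v1: int, v0: int) -> float:
    """Relative change (v1 - v0) / v0 in enhancing voxel counts.

    Equals -1 when the comparison count is zero, +1 when it doubles, 0 when
    unchanged.  Undefined for v0 = 0 (scans with no enhancing tumor are
    excluded upstream).
    """
    if v0 <= 0:
        raise ValueError(f"baseline count must be > 0, got {v0}")
    if v1 < 0:
        raise ValueError(f"counts must be >= 0, got {v1}")
    return (v1 - v0) / v0


def best_scenario(v_sims: Sequence[int], v_obs: int) -> tuple[int, float]:
    """Closest-volume scenario: (1-based position, R_best).

    R_best = (V* - V_obs)/V_obs where V* is the simulated count closest to
    the observed one; ties break to the lowest position.
    """
    if len(v_sims) == 0:
        raise ValueError("empty scenario volume list")
    if v_obs <= 0:
        raise ValueError(f"observed count must be > 0, got {v_obs}")
    arr = np.asarray(v_sims, dtype=float)
    pos = int(np.argmin(np.abs(arr - v_obs)))  # argmin takes first on ties
    return pos + 1, float((arr[pos] - v_obs) / v_obs)


@dataclass(frozen=True)
class OverlapScores:
    """Containment and agreement between a simulated and an observed mask."""

    agreement: float
    containment: float
    size_sim: int
    size_obs: int
    intersection: int
    union: int

    def as_dict(self) -> dict:
        return {
            "agreement": self.agreement,
            "containment": self.containment,
            "size_sim": self.size_sim,
            "size_obs": self.size_obs,
            "intersection": self.intersection,
            "union": self.union,
        }


def overlap_scores(S: np.ndarray, R: np.ndarray) -> OverlapScores:
    """Spatial overlap of simulated mask S against observed mask R.

    containment C = |S∩R| / |R|, agreement A = |S∩R| / |S∪R|.
    """
    S = np.asarray(S).astype(bool)
    R = np.asarray(R).astype(bool)
    if S.shape != R.shape:
        raise ValueError(f"mask shapes differ: {S.shape} vs {R.shape}")
    n_obs = int(np.count_nonzero(R))
    if n_obs == 0:
        raise ValueError("observed mask R is empty; containment is undefined")
    n_sim = int(np.count_nonzero(S))
    inter = int(np.count_nonzero(S & R))
    union = int(np.count_nonzero(S | R))
    return OverlapScores(
        agreement=inter / union,
        containment=inter / n_obs,
        size_sim=n_sim,
        size_obs=n_obs,
        intersection=inter,
        union=union,
    )


def threshold_summary(
    deltas: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Fractions of relative changes beyond signed thresholds.

    For each negative threshold tau, the fraction of deltas <= tau (chance
    of shrinking at least that much); for each nonnegative tau, the
    fraction >= tau.  The overall fractions < 0 and >= 0 are always
    included.  Fractions are exact; rounding is left to display.
    """
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size == 0:
        raise ValueError("empty list of relative changes")
    rows = []
    for tau in thresholds:
        if tau < 0:
            frac = float(np.mean(deltas <= tau))
            label = f"<= {tau:+.0%}"
        else:
            frac = float(np.mean(deltas >= tau))
            label = f">= {tau:+.0%}"
        rows.append({"threshold": label, "tau": float(tau), "fraction": frac})
    rows.append(
        {"threshold": "< +0%", "tau": float("nan"), "fraction": float(np.mean(deltas < 0))}
    )
    rows.append(
        {"threshold": ">= +0%", "tau": float("nan"), "fraction": float(np.mean(deltas >= 0))}
    )
    return pd.DataFrame(rows, columns=["threshold", "tau", "fraction"])


@dataclass
class IntervalReport:
    """All volumetric and spatial metrics for one imaging interval."""

    V_0: int
    V_obs: int
    delta_obs: float
    scenario_indices: list[int]
    V_sims: list[int]
    delta_sims: list[float]
    overlaps: list[OverlapScores]
    best_index: int
    R_best: float
    interval_days: float = field(default=float("nan"))

    def as_dict(self) -> dict:
        return {
            "schema_version": 1,
            "V_0": self.V_0,
            "V_obs": self.V_obs,
            "delta_obs": self.delta_obs,
            "interval_days": self.interval_days,
            "best_index": self.best_index,
            "R_best": self.R_best,
            "scenarios": [
                {
                    "index": i,
                    "V_sim": v,
                    "delta_sim": d,
                    **o.as_dict(),
                }
                for i, v, d, o in zip(
                    self.scenario_indices, self.V_sims, self.delta_sims, self.overlaps
                )
            ],
        }

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.as_dict(), indent=indent)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text + "\n")
        return text


def evaluate_interval(pair: StudyPair, results: Sequence) -> IntervalReport:
    """Compare ensemble results against the observed follow-up scan.

    ``results`` are :class:`~gliosim.ensemble.ScenarioResult` objects from
    an ensemble run on ``pair.baseline``.  The observed mask R is the
    follow-up's enhancing segmentation; each scenario contributes its
    simulated enhancing mask S.
    """
    if len(results) == 0:
        raise ValueError("no scenario results to evaluate")
    R = pair.followup.enhancing_mask
    v_obs = int(np.count_nonzero(R))
    if v_obs == 0:
        raise ValueError(
            "follow-up scan has no enhancing voxels; the interval is excluded "
            "from volumetric comparison"
        )
    v0 = pair.baseline.enhancing_count
    indices = [r.index for r in results]
    v_sims = [int(r.V_sim) for r in results]
    d_sims = [float(r.delta_sim) for r in results]
    overlaps = [overlap_scores(r.sim_enhancing_mask, R) for r in results]
    pos, r_best = best_scenario(v_sims, v_obs)
    return IntervalReport(
        V_0=v0,
        V_obs=v_obs,
        delta_obs=relative_change(v_obs, v0),
        scenario_indices=indices,
        V_sims=v_sims,
        delta_sims=d_sims,
        overlaps=overlaps,
        best_index=indices[pos - 1],
        R_best=r_best,
        interval_days=float(pair.interval_days),
    )
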