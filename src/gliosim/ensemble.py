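"""Ensemble execution and the modelling front end.

Running the ensemble means simulating the same baseline scan once per
scenario: build the coefficient fields, impute the initial densities,
integrate over the inter-scan interval, and re-segment the final state with
that scenario's own density windows.  Scenarios are independent, so the
results are identical whatever the execution order or worker count.

:class:`TumorGrowthModel` wraps this as a statsmodels-style modelling
object: construct it from a baseline (and optionally a follow-up) study,
call :meth:`~TumorGrowthModel.fit`, and read the estimates off the returned
:class:`EnsembleResults` — per-scenario simulated volumes and relative
changes, and, when a follow-up is supplied, the closest-volume scenario
(a discrete estimate over the parameter grid), its relative error R_best,
and the spatial overlap diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .grids import VoxelGrid
from .io import ImagingStudy, StudyPair, load_study_manifest
from .metrics import IntervalReport, classify_state, evaluate_interval, relative_change
from .params import ModelParameters, ScenarioSet, default_scenarios
from .pde import (
    SimulationError,
    SolverOptions,
    StateFields,
    build_coefficients,
    impute_initial_state,
    simulate,
)

__all__ = ["ScenarioResult", "run_ensemble", "TumorGrowthModel", "EnsembleResults"]


@dataclass
class ScenarioResult:
    """Outcome of one scenario: final state, virtual masks, volume metrics."""

    index: int
    params: ModelParameters
    final_state: StateFields
    sim_enhancing_mask: np.ndarray
    sim_edema_mask: np.ndarray
    V_sim: int
    delta_sim: float

    def __post_init__(self) -> None:
        if self.V_sim != int(np.count_nonzero(self.sim_enhancing_mask)):
            raise ValueError("V_sim does not equal the simulated enhancing voxel count")


def _run_one(
    index: int,
    params: ModelParameters,
    study: ImagingStudy,
    interval_days: float,
    v0: int,
    opts: Optional[SolverOptions],
) -> ScenarioResult:
    try:
        coeffs = build_coefficients(study.grid, study, params)
        state0 = impute_initial_state(study, params)
        final = simulate(state0, coeffs, study.grid, interval_days, opts)
        enhancing, edema = classify_state(final, params)
        v_sim = int(np.count_nonzero(enhancing))
        return ScenarioResult(
            index=index,
            params=params,
            final_state=final,
            sim_enhancing_mask=enhancing,
            sim_edema_mask=edema,
            V_sim=v_sim,
            delta_sim=relative_change(v_sim, v0),
        )
    except SimulationError as exc:
        raise SimulationError(f"scenario {index}: {exc}") from exc


def run_ensemble(
    study: ImagingStudy,
    interval_days: float,
    sset: Optional[ScenarioSet] = None,
    opts: Optional[SolverOptions] = None,
    workers: int = 1,
) -> list[ScenarioResult]:
    """Simulate every scenario over the interval; results ordered by index.

    ``workers > 1`` distributes scenarios over processes; the output is
    independent of worker count and execution order (the model is
    deterministic and scenarios do not interact).
    """
    if not interval_days > 0:
        raise ValueError(f"interval_days must be > 0, got {interval_days}")
    sset = sset or default_scenarios()
    v0 = study.enhancing_count
    if v0 == 0:
        raise ValueError("baseline has no enhancing voxels; nothing to simulate")
    if workers == 1:
        results = [
            _run_one(i, p, study, interval_days, v0, opts) for i, p in sset
        ]
    else:
        results = Parallel(n_jobs=workers)(
            delayed(_run_one)(i, p, study, interval_days, v0, opts) for i, p in sset
        )
    return sorted(results, key=lambda r: r.index)


class TumorGrowthModel:
    """Scenario-ensemble growth model for one imaging interval.

    Parameters
    ----------
    baseline : ImagingStudy
        The starting scan; its enhancing segmentation must be nonempty.
    followup : ImagingStudy, optional
        The comparison scan.  When given, fitting also evaluates the
        volumetric error of every scenario against the observed follow-up
        and selects the closest one.
    interval_days : float, optional
        Simulation horizon in days; defaults to the day difference between
        the two studies when a follow-up is given.
    scenarios : ScenarioSet, optional
        Parameter ensemble; defaults to the packaged 18-scenario design.
    solver_options : SolverOptions, optional
        Integrator tolerances.

    Examples
    --------
    >>> model = TumorGrowthModel(baseline, followup)
    >>> res = model.fit()
    >>> res.best_index, res.r_best
    """

    def __init__(
        self,
        baseline: ImagingStudy,
        followup: Optional[ImagingStudy] = None,
        interval_days: Optional[float] = None,
        scenarios: Optional[ScenarioSet] = None,
        solver_options: Optional[SolverOptions] = None,
    ) -> None:
        self.baseline = baseline
        self.followup = followup
        self.pair = StudyPair(baseline, followup) if followup is not None else None
        if interval_days is None:
            if self.pair is None:
                raise ValueError(
                    "interval_days is required when no follow-up study is given"
                )
            interval_days = float(self.pair.interval_days)
        if not interval_days > 0:
            raise ValueError(f"interval_days must be > 0, got {interval_days}")
        self.interval_days = float(interval_days)
        self.scenarios = scenarios or default_scenarios()
        self.solver_options = solver_options or SolverOptions()

    @classmethod
    def from_manifests(
        cls,
        baseline_manifest,
        followup_manifest=None,
        **kwargs,
    ) -> "TumorGrowthModel":
        """Build the model from study manifest files on disk."""
        baseline = load_study_manifest(baseline_manifest)
        followup = (
            load_study_manifest(followup_manifest)
            if followup_manifest is not None
            else None
        )
        return cls(baseline, followup, **kwargs)

    def fit(self, workers: int = 1) -> "EnsembleResults":
        """Run all scenarios (and, with a follow-up, the interval evaluation)."""
        results = run_ensemble(
            self.baseline,
            self.interval_days,
            self.scenarios,
            self.solver_options,
            workers=workers,
        )
        report = evaluate_interval(self.pair, results) if self.pair is not None else None
        return EnsembleResults(self, results, report)


class EnsembleResults:
    """Fitted ensemble: per-scenario volumes, changes and diagnostics."""

    def __init__(
        self,
        model: TumorGrowthModel,
        scenario_results: Sequence[ScenarioResult],
        report: Optional[IntervalReport] = None,
    ) -> None:
        self.model = model
        self.scenario_results = list(scenario_results)
        self.report = report
        self.V_0 = model.baseline.enhancing_count

    @property
    def v_sims(self) -> list[int]:
        return [r.V_sim for r in self.scenario_results]

    @property
    def delta_sims(self) -> list[float]:
        return [r.delta_sim for r in self.scenario_results]

    @property
    def best_index(self) -> Optional[int]:
        return None if self.report is None else self.report.best_index

    @property
    def r_best(self) -> Optional[float]:
        return None if self.report is None else self.report.R_best

    def to_frame(self) -> pd.DataFrame:
        """One row per scenario: parameters, V_sim, delta_sim, overlaps."""
        rows = []
        for r in self.scenario_results:
            row = r.params.as_row(r.index)
            row["V_sim"] = r.V_sim
            row["delta_sim"] = r.delta_sim
            rows.append(row)
        df = pd.DataFrame(rows).set_index("index")
        if self.report is not None:
            df["agreement"] = [o.agreement for o in self.report.overlaps]
            df["containment"] = [o.containment for o in self.report.overlaps]
        return df

    def as_dict(self) -> dict:
        out = {
            "schema_version": 1,
            "interval_days": self.model.interval_days,
            "V_0": self.V_0,
            "scenarios": [
                {"index": r.index, "V_sim": r.V_sim, "delta_sim": r.delta_sim}
                for r in self.scenario_results
            ],
        }
        if self.report is not None:
            out["interval_report"] = self.report.as_dict()
        return out

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.as_dict(), indent=indent)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        """Human-readable fit summary in the style of statsmodels results."""
        lines = [
            "Tumor growth scenario ensemble",
            "=" * 64,
            f"scenarios:        {len(self.scenario_results)}",
            f"interval:         {self.model.interval_days:g} days",
            f"V_0 (enhancing):  {self.V_0} voxels",
        ]
        if self.report is not None:
            lines += [
                f"V_obs:            {self.report.V_obs} voxels",
                f"delta_obs:        {self.report.delta_obs:+.4f}",
                f"best scenario:    {self.report.best_index}"
                f"  (R_best = {self.report.R_best:+.4f})",
            ]
        lines.append("-" * 64)
        df = self.to_frame()
        cols = ["V_sim", "delta_sim"] + (
            ["agreement", "containment"] if self.report is not None else []
        )
        lines.append(df[cols].to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("=" * 64)
        return "\n".join(lines)
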