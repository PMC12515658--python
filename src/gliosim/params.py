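"""Model parameters and the 18-scenario orthogonal-array ensemble design.

A scenario is one complete parameterization of the growth model.  Growth and
quiescence rates are specified as doubling and halving times in days (their
interpretation under pure exponential growth/decay); the rates actually used
in the equations are ``ln 2 / time``.  The density windows I_e and I_c map
total cell density to the imaging appearance: voxels whose density falls in
I_c would enhance on post-contrast T1, those in I_e would appear edematous
on T2/FLAIR.

The default ensemble samples seven three-level parameters with an 18-run
Taguchi design (the standard L18 orthogonal array): each of the 9 level
pairs of the two most sensitive parameters (edema halving and doubling
times) occurs exactly twice, and every parameter takes each of its 3 levels
exactly 6 times.  The table ships with the package as CSV and
:func:`validate_design` verifies those balance properties at runtime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "ModelParameters",
    "ScenarioSet",
    "DesignReport",
    "rate_from_time",
    "default_scenarios",
    "validate_design",
    "read_scenarios_csv",
    "write_scenarios_csv",
]

LN2 = math.log(2.0)

#: canonical CSV column order for scenario tables
SCENARIO_COLUMNS = [
    "index",
    "khat0_d",
    "rhohat0_d",
    "Dw_mm2_per_d",
    "Ie_lo",
    "Ie_hi",
    "Ic_lo",
    "Ic_hi",
    "khat1_d",
    "rhohat1_d",
]


def rate_from_time(that: float) -> float:
    """Convert a doubling or halving time (days) to a rate (1/day).

    Under pure exponential growth/decay a population changes by a factor of
    2 every ``that`` days when the per-capita rate is ``ln(2)/that``.
    """
    if not that > 0:
        raise ValueError(f"doubling/halving time must be > 0 days, got {that}")
    return LN2 / float(that)


@dataclass(frozen=True)
class ModelParameters:
    """One scenario: rate time-scales, diffusivity and density windows.

    Parameters
    ----------
    khat0, rhohat0 : float
        Halving and doubling times (days) of the quiescence and growth
        rates in edema and all other non-enhancing tissue.
    D_w : float
        Diffusivity in white matter and tumorous tissue, mm²/day.  Gray
        matter gets ``D_w / 2``; CSF and background get 0.
    I_e, I_c : (float, float)
        Closed total-density windows classified as edematous / enhancing.
        Must satisfy ``0 < Ie_lo < Ie_hi < Ic_lo < Ic_hi <= 1``.
    khat1, rhohat1 : float
        Halving and doubling times (days) inside the enhancing region.
    validate : bool
        Skip invariant checks when False (used by design validation to
        examine deliberately broken tables).
    """

    khat0: float
    rhohat0: float
    D_w: float
    I_e: tuple[float, float]
    I_c: tuple[float, float]
    khat1: float
    rhohat1: float
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "I_e", (float(self.I_e[0]), float(self.I_e[1])))
        object.__setattr__(self, "I_c", (float(self.I_c[0]), float(self.I_c[1])))
        if not self.validate:
            return
        for name in ("khat0", "rhohat0", "khat1", "rhohat1"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 days, got {getattr(self, name)}")
        if not self.D_w > 0:
            raise ValueError(f"D_w must be > 0 mm^2/day, got {self.D_w}")
        p1e, p2e = self.I_e
        p1c, p2c = self.I_c
        if not (0 < p1e < p2e < p1c < p2c <= 1):
            raise ValueError(
                "density windows must satisfy 0 < Ie_lo < Ie_hi < Ic_lo < Ic_hi <= 1, "
                f"got I_e={self.I_e}, I_c={self.I_c}"
            )

    # rates actually used in the equations
    @property
    def k0(self) -> float:
        """Quiescence rate outside the enhancing region, 1/day."""
        return rate_from_time(self.khat0)

    @property
    def rho0(self) -> float:
        """Growth rate outside the enhancing region, 1/day."""
        return rate_from_time(self.rhohat0)

    @property
    def k1(self) -> float:
        """Quiescence rate inside the enhancing region, 1/day."""
        return rate_from_time(self.khat1)

    @property
    def rho1(self) -> float:
        """Growth rate inside the enhancing region, 1/day."""
        return rate_from_time(self.rhohat1)

    def as_row(self, index: int) -> dict:
        return {
            "index": index,
            "khat0_d": self.khat0,
            "rhohat0_d": self.rhohat0,
            "Dw_mm2_per_d": self.D_w,
            "Ie_lo": self.I_e[0],
            "Ie_hi": self.I_e[1],
            "Ic_lo": self.I_c[0],
            "Ic_hi": self.I_c[1],
            "khat1_d": self.khat1,
            "rhohat1_d": self.rhohat1,
        }


@dataclass
class ScenarioSet:
    """An ordered ensemble of (index, ModelParameters), indices 1..n."""

    scenarios: list[tuple[int, ModelParameters]]

    def __post_init__(self) -> None:
        indices = [i for i, _ in self.scenarios]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError(
                f"scenario indices must be contiguous from 1, got {indices}"
            )

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self) -> Iterator[tuple[int, ModelParameters]]:
        return iter(self.scenarios)

    def __getitem__(self, index: int) -> ModelParameters:
        """Look up a scenario by its 1-based index."""
        for i, p in self.scenarios:
            if i == index:
                return p
        raise KeyError(f"no scenario with index {index}")

    def subset(self, indices: Sequence[int]) -> "ScenarioSet":
        """A new set (re-indexed from 1) of the selected scenario indices."""
        picked = [self[i] for i in indices]
        return ScenarioSet(list(enumerate(picked, start=1)))

    @classmethod
    def from_params(cls, params: Iterable[ModelParameters]) -> "ScenarioSet":
        return cls(list(enumerate(params, start=1)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.as_row(i) for i, p in self.scenarios])[SCENARIO_COLUMNS]


def _params_from_row(row: pd.Series, validate: bool = True) -> ModelParameters:
    return ModelParameters(
        khat0=float(row["khat0_d"]),
        rhohat0=float(row["rhohat0_d"]),
        D_w=float(row["Dw_mm2_per_d"]),
        I_e=(float(row["Ie_lo"]), float(row["Ie_hi"])),
        I_c=(float(row["Ic_lo"]), float(row["Ic_hi"])),
        khat1=float(row["khat1_d"]),
        rhohat1=float(row["rhohat1_d"]),
        validate=validate,
    )


def read_scenarios_csv(path: Path | str, validate: bool = True) -> ScenarioSet:
    """Read a scenario table from CSV (columns per ``SCENARIO_COLUMNS``)."""
    df = pd.read_csv(path)
    missing = [c for c in SCENARIO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scenario table {path} is missing column(s) {missing}")
    df = df.sort_values("index")
    scenarios = [
        (int(row["index"]), _params_from_row(row, validate=validate))
        for _, row in df.iterrows()
    ]
    return ScenarioSet(scenarios)


def write_scenarios_csv(sset: ScenarioSet, path: Path | str) -> None:
    sset.to_frame().to_csv(path, index=False)


def default_scenarios() -> ScenarioSet:
    """The packaged 18-scenario L18 ensemble used to simulate every tumor."""
    with resources.as_file(
        resources.files("gliosim").joinpath("data/scenarios.csv")
    ) as p:
        return read_scenarios_csv(p)


@dataclass
class DesignReport:
    """Outcome of the ensemble balance checks; failures are content, not errors."""

    checks: list[tuple[str, str, str]]  # (name, status, detail); status pass/fail/n-a

    @property
    def passed(self) -> bool:
        return all(status != "fail" for _, status, _ in self.checks)

    def failures(self) -> list[tuple[str, str]]:
        return [(n, d) for n, s, d in self.checks if s == "fail"]

    def __str__(self) -> str:
        lines = []
        for name, status, detail in self.checks:
            lines.append(f"[{status.upper():4s}] {name}: {detail}")
        verdict = "DESIGN OK" if self.passed else "DESIGN INVALID"
        return "\n".join(lines + [verdict])


def validate_design(sset: ScenarioSet) -> DesignReport:
    """Check the Taguchi balance properties of a scenario ensemble.

    For a three-level design the checks are: (a) each of the 9 level pairs
    of the two most sensitive parameters (edema halving/doubling times)
    occurs exactly twice; (b) each of the 7 parameters takes exactly 3
    distinct levels, each occurring n/3 times; (c) the edema and enhancing
    density windows are disjoint in every scenario.  For non-three-level
    tables the balance checks are reported as not applicable; the window
    check always applies.
    """
    if len(sset) == 0:
        raise ValueError("empty scenario set")
    df = sset.to_frame()
    n = len(df)
    checks: list[tuple[str, str, str]] = []

    params = {
        "khat0": df["khat0_d"],
        "rhohat0": df["rhohat0_d"],
        "D_w": df["Dw_mm2_per_d"],
        "I_e": list(zip(df["Ie_lo"], df["Ie_hi"])),
        "I_c": list(zip(df["Ic_lo"], df["Ic_hi"])),
        "khat1": df["khat1_d"],
        "rhohat1": df["rhohat1_d"],
    }
    level_counts = {name: pd.Series(list(vals)).value_counts() for name, vals in params.items()}
    three_level = all(len(c) == 3 for c in level_counts.values()) and n % 3 == 0

    # (a) pair balance of the two most sensitive parameters
    if three_level and n % 9 == 0:
        pairs = pd.Series(list(zip(df["khat0_d"], df["rhohat0_d"]))).value_counts()
        want = n // 9
        bad = {p: int(c) for p, c in pairs.items() if c != want} if len(pairs) == 9 else dict(pairs)
        if len(pairs) == 9 and not bad:
            checks.append(
                ("pair-balance", "pass", f"all 9 (khat0, rhohat0) pairs occur {want}x")
            )
        else:
            checks.append(
                (
                    "pair-balance",
                    "fail",
                    f"expected 9 (khat0, rhohat0) pairs each {want}x, got {dict(pairs)}",
                )
            )
    else:
        checks.append(
            ("pair-balance", "n/a", "not a 3-level design with n divisible by 9")
        )

    # (b) per-parameter level balance
    if three_level:
        want = n // 3
        bad_params = {
            name: {lvl: int(c) for lvl, c in counts.items()}
            for name, counts in level_counts.items()
            if len(counts) != 3 or any(c != want for c in counts)
        }
        if not bad_params:
            checks.append(
                ("level-balance", "pass", f"7 parameters x 3 levels, each level {want}x")
            )
        else:
            checks.append(("level-balance", "fail", f"unbalanced: {bad_params}"))
    else:
        checks.append(("level-balance", "n/a", "not a 3-level design"))

    # (c) density-window disjointness within each scenario
    overlapping = [
        i
        for i, p in sset
        if not (0 < p.I_e[0] < p.I_e[1] < p.I_c[0] < p.I_c[1] <= 1)
    ]
    if not overlapping:
        checks.append(("window-disjoint", "pass", "I_e < I_c strictly in all scenarios"))
    else:
        checks.append(
            ("window-disjoint", "fail", f"I_e/I_c overlap or misordered in scenario(s) {overlapping}")
        )

    return DesignReport(checks)
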