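"""Farmland-cover scenario engine.

A scenario is (1) a deterministic relabelling of each region's main
agroecosystem and (2) a constraint set on the nine crop shares for each
target agroecosystem. Future shares are the feasible point of the 9-simplex
closest to the current shares in L1 distance ("minimal-disturbance"
reallocation), found by linear programming; among equally close solutions a
lexicographic secondary objective favours grassland retention.

Six scenarios mirroring plausible 2050 agricultural-policy pathways ship as
YAML defaults (status quo, global/regional biofuel, livestock
extensification, global/regional extensification). Only two of their
numbers are pinned by the study narrative — a 5% permanent-grassland floor
under global extensification and a 45% primary-crop cap under regional
extensification; the remaining bounds are an interpretive encoding of the
scenario descriptions and are meant to be edited.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linprog

from .synthetic import CROPS, Region

__all__ = [
    "SCENARIO_NAMES",
    "InfeasibleScenarioError",
    "ScenarioConfigError",
    "Bound",
    "GroupConstraint",
    "ConstraintSet",
    "ScenarioSpec",
    "load_scenario",
    "default_scenario",
    "transition_agroecosystems",
    "solve_crop_shares",
    "apply_scenario",
]

SCENARIO_NAMES = (
    "status_quo",
    "global_biofuel",
    "regional_biofuel",
    "livestock_extensification",
    "global_extensification",
    "regional_extensification",
)

_SIMPLEX_TOL = 1e-8
_CROP_INDEX = {c: i for i, c in enumerate(CROPS)}


class InfeasibleScenarioError(ValueError):
    """No crop composition satisfies the scenario's constraints."""


class ScenarioConfigError(ValueError):
    """Malformed or incomplete scenario specification."""


@dataclass
class Bound:
    """One bound on a share, resolved against the current value.

    The resolved value is ``abs`` if given, else ``rel * current + shift``
    (rel defaults to 1, shift to 0), then raised to ``floor`` and clipped by
    ``cap`` if given, and always clipped to [0, 1].
    """

    abs: float | None = None
    rel: float | None = None
    shift: float = 0.0
    cap: float | None = None
    floor: float | None = None

    def resolve(self, current: float) -> float:
        if self.abs is not None:
            v = self.abs
        else:
            v = (self.rel if self.rel is not None else 1.0) * current + self.shift
        if self.cap is not None:
            v = min(v, self.cap)
        if self.floor is not None:
            v = max(v, self.floor)
        return float(np.clip(v, 0.0, 1.0))

    @classmethod
    def parse(cls, spec) -> "Bound":
        if isinstance(spec, (int, float)):
            return cls(abs=float(spec))
        if isinstance(spec, Mapping):
            unknown = set(spec) - {"abs", "rel", "shift", "cap", "floor"}
            if unknown:
                raise ScenarioConfigError(f"unknown bound keys: {sorted(unknown)}")
            return cls(
                abs=spec.get("abs"),
                rel=spec.get("rel"),
                shift=float(spec.get("shift", 0.0)),
                cap=spec.get("cap"),
                floor=spec.get("floor"),
            )
        raise ScenarioConfigError(f"cannot parse bound spec {spec!r}")


@dataclass
class GroupConstraint:
    """A bound on the summed share of a crop group (e.g. COP crops)."""

    crops: tuple[str, ...]
    min: Bound | None = None
    max: Bound | None = None

    def indices(self) -> list[int]:
        try:
            return [_CROP_INDEX[c] for c in self.crops]
        except KeyError as e:
            raise ScenarioConfigError(f"unknown crop in group constraint: {e}") from None


@dataclass
class ConstraintSet:
    """Per-agroecosystem constraints on the nine crop shares."""

    lower: dict[str, Bound] = dc_field(default_factory=dict)
    upper: dict[str, Bound] = dc_field(default_factory=dict)
    groups: list[GroupConstraint] = dc_field(default_factory=list)
    primary_crop_cap: float | None = None
    fixed_crops: tuple[str, ...] = ()

    def resolve(self, current: np.ndarray) -> "ResolvedConstraints":
        lo = np.zeros(len(CROPS))
        hi = np.ones(len(CROPS))
        for crop, b in self.lower.items():
            lo[_CROP_INDEX[crop]] = max(lo[_CROP_INDEX[crop]], b.resolve(current[_CROP_INDEX[crop]]))
        for crop, b in self.upper.items():
            hi[_CROP_INDEX[crop]] = min(hi[_CROP_INDEX[crop]], b.resolve(current[_CROP_INDEX[crop]]))
        if self.primary_crop_cap is not None:
            hi = np.minimum(hi, self.primary_crop_cap)
        for crop in self.fixed_crops:
            i = _CROP_INDEX[crop]
            lo[i] = hi[i] = current[i]
        grp = []
        for g in self.groups:
            idx = g.indices()
            cur = float(current[idx].sum())
            gmin = g.min.resolve(cur) if g.min is not None else None
            gmax = g.max.resolve(cur) if g.max is not None else None
            grp.append((idx, gmin, gmax))
        return ResolvedConstraints(lower=lo, upper=hi, groups=grp)

    @classmethod
    def parse(cls, spec: Mapping) -> "ConstraintSet":
        unknown = set(spec) - {"lower", "upper", "groups", "primary_crop_cap", "fixed_crops"}
        if unknown:
            raise ScenarioConfigError(f"unknown constraint keys: {sorted(unknown)}")
        for side in ("lower", "upper"):
            for crop in spec.get(side, {}):
                if crop not in _CROP_INDEX:
                    raise ScenarioConfigError(f"unknown crop {crop!r} in {side} bounds")
        return cls(
            lower={c: Bound.parse(b) for c, b in spec.get("lower", {}).items()},
            upper={c: Bound.parse(b) for c, b in spec.get("upper", {}).items()},
            groups=[
                GroupConstraint(
                    crops=tuple(g["crops"]),
                    min=Bound.parse(g["min"]) if "min" in g else None,
                    max=Bound.parse(g["max"]) if "max" in g else None,
                )
                for g in spec.get("groups", [])
            ],
            primary_crop_cap=spec.get("primary_crop_cap"),
            fixed_crops=tuple(spec.get("fixed_crops", ())),
        )


@dataclass
class ResolvedConstraints:
    """Absolute bounds for one region, ready for the LP."""

    lower: np.ndarray
    upper: np.ndarray
    groups: list[tuple[list[int], float | None, float | None]]

    def violations(self, x: np.ndarray, tol: float = _SIMPLEX_TOL) -> list[str]:
        out = []
        for i, c in enumerate(CROPS):
            if x[i] < self.lower[i] - tol:
                out.append(f"{c} below lower bound {self.lower[i]:.4f}")
            if x[i] > self.upper[i] + tol:
                out.append(f"{c} above upper bound {self.upper[i]:.4f}")
        for idx, gmin, gmax in self.groups:
            s = float(x[idx].sum())
            names = "+".join(CROPS[i] for i in idx)
            if gmin is not None and s < gmin - tol:
                out.append(f"group {names} below {gmin:.4f}")
            if gmax is not None and s > gmax + tol:
                out.append(f"group {names} above {gmax:.4f}")
        if abs(x.sum() - 1.0) > tol:
            out.append(f"shares sum to {x.sum():.10f}")
        return out


@dataclass
class ScenarioSpec:
    """Named scenario: agroecosystem transitions plus per-target constraints."""

    name: str
    transitions: dict[str, str]
    constraints: dict[str, ConstraintSet]

    def constraint_set_for(self, target: str) -> ConstraintSet:
        return self.constraints.get(target, ConstraintSet())


def _scenario_from_dict(raw: Mapping) -> ScenarioSpec:
    if "name" not in raw:
        raise ScenarioConfigError("scenario is missing a 'name'")
    return ScenarioSpec(
        name=str(raw["name"]),
        transitions=dict(raw.get("transitions", {})),
        constraints={k: ConstraintSet.parse(v or {}) for k, v in raw.get("constraints", {}).items()},
    )


def load_scenario(path: str | Path) -> ScenarioSpec:
    """Load a scenario from a YAML file."""
    path = Path(path)
    if not path.exists():
        raise ScenarioConfigError(f"scenario file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _scenario_from_dict(raw)


def default_scenario(name: str) -> ScenarioSpec:
    """Load one of the six built-in scenarios by name."""
    if name not in SCENARIO_NAMES:
        raise ScenarioConfigError(
            f"unknown scenario {name!r}; built-ins are {', '.join(SCENARIO_NAMES)}"
        )
    ref = resources.files("farmbird") / "data" / "scenarios" / f"{name}.yaml"
    raw = yaml.safe_load(ref.read_text())
    return _scenario_from_dict(raw)


def transition_agroecosystems(
    regions: Sequence[Region],
    scenario: ScenarioSpec,
) -> dict[str, str]:
    """Map region_id -> target agroecosystem under the scenario's rules.

    Labels without a rule are a configuration error; identity rules leave
    labels unchanged.
    """
    present = {r.agroecosystem for r in regions}
    uncovered = present - set(scenario.transitions)
    if uncovered:
        raise ScenarioConfigError(
            f"scenario {scenario.name!r} has no transition rule for: {sorted(uncovered)}"
        )
    return {r.region_id: scenario.transitions[r.agroecosystem] for r in regions}


def solve_crop_shares(
    current_shares: np.ndarray,
    constraints: ConstraintSet | ResolvedConstraints,
    grassland_tiebreak: bool = True,
) -> np.ndarray:
    """Minimal-disturbance crop reallocation under constraints.

    Returns the point of the 9-simplex minimizing ``sum_k |x_k - current_k|``
    subject to the resolved bounds and group constraints, via LP (variables
    x and elementwise slack t >= |x - current|). If the current composition
    is already feasible it is returned unchanged. Ties among equally optimal
    solutions are broken by a secondary LP maximizing the permanent-grassland
    share (grassland retention) within the optimal L1 level set.
    """
    c0 = np.asarray(current_shares, dtype=float)
    if c0.shape != (len(CROPS),):
        raise ValueError(f"expected {len(CROPS)} current shares")
    if abs(c0.sum() - 1.0) > 1e-6 or (c0 < -1e-9).any():
        raise ValueError("current shares must lie on the simplex")
    rc = constraints.resolve(c0) if isinstance(constraints, ConstraintSet) else constraints
    if (rc.lower > rc.upper + _SIMPLEX_TOL).any():
        bad = [CROPS[i] for i in np.where(rc.lower > rc.upper + _SIMPLEX_TOL)[0]]
        raise InfeasibleScenarioError(f"empty bound interval for crops: {bad}")
    if not rc.violations(c0):
        return c0.copy()

    n = len(CROPS)
    # variables: x (n) then t (n); minimize sum(t)
    cost = np.concatenate([np.zeros(n), np.ones(n)])
    A_ub, b_ub = [], []
    for i in range(n):
        row = np.zeros(2 * n)
        row[i], row[n + i] = 1.0, -1.0  # x_i - t_i <= c_i
        A_ub.append(row)
        b_ub.append(c0[i])
        row = np.zeros(2 * n)
        row[i], row[n + i] = -1.0, -1.0  # -x_i - t_i <= -c_i
        A_ub.append(row)
        b_ub.append(-c0[i])
    for idx, gmin, gmax in rc.groups:
        if gmin is not None:
            row = np.zeros(2 * n)
            row[idx] = -1.0
            A_ub.append(row)
            b_ub.append(-gmin)
        if gmax is not None:
            row = np.zeros(2 * n)
            row[idx] = 1.0
            A_ub.append(row)
            b_ub.append(gmax)
    A_eq = [np.concatenate([np.ones(n), np.zeros(n)])]
    b_eq = [1.0]
    bounds = [(rc.lower[i], rc.upper[i]) for i in range(n)] + [(0, None)] * n

    res = linprog(cost, A_ub=np.array(A_ub), b_ub=np.array(b_ub),
                  A_eq=np.array(A_eq), b_eq=np.array(b_eq), bounds=bounds, method="highs")
    if not res.success:
        raise InfeasibleScenarioError(
            "no feasible crop composition; binding constraints: "
            + "; ".join(rc.violations(np.clip(c0, rc.lower, rc.upper)))
        )
    objective = float(res.fun)

    if grassland_tiebreak:
        # among L1-optimal points, maximize permanent grassland
        cost2 = np.zeros(2 * n)
        cost2[_CROP_INDEX["permanent_grassland"]] = -1.0
        A_ub2 = np.vstack([A_ub, cost])
        b_ub2 = np.array(b_ub + [objective + 1e-9])
        res2 = linprog(cost2, A_ub=A_ub2, b_ub=b_ub2, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                       bounds=bounds, method="highs")
        if res2.success:
            res = res2

    x = np.clip(res.x[:n], rc.lower, rc.upper)
    x = x / x.sum()  # polish to the simplex within 1e-8
    return x


def apply_scenario(
    regions: Sequence[Region],
    scenario: ScenarioSpec,
) -> tuple[list[Region], pd.DataFrame, pd.DataFrame]:
    """Run the two-step scenario pipeline over all regions.

    Step 1 relabels agroecosystems; step 2 solves each region's future crop
    composition under the target agroecosystem's constraints. Returns
    (future regions, per-region change table, national aggregate shares).
    National shares are area-weighted (region area as the UAA proxy).
    """
    targets = transition_agroecosystems(regions, scenario)
    out_regions: list[Region] = []
    recs = []
    for r in regions:
        target = targets[r.region_id]
        cs = scenario.constraint_set_for(target)
        try:
            future = solve_crop_shares(np.asarray(r.crop_shares, dtype=float), cs)
        except InfeasibleScenarioError as e:
            raise InfeasibleScenarioError(f"region {r.region_id}: {e}") from e
        nr = copy.deepcopy(r)
        nr.agroecosystem = target
        nr.crop_shares = future
        out_regions.append(nr)
        for crop, cur, fut in zip(CROPS, r.crop_shares, future):
            recs.append((r.region_id, target, crop, float(cur), float(fut), float(fut - cur)))
    changes = pd.DataFrame(
        recs, columns=["region_id", "agroecosystem", "crop", "current", "future", "delta"]
    )
    areas = np.array([r.area for r in regions])
    w = areas / areas.sum()
    cur_nat = np.array([r.crop_shares for r in regions]).T @ w
    fut_nat = np.array([r.crop_shares for r in out_regions]).T @ w
    national = pd.DataFrame(
        {"crop": CROPS, "current": cur_nat, "future": fut_nat, "delta": fut_nat - cur_nat}
    )
    return out_regions, changes, national
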