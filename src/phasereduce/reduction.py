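"""Assembling and scoring reduced-order models.

The reduction recipe: species pairs whose phase-loop hysteresis area falls
below a chosen threshold, and where one species' equation directly
references the other, have the downstream (dependent) species' differential
or implicit algebraic equation replaced by the explicit steady-state
relation fitted to its concentration clamp.  Model-specific simplifications
(conservation-of-mass elimination, free≈total approximations, negligible or
equal species) are user-declared actions, since they encode knowledge the
area matrix alone cannot supply.

Reduced species remain part of the model — they are still predicted, but by
explicit algebra instead of dynamics — so the reduced model's trajectories
can be scored state-by-state against the original.  The accuracy metric is
the mean over output times of |x_red − x_orig| divided by the original
state's dynamic range over the protocol, ×100 (a pointwise-relative variant
is available behind a switch).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .clamp import FittedRelation
from .models import ModelError, NetworkModel
from .phase import AreaMatrix
from .simulate import StimulusProtocol, simulate_transient

__all__ = [
    "ReductionAction",
    "ReductionPlan",
    "ErrorReport",
    "Scenario",
    "PlanError",
    "propose_plan",
    "apply_plan",
    "score_reduction",
    "run_perturbation_suite",
]

ACTIONS = (
    "keep_ode",
    "ode_to_algebraic",
    "implicit_to_explicit",
    "conservation_eliminate",
    "free_equals_total",
    "assume_negligible",
    "assume_equal",
)


class PlanError(ValueError):
    """Ill-formed reduction plan (cycles, missing fits, unknown states)."""


@dataclass
class ReductionAction:
    """One per-state reduction decision.

    ``driver`` names the upstream state for algebraic replacements, the
    total parameter for ``free_equals_total``, or the partner state for
    ``assume_equal``.  ``members`` lists the sibling states for
    ``conservation_eliminate`` (the target is computed as total − Σ others).
    ``justification`` carries free text plus the pair's loop area.
    """

    target: str
    action: str
    driver: str | None = None
    members: tuple[str, ...] = ()
    area: float | None = None
    justification: str = ""

    def __post_init__(self):
        if self.action not in ACTIONS:
            raise PlanError(f"unknown action {self.action!r}")
        needs_driver = ("ode_to_algebraic", "implicit_to_explicit",
                        "free_equals_total", "assume_equal")
        if self.action in needs_driver and not self.driver:
            raise PlanError(f"action {self.action} on {self.target} needs a driver")
        if self.action == "conservation_eliminate" and not (
                self.driver and self.members):
            raise PlanError(
                "conservation_eliminate needs the total parameter (driver) "
                "and the member states")


@dataclass
class ReductionPlan:
    """Ordered reduction actions plus the area threshold that produced them."""

    actions: list[ReductionAction]
    threshold: float
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for a in self.actions:
            if a.target in seen:
                raise PlanError(f"state {a.target} receives two actions")
            seen.add(a.target)
        self._check_cycles()

    def _check_cycles(self):
        """Reject plans where reduced states depend on each other cyclically."""
        dep = {a.target: a.driver for a in self.actions
               if a.action in ("ode_to_algebraic", "implicit_to_explicit",
                               "assume_equal") and a.driver}
        for start in dep:
            seen = [start]
            cur = dep.get(start)
            while cur is not None:
                if cur == start:
                    raise PlanError(f"cyclic reduction dependency: "
                                    f"{' -> '.join(seen + [cur])}")
                if cur in seen:
                    break
                seen.append(cur)
                cur = dep.get(cur)

    @property
    def reduced_states(self) -> list[str]:
        return [a.target for a in self.actions if a.action != "keep_ode"]

    def to_json(self, path=None) -> str:
        doc = {
            "threshold": self.threshold,
            "notes": self.notes,
            "actions": [
                {"target": a.target, "action": a.action, "driver": a.driver,
                 "members": list(a.members), "area": a.area,
                 "justification": a.justification}
                for a in self.actions],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def propose_plan(
    am: AreaMatrix,
    classes: Mapping[tuple[str, str], str],
    model: NetworkModel,
    threshold: float = 0.05,
    extra_actions: Iterable[ReductionAction] = (),
) -> ReductionPlan:
    """Derive a reduction plan from the direct-pair area classification.

    Every direct pair with area ≤ ``threshold`` contributes an algebraic
    replacement of its downstream state (the one whose equation references
    the other).  Mutually-dependent pairs are not auto-reduced; they are
    recorded in the plan notes for user intervention.  ``extra_actions``
    carries user-declared conservation/total approximations.
    """
    deps = model.dependencies or {}
    notes: list[str] = []
    candidates: dict[str, tuple[float, str]] = {}  # target -> (area, driver)
    for (a, b), cls in classes.items():
        area = am.area(a, b)
        if area > threshold:
            continue
        a_dep_b = b in deps.get(a, set())
        b_dep_a = a in deps.get(b, set())
        if a_dep_b and b_dep_a:
            notes.append(
                f"pair ({a}, {b}) area {area:.4f} is mutually dependent; "
                "not auto-reduced, supply an explicit action")
            continue
        if a_dep_b:
            target, driver = a, b
        elif b_dep_a:
            target, driver = b, a
        else:
            continue  # not a direct pair
        if model.kinds.get(target) not in ("ode", "implicit_algebraic"):
            continue
        if target not in candidates or area < candidates[target][0]:
            candidates[target] = (area, driver)

    extra = list(extra_actions)
    taken = {a.target for a in extra}
    actions = list(extra)
    for target, (area, driver) in sorted(candidates.items()):
        if target in taken:
            continue
        kind = model.kinds[target]
        act = ("ode_to_algebraic" if kind == "ode" else "implicit_to_explicit")
        actions.append(ReductionAction(
            target=target, action=act, driver=driver, area=area,
            justification=f"direct pair area {area:.4f} <= {threshold:g}"))
        taken.add(target)
    for s in model.states:
        if s not in taken and model.kinds[s] == "ode":
            actions.append(ReductionAction(target=s, action="keep_ode"))
    return ReductionPlan(actions=actions, threshold=threshold, notes=notes)


def apply_plan(
    model: NetworkModel,
    plan: ReductionPlan,
    fits: Mapping[str, FittedRelation] | None = None,
) -> NetworkModel:
    """Materialize a reduction plan as a new :class:`NetworkModel`.

    Reduced states become ``explicit_algebraic`` (they are still predicted);
    algebraic replacements evaluate the attached fitted relation at the
    driver state's current value, in dependency order so chained reductions
    compose.
    """
    fits = dict(fits or {})
    new = model.copy()
    deps = {k: set(v) for k, v in (model.dependencies or {}).items()}

    def drop_equation(state):
        kind = new.kinds[state]
        if kind == "ode":
            del new.ode_funcs[state]
        elif kind == "implicit_algebraic":
            del new.residual_funcs[state]
        elif kind == "explicit_algebraic":
            del new.explicit_funcs[state]

    for a in plan.actions:
        if a.target not in new.states:
            raise PlanError(f"plan targets unknown state {a.target!r}")
        if a.action == "keep_ode":
            continue
        drop_equation(a.target)
        new.expressions.pop(a.target, None)  # the old equation no longer holds
        idx_target = new.index(a.target)
        if a.action in ("ode_to_algebraic", "implicit_to_explicit"):
            fit = fits.get(a.target)
            if fit is None:
                raise PlanError(
                    f"{a.action} on {a.target} requires a fitted relation")
            if fit.clamped != a.driver:
                raise PlanError(
                    f"fit for {a.target} is driven by {fit.clamped!r}, plan "
                    f"says {a.driver!r}")
            didx = new.index(a.driver)
            new.explicit_funcs[a.target] = (
                lambda y, p, _f=fit, _i=didx: float(_f.predict(y[_i])))
            deps[a.target] = {a.driver}
            new.expressions[a.target] = fit.expression(a.driver)
        elif a.action == "conservation_eliminate":
            if a.driver not in new.params:
                raise PlanError(f"total parameter {a.driver!r} not found")
            midx = [new.index(m) for m in a.members]
            new.explicit_funcs[a.target] = (
                lambda y, p, _t=a.driver, _m=tuple(midx):
                float(p[_t] - sum(y[i] for i in _m)))
            deps[a.target] = set(a.members)
            new.expressions[a.target] = f"{a.driver} - {' - '.join(a.members)}"
        elif a.action == "free_equals_total":
            if a.driver not in new.params:
                raise PlanError(f"total parameter {a.driver!r} not found")
            new.explicit_funcs[a.target] = (
                lambda y, p, _t=a.driver: float(p[_t]))
            deps[a.target] = set()
            new.expressions[a.target] = a.driver
        elif a.action == "assume_negligible":
            new.explicit_funcs[a.target] = lambda y, p: 0.0
            deps[a.target] = set()
            new.expressions[a.target] = "0"
        elif a.action == "assume_equal":
            oidx = new.index(a.driver)
            new.explicit_funcs[a.target] = (
                lambda y, p, _i=oidx: float(y[_i]))
            deps[a.target] = {a.driver}
            new.expressions[a.target] = a.driver
        new.kinds[a.target] = "explicit_algebraic"

    return NetworkModel(
        name=f"{model.name}_reduced{sum(1 for s in new.states if new.kinds[s] == 'ode')}",
        states=list(new.states),
        kinds=dict(new.kinds),
        params=dict(new.params),
        ode_funcs=dict(new.ode_funcs),
        residual_funcs=dict(new.residual_funcs),
        explicit_funcs=dict(new.explicit_funcs),
        conserved_totals=[(t, list(m)) for t, m in new.conserved_totals],
        dependencies=deps,
        initial=dict(new.initial),
        expressions=dict(new.expressions),
    )


@dataclass
class ErrorReport:
    """Per-state accuracy of a reduced model against the original.

    ``per_state`` maps state → mean error in percent; ``overall`` is the
    arithmetic mean over included states.  ``metric`` is ``"range"``
    (|Δ| / dynamic range of the original) or ``"relative"`` (pointwise
    |Δ| / max(|x_orig|, floor)).
    """

    per_state: dict[str, float]
    overall: float
    protocol: str
    excluded: list[str] = field(default_factory=list)
    metric: str = "range"
    insensitive_params: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        doc = {"per_state_pct": self.per_state, "overall_pct": self.overall,
               "protocol": self.protocol, "excluded": self.excluded,
               "metric": self.metric,
               "insensitive_params": self.insensitive_params}
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_csv(self, path) -> None:
        rows = [{"species": s, "mean_error_pct": e}
                for s, e in self.per_state.items()]
        rows.append({"species": "Mean", "mean_error_pct": self.overall})
        pd.DataFrame(rows).to_csv(path, index=False)


def score_reduction(
    original: NetworkModel,
    reduced: NetworkModel,
    protocol: StimulusProtocol,
    excluded: Iterable[str] = (),
    metric: str = "range",
    rel_floor: float = 1e-3,
) -> ErrorReport:
    """Simulate both models under the protocol and report per-state errors.

    States fixed under the protocol or removed by the plan should be passed
    as ``excluded``; a state present in one model's output but absent from
    the other and not excluded is an error.
    """
    if metric not in ("range", "relative"):
        raise ValueError("metric must be 'range' or 'relative'")
    excluded = list(excluded)
    tco = simulate_transient(original, protocol)
    tcr = simulate_transient(reduced, protocol)
    per_state: dict[str, float] = {}
    for s in tco.states:
        if s in excluded:
            continue
        if s not in tcr.states:
            raise ModelError(
                f"state {s!r} missing from reduced model output and not excluded")
        xo, xr = tco[s], tcr[s]
        diff = np.abs(xr - xo)
        if metric == "range":
            rng = float(xo.max() - xo.min())
            if rng <= 0:
                excluded.append(s)
                continue
            err = float(np.mean(diff) / rng * 100.0)
        else:
            err = float(np.mean(diff / np.maximum(np.abs(xo), rel_floor)) * 100.0)
        per_state[s] = err
    if not per_state:
        raise ModelError("no states left to score after exclusions")
    return ErrorReport(
        per_state=per_state,
        overall=float(np.mean(list(per_state.values()))),
        protocol=tco.provenance,
        excluded=excluded,
        metric=metric,
    )


@dataclass(frozen=True)
class Scenario:
    """A named perturbation: a transient protocol plus fixed overrides."""

    name: str
    protocol: StimulusProtocol
    overrides: Mapping[str, float] = field(default_factory=dict)


def run_perturbation_suite(
    original: NetworkModel,
    reduced: NetworkModel,
    scenarios: Iterable[Scenario],
    excluded: Iterable[str] = (),
    metric: str = "range",
) -> dict[str, ErrorReport]:
    """Score the reduced model under each perturbation scenario.

    Scenario parameters structurally absent from the reduced model are
    reported via ``insensitive_params`` (the reduced model simply cannot
    respond to them); the scenario still runs, with the missing parameter
    injected inertly so trajectories remain comparable.
    """
    reports: dict[str, ErrorReport] = {}
    for sc in scenarios:
        insens = []
        red = reduced.copy()
        wanted = dict(sc.overrides)
        wanted[sc.protocol.parameter] = sc.protocol.off_value
        for p, v in wanted.items():
            if p not in red.params:
                red.params[p] = v  # inert: nothing references it
                insens.append(p)
        orig = original.with_params(dict(sc.overrides))
        red = red.with_params({p: v for p, v in sc.overrides.items()})
        report = score_reduction(orig, red, sc.protocol,
                                 excluded=excluded, metric=metric)
        report.insensitive_params = insens
        reports[sc.name] = report
    return reports
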