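"""Concentration clamps and explicit steady-state relation fitting.

A concentration clamp holds one species fixed while the rest of the system
relaxes to steady state, sweeping the clamped value over a range to trace
the steady-state input–response curve between a species pair.  Fitting a
simple saturating or linear form to that curve yields the explicit algebraic
relationship that replaces the fast species' differential (or implicit
algebraic) equation during model reduction.

Candidate forms (x = clamped driver, y = response, concentrations in µM):

``hill``         y = y_max · x^h / (K^h + x^h),  K > 0, h > 0
``linear``       y = slope·x + intercept
``exponential``  y = amplitude · (1 − exp(−rate·x)) + offset   (saturating)
``power``        y = coefficient · x^exponent

Fitting is nonlinear least squares (lmfit/Levenberg–Marquardt) with
multi-start over the Hill coefficient when the first attempt stalls; form
selection is automatic by least root-mean-square error but can be
constrained by passing a single candidate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import lmfit

from .models import NetworkModel
from .phase import PhaseLoop
from .simulate import SteadyStateError, find_steady_state

__all__ = [
    "ClampCurve",
    "FittedRelation",
    "FitError",
    "concentration_clamp",
    "default_sweep",
    "fit_relation",
    "compare_clamp_to_loop",
    "FORMS",
]

FORMS = ("hill", "linear", "exponential", "power")


class FitError(RuntimeError):
    """No candidate form could be fitted to the clamp curve."""


@dataclass
class ClampCurve:
    """Steady-state responses of ``record`` while ``clamped`` is swept.

    ``flagged`` indexes sweep points where the steady-state search failed or
    conservation was violated; they are kept (as NaN responses) rather than
    silently dropped.
    """

    clamped: str
    record: str
    sweep: np.ndarray
    response: np.ndarray
    context: dict[str, float] = field(default_factory=dict)
    flagged: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.sweep = np.asarray(self.sweep, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.sweep.shape != self.response.shape:
            raise ValueError("sweep and response must align")
        if len(self.sweep) and not np.all(np.diff(self.sweep) > 0):
            raise ValueError("sweep must be strictly increasing")

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        ok = np.isfinite(self.response)
        return self.sweep[ok], self.response[ok]

    @property
    def domain(self) -> tuple[float, float]:
        x, _ = self.valid()
        return float(x.min()), float(x.max())

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame({"clamp_value": self.sweep,
                      "response": self.response}).to_csv(path, index=False)


_FORM_PARAMS = {
    "hill": ("y_max", "K", "h"),
    "linear": ("slope", "intercept"),
    "exponential": ("amplitude", "rate", "offset"),
    "power": ("coefficient", "exponent"),
}


def _form_eval(form: str, p: Mapping[str, float], x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if form == "hill":
        xs = np.maximum(x, 0.0)
        return p["y_max"] * xs ** p["h"] / (p["K"] ** p["h"] + xs ** p["h"])
    if form == "linear":
        return p["slope"] * x + p["intercept"]
    if form == "exponential":
        return p["amplitude"] * (1.0 - np.exp(-p["rate"] * x)) + p["offset"]
    if form == "power":
        return p["coefficient"] * np.maximum(x, 0.0) ** p["exponent"]
    raise ValueError(f"unknown form {form!r}")


@dataclass
class FittedRelation:
    """An explicit algebraic form fitted to a clamp curve."""

    form: str
    parameters: dict[str, float]
    rmse: float
    domain: tuple[float, float]
    clamped: str = ""
    record: str = ""

    def __post_init__(self):
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        if self.form == "hill" and not (self.parameters["K"] > 0
                                        and self.parameters["h"] > 0):
            raise ValueError("hill requires K > 0 and h > 0")
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")

    def predict(self, x, *, allow_extrapolation: bool = True) -> np.ndarray:
        """Evaluate the fitted form.  Outside the fitted domain either warn
        (default, via the ``extrapolated`` attribute of the result check) or
        raise if ``allow_extrapolation`` is False."""
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        outside = (x < lo - 1e-12) | (x > hi + 1e-12)
        if np.any(outside) and not allow_extrapolation:
            raise ValueError(
                f"{self.form} fit for {self.record} evaluated outside its "
                f"fitted domain [{lo:g}, {hi:g}]")
        return _form_eval(self.form, self.parameters, x)

    def is_extrapolating(self, x) -> bool:
        x = np.asarray(x, dtype=float)
        lo, hi = self.domain
        return bool(np.any((x < lo - 1e-12) | (x > hi + 1e-12)))

    def expression(self, var: str) -> str:
        """The fitted form as a sympy-parseable expression in ``var``,
        with parameter values substituted (for declarative serialization)."""
        p = self.parameters
        if self.form == "hill":
            return (f"{p['y_max']!r}*{var}**{p['h']!r}/"
                    f"({p['K']!r}**{p['h']!r} + {var}**{p['h']!r})")
        if self.form == "linear":
            return f"{p['slope']!r}*{var} + {p['intercept']!r}"
        if self.form == "exponential":
            return (f"{p['amplitude']!r}*(1 - exp(-{p['rate']!r}*{var})) "
                    f"+ {p['offset']!r}")
        return f"{p['coefficient']!r}*{var}**{p['exponent']!r}"

    def to_json(self, path=None) -> str:
        doc = {
            "form": self.form,
            "parameters": self.parameters,
            "rmse_uM": self.rmse,
            "domain_uM": list(self.domain),
            "clamped": self.clamped,
            "record": self.record,
            "units": {"concentration": "uM"},
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "FittedRelation":
        doc = json.loads(text)
        return cls(form=doc["form"], parameters=doc["parameters"],
                   rmse=doc["rmse_uM"], domain=tuple(doc["domain_uM"]),
                   clamped=doc.get("clamped", ""), record=doc.get("record", ""))


def default_sweep(tc, state: str, n_points: int = 25, *,
                  log_spacing: bool = False) -> np.ndarray:
    """Sweep grid for a clamp: 0 to 1.5× the state's maximum over the
    reference transient, covering slightly beyond the observed range."""
    top = 1.5 * float(np.max(tc[state]))
    if top <= 0:
        raise ValueError(f"state {state!r} never leaves zero in the reference "
                         "transient; nothing to sweep")
    if log_spacing:
        return np.geomspace(max(top * 1e-4, 1e-9), top, n_points)
    return np.linspace(0.0, top, n_points)


def concentration_clamp(
    model: NetworkModel,
    clamp: str,
    values: Sequence[float],
    record: str,
    context: Mapping[str, float] | None = None,
) -> ClampCurve:
    """Sweep ``clamp`` over ``values``, recording ``record`` at steady state.

    For each sweep value the clamped state's dynamics are frozen at that
    value (its equation is removed and the value fixed) and the remaining
    system is run to steady state under the fixed-input ``context``.
    Non-convergent sweep points and conservation violations are flagged,
    never silently dropped.
    """
    context = dict(context or {})
    values = np.asarray(values, dtype=float)
    responses = np.full(len(values), np.nan)
    flagged: list[int] = []
    guess: dict[str, float] | None = None
    for i, v in enumerate(values):
        cm = model.clamp_state(clamp, float(v))
        try:
            ss = find_steady_state(cm, context, x0=guess)
        except SteadyStateError:
            flagged.append(i)
            continue
        y = cm.full_state({s: ss[s] for s in cm.dynamic_states})
        if cm.check_conservation(y):
            flagged.append(i)
            continue
        responses[i] = ss[record]
        guess = {s: ss[s] for s in cm.dynamic_states}  # warm start next point
    return ClampCurve(clamped=clamp, record=record, sweep=values,
                      response=responses, context=context, flagged=flagged)


def _initial_params(form: str, x: np.ndarray, y: np.ndarray) -> lmfit.Parameters:
    p = lmfit.Parameters()
    ymax = float(np.max(np.abs(y))) or 1.0
    if form == "hill":
        half = ymax / 2.0
        above = x[y >= half]
        k0 = float(above[0]) if len(above) and above[0] > 0 else float(
            np.median(x[x > 0]) if np.any(x > 0) else 1.0)
        p.add("y_max", value=float(np.max(y)), min=0.0)
        p.add("K", value=max(k0, 1e-9), min=1e-12)
        p.add("h", value=1.0, min=1e-3, max=50.0)
    elif form == "linear":
        slope = np.polyfit(x, y, 1)
        p.add("slope", value=float(slope[0]))
        p.add("intercept", value=float(slope[1]))
    elif form == "exponential":
        p.add("amplitude", value=float(y[-1] - y[0]) or ymax)
        span = float(x.max() - x.min()) or 1.0
        p.add("rate", value=2.0 / span, min=1e-12)
        p.add("offset", value=float(y[0]))
    elif form == "power":
        p.add("coefficient", value=ymax / max(float(x.max()), 1e-9))
        p.add("exponent", value=1.0, min=1e-3, max=10.0)
    return p


def _fit_one(form: str, x: np.ndarray, y: np.ndarray) -> tuple[dict, float] | None:
    def residual(pars):
        vals = {k: pars[k].value for k in pars}
        return _form_eval(form, vals, x) - y

    starts = [None]
    if form == "hill":
        starts = [None, 0.5, 2.0, 4.0]
    best = None
    for h0 in starts:
        pars = _initial_params(form, x, y)
        if h0 is not None:
            pars["h"].value = h0
        try:
            out = lmfit.minimize(residual, pars, method="leastsq")
        except Exception:
            continue
        if not np.all(np.isfinite(out.residual)):
            continue
        rmse = float(np.sqrt(np.mean(out.residual ** 2)))
        if best is None or rmse < best[1]:
            best = ({k: float(out.params[k].value) for k in out.params}, rmse)
        if best[1] < 1e-12:
            break
    return best


def fit_relation(
    curve: ClampCurve,
    candidate_forms: Iterable[str] = FORMS,
) -> FittedRelation:
    """Fit each candidate form to the clamp curve and return the best.

    Selection is by least rmse (automating the manual choice of functional
    form); pass a single-element ``candidate_forms`` to override.  Requires
    at least 4 valid sweep points and more points than parameters.
    """
    x, y = curve.valid()
    if len(x) < 4:
        raise FitError("need at least 4 valid sweep points")
    results = {}
    for form in candidate_forms:
        if form not in FORMS:
            raise ValueError(f"unknown candidate form {form!r}")
        if len(x) <= len(_FORM_PARAMS[form]):
            continue
        got = _fit_one(form, x, y)
        if got is not None:
            results[form] = got
    if not results:
        raise FitError(
            f"no candidate form converged for {curve.record} vs {curve.clamped}")
    # least rmse wins; numerically tied fits go to the most parsimonious form
    best_rmse = min(r[1] for r in results.values())
    tie_tol = best_rmse * 1e-6 + 1e-10 * max(1.0, float(np.max(np.abs(y))))
    parsimony = {"linear": 0, "power": 1, "exponential": 2, "hill": 3}
    form = min((f for f in results if results[f][1] <= best_rmse + tie_tol),
               key=lambda f: parsimony[f])
    params, rmse = results[form]
    return FittedRelation(form=form, parameters=params, rmse=rmse,
                          domain=(float(x.min()), float(x.max())),
                          clamped=curve.clamped, record=curve.record)


def compare_clamp_to_loop(
    curve: ClampCurve,
    loop: PhaseLoop,
    ranges: Mapping[str, tuple[float, float]],
) -> dict[str, float]:
    """Normalized deviation between a phase loop and its clamp curve.

    The clamp curve is mapped into the loop's normalized coordinates using
    the per-state (x_min, x_max) from ``ranges``, interpolated at each loop
    abscissa, and compared with the loop ordinate.  Returns max and mean
    absolute deviation (dimensionless) plus an ``extrapolated`` flag when
    the clamp sweep does not cover the loop's abscissa range.
    """
    if {curve.clamped, curve.record} != {loop.x_name, loop.y_name}:
        raise ValueError("clamp curve and loop refer to different state pairs")
    if curve.clamped != loop.x_name:
        loop = loop.swapped()
    xs, ys = curve.valid()
    xlo, xhi = ranges[loop.x_name]
    ylo, yhi = ranges[loop.y_name]
    xn = (xs - xlo) / (xhi - xlo)
    yn = (ys - ylo) / (yhi - ylo)
    extrapolated = bool(loop.x.min() < xn.min() - 1e-9
                        or loop.x.max() > xn.max() + 1e-9)
    pred = np.interp(loop.x, xn, yn)
    dev = np.abs(pred - loop.y)
    return {"max_deviation": float(dev.max()),
            "mean_deviation": float(dev.mean()),
            "extrapolated": extrapolated}
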