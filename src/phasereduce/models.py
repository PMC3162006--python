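"""Executable representations of biochemical reaction networks.

A :class:`NetworkModel` is a differential-algebraic description of a
reaction system.  Every state variable has exactly one *kind*:

``ode``
    evolved by a differential equation ``d[x]/dt = f(t, y, params)``;
``implicit_algebraic``
    constrained by a residual equation ``g(y, params) = 0`` that is solved
    alongside the ODEs (semi-explicit index-1 treatment);
``explicit_algebraic``
    computed directly from other states, ``x = h(y, params)``;
``parameterized``
    held at the value of the like-named parameter.

All concentrations are in µM, all times in seconds, first-order rates in
s⁻¹ and zeroth-order fluxes in µM s⁻¹.

Models can be built three ways: programmatically from per-state callables,
symbolically from rate-expression strings (:func:`build_model`), or from a
declarative text file (:mod:`phasereduce.modelfile`).  Symbolic construction
is preferred because it yields exact state-dependency information, which the
reduction machinery uses to enumerate *direct* species pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "NetworkModel",
    "SyntheticCascadeSpec",
    "ModelError",
    "build_model",
    "make_toy_model",
    "generate_cascade",
    "random_cascade_spec",
    "TOY_STIMULUS_PARAM",
]

VALID_KINDS = ("ode", "implicit_algebraic", "explicit_algebraic", "parameterized")

#: name of the toy model's switchable input parameter
TOY_STIMULUS_PARAM = "k1"


class ModelError(ValueError):
    """Raised for ill-posed model definitions or evaluation failures."""


@dataclass
class NetworkModel:
    """A DAE reaction system over a fixed ordered set of state variables.

    The *full state vector* ``y`` used by every callable is ordered like
    :attr:`states` and contains a value for every state regardless of kind.
    The simulator integrates only the dynamic (ode + implicit) entries and
    fills in explicit/parameterized entries before each evaluation.

    Parameters
    ----------
    name : str
        Identifier carried into provenance records.
    states : sequence of str
        Ordered state-variable names.
    kinds : mapping state -> kind
        One of :data:`VALID_KINDS` per state.
    params : mapping str -> float
        Parameter values (µM, s⁻¹, µM⁻¹s⁻¹ or µM s⁻¹ as appropriate).
    ode_funcs : mapping state -> f(t, y, params) -> float
        Time derivative of each ``ode`` state.
    residual_funcs : mapping state -> g(y, params) -> float
        Residual defining each ``implicit_algebraic`` state.
    explicit_funcs : mapping state -> h(y, params) -> float
        Value of each ``explicit_algebraic`` state.  Evaluated in a
        dependency-consistent (topological) order.
    conserved_totals : list of (total parameter name, member states)
        Conservation constraints checked along trajectories.
    dependencies : mapping state -> set of states, optional
        Which states each state's defining expression references.  Supplied
        automatically by the symbolic builders; required for direct-pair
        analysis when constructing from raw callables.
    initial : mapping state -> float, optional
        Resting initial guesses (defaults to zero).
    """

    name: str
    states: list[str]
    kinds: dict[str, str]
    params: dict[str, float]
    ode_funcs: dict[str, Callable] = field(default_factory=dict)
    residual_funcs: dict[str, Callable] = field(default_factory=dict)
    explicit_funcs: dict[str, Callable] = field(default_factory=dict)
    conserved_totals: list[tuple[str, list[str]]] = field(default_factory=list)
    dependencies: dict[str, set[str]] | None = None
    initial: dict[str, float] = field(default_factory=dict)
    expressions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = list(self.states)
        for s in self.states:
            kind = self.kinds.get(s)
            if kind not in VALID_KINDS:
                raise ModelError(f"state {s!r} has invalid kind {kind!r}")
        if set(self.kinds) != set(self.states):
            raise ModelError("kinds must cover exactly the declared states")
        if set(self.ode_funcs) != set(self.ode_states):
            raise ModelError("ode_funcs must cover exactly the ode states")
        if set(self.residual_funcs) != set(self.implicit_states):
            raise ModelError("residual_funcs must cover exactly the implicit states")
        if set(self.explicit_funcs) != set(self.explicit_states):
            raise ModelError("explicit_funcs must cover exactly the explicit states")
        for total, members in self.conserved_totals:
            if total not in self.params:
                raise ModelError(f"conserved total {total!r} is not a parameter")
            for m in members:
                if m not in self.states:
                    raise ModelError(f"conserved member {m!r} is not a state")
        self._index = {s: i for i, s in enumerate(self.states)}
        self._explicit_order = self._topo_explicit_order()

    # -- state bookkeeping -------------------------------------------------

    @property
    def ode_states(self) -> list[str]:
        return [s for s in self.states if self.kinds[s] == "ode"]

    @property
    def implicit_states(self) -> list[str]:
        return [s for s in self.states if self.kinds[s] == "implicit_algebraic"]

    @property
    def explicit_states(self) -> list[str]:
        return [s for s in self.states if self.kinds[s] == "explicit_algebraic"]

    @property
    def parameterized_states(self) -> list[str]:
        return [s for s in self.states if self.kinds[s] == "parameterized"]

    @property
    def dynamic_states(self) -> list[str]:
        """States carried by the integrator: ode then implicit, model order."""
        return [s for s in self.states
                if self.kinds[s] in ("ode", "implicit_algebraic")]

    def index(self, state: str) -> int:
        try:
            return self._index[state]
        except KeyError:
            raise ModelError(f"unknown state {state!r}") from None

    def _topo_explicit_order(self) -> list[str]:
        """Order explicit states so each is computed after the states it reads."""
        exp = self.explicit_states
        if not exp:
            return []
        deps = self.dependencies or {}
        remaining = list(exp)
        ordered: list[str] = []
        placed = set(self.states) - set(exp)
        guard = 0
        while remaining:
            progressed = False
            for s in list(remaining):
                need = {d for d in deps.get(s, set()) if d in exp}
                if need <= set(ordered):
                    ordered.append(s)
                    placed.add(s)
                    remaining.remove(s)
                    progressed = True
            guard += 1
            if not progressed:
                raise ModelError(
                    f"cyclic explicit-state dependencies among {remaining}")
            if guard > len(exp) + 1:  # pragma: no cover
                raise ModelError("explicit ordering failed to terminate")
        return ordered

    # -- evaluation --------------------------------------------------------

    def fill_full_state(self, y_full: np.ndarray) -> np.ndarray:
        """Overwrite parameterized and explicit entries of ``y_full`` in place."""
        for s in self.parameterized_states:
            y_full[self._index[s]] = self.params[s]
        for s in self._explicit_order:
            y_full[self._index[s]] = self.explicit_funcs[s](y_full, self.params)
        return y_full

    def full_state(self, dynamic_values: Mapping[str, float] | Sequence[float]) -> np.ndarray:
        """Assemble a full state vector from dynamic-state values."""
        y = np.zeros(len(self.states))
        dyn = self.dynamic_states
        if isinstance(dynamic_values, Mapping):
            for s in dyn:
                y[self._index[s]] = dynamic_values[s]
        else:
            vals = np.asarray(dynamic_values, dtype=float)
            if vals.shape != (len(dyn),):
                raise ModelError(
                    f"expected {len(dyn)} dynamic values, got shape {vals.shape}")
            for s, v in zip(dyn, vals):
                y[self._index[s]] = v
        return self.fill_full_state(y)

    def rhs(self, t: float, y_full: np.ndarray, params: Mapping[str, float] | None = None):
        """Time derivatives of the ode states, in :attr:`ode_states` order."""
        p = self.params if params is None else params
        return np.array([self.ode_funcs[s](t, y_full, p) for s in self.ode_states])

    def residuals(self, y_full: np.ndarray, params: Mapping[str, float] | None = None):
        """Residuals of the implicit states, in :attr:`implicit_states` order."""
        p = self.params if params is None else params
        return np.array([self.residual_funcs[s](y_full, p) for s in self.implicit_states])

    def explicit(self, y_full: np.ndarray, params: Mapping[str, float] | None = None):
        """Values of the explicit states, in :attr:`explicit_states` order."""
        p = self.params if params is None else params
        y = np.array(y_full, dtype=float)
        for s in self._explicit_order:
            y[self._index[s]] = self.explicit_funcs[s](y, p)
        return np.array([y[self._index[s]] for s in self.explicit_states])

    def check_conservation(self, y_full: np.ndarray, rtol: float = 1e-6) -> list[str]:
        """Return the names of violated conservation totals (empty if none)."""
        bad = []
        for total, members in self.conserved_totals:
            tot = self.params[total]
            s = sum(y_full[self._index[m]] for m in members)
            if abs(s - tot) > rtol * max(abs(tot), 1e-12):
                bad.append(total)
        return bad

    # -- derived copies ----------------------------------------------------

    def with_params(self, overrides: Mapping[str, float]) -> "NetworkModel":
        """Copy of the model with parameter values overridden."""
        unknown = set(overrides) - set(self.params)
        if unknown:
            raise ModelError(f"unknown parameters {sorted(unknown)}")
        new = self.copy()
        new.params.update(overrides)
        return new

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            name=self.name,
            states=list(self.states),
            kinds=dict(self.kinds),
            params=dict(self.params),
            ode_funcs=dict(self.ode_funcs),
            residual_funcs=dict(self.residual_funcs),
            explicit_funcs=dict(self.explicit_funcs),
            conserved_totals=[(t, list(m)) for t, m in self.conserved_totals],
            dependencies=None if self.dependencies is None
            else {k: set(v) for k, v in self.dependencies.items()},
            initial=dict(self.initial),
            expressions=dict(self.expressions),
        )

    def clamp_state(self, state: str, value: float) -> "NetworkModel":
        """Freeze ``state`` at ``value``: it becomes parameterized and its
        defining equation is dropped (the literal concentration clamp)."""
        if state not in self.states:
            raise ModelError(f"unknown state {state!r}")
        new = self.copy()
        kind = new.kinds[state]
        if kind == "parameterized":
            pass
        elif kind == "ode":
            del new.ode_funcs[state]
        elif kind == "implicit_algebraic":
            del new.residual_funcs[state]
        else:
            del new.explicit_funcs[state]
        new.kinds[state] = "parameterized"
        new.params[state] = float(value)
        new.name = f"{self.name}[{state}={value:g}]"
        return NetworkModel(**{f: getattr(new, f) for f in (
            "name", "states", "kinds", "params", "ode_funcs", "residual_funcs",
            "explicit_funcs", "conserved_totals", "dependencies", "initial",
            "expressions")})

    # -- structure ---------------------------------------------------------

    def direct_pairs(self) -> list[tuple[str, str]]:
        """Unordered pairs (u, v) where one state's defining expression
        references the other.  Requires dependency information."""
        if self.dependencies is None:
            raise ModelError(
                "model lacks dependency information; build it symbolically or "
                "pass dependencies explicitly")
        pairs = set()
        for s, deps in self.dependencies.items():
            for d in deps:
                if d != s and d in self._index:
                    pairs.add(tuple(sorted((s, d))))
        return sorted(pairs)


# ---------------------------------------------------------------------------
# symbolic construction


def _compile(expr: sp.Expr, states: Sequence[str], with_t: bool):
    syms = [sp.Symbol("t")] if with_t else []
    state_syms = [sp.Symbol(s) for s in states]
    param_syms = sorted(expr.free_symbols - set(state_syms) - set(syms),
                        key=lambda s: s.name)
    fn = sp.lambdify(syms + state_syms + param_syms, expr, modules="numpy")
    pnames = [s.name for s in param_syms]
    n = len(states)

    if with_t:
        def call(t, y, params, _fn=fn, _pn=pnames, _n=n):
            return float(_fn(t, *y[:_n], *(params[p] for p in _pn)))
    else:
        def call(y, params, _fn=fn, _pn=pnames, _n=n):
            return float(_fn(*y[:_n], *(params[p] for p in _pn)))
    return call


def build_model(
    name: str,
    *,
    odes: Mapping[str, str] | None = None,
    algebraic: Mapping[str, str] | None = None,
    explicit: Mapping[str, str] | None = None,
    parameterized: Iterable[str] = (),
    params: Mapping[str, float],
    conserved: Iterable[tuple[str, Iterable[str]]] = (),
    initial: Mapping[str, float] | None = None,
) -> NetworkModel:
    """Build a :class:`NetworkModel` from sympy-parseable expression strings.

    ``odes[s]`` is d[s]/dt; ``algebraic[s]`` is a residual expression whose
    root defines s; ``explicit[s]`` gives s directly.  Any symbol that is not
    a state (or ``t``) must appear in ``params``.  State-dependency sets are
    extracted from the expressions' free symbols.
    """
    odes = dict(odes or {})
    algebraic = dict(algebraic or {})
    explicit = dict(explicit or {})
    states = list(odes) + list(algebraic) + list(explicit) + list(parameterized)
    if len(set(states)) != len(states):
        raise ModelError("a state may appear in only one kind")
    kinds = {s: "ode" for s in odes}
    kinds.update({s: "implicit_algebraic" for s in algebraic})
    kinds.update({s: "explicit_algebraic" for s in explicit})
    kinds.update({s: "parameterized" for s in parameterized})

    state_set = set(states)
    params = dict(params)
    for s in parameterized:
        params.setdefault(s, 0.0)
    deps: dict[str, set[str]] = {s: set() for s in states}
    expressions: dict[str, str] = {}
    ode_funcs, residual_funcs, explicit_funcs = {}, {}, {}

    # explicit symbol table so names like E, S, I, beta are plain symbols,
    # not sympy singletons/functions
    symtab = {n: sp.Symbol(n) for n in (*state_set, *params, "t")}

    def parse(s: str, text: str) -> sp.Expr:
        try:
            expr = sp.parse_expr(text, local_dict=symtab)
        except Exception as e:
            raise ModelError(f"cannot parse expression for {s!r}: {text!r}") from e
        for sym in expr.free_symbols:
            nm = sym.name
            if nm in state_set:
                deps[s].add(nm)
            elif nm != "t" and nm not in params:
                raise ModelError(
                    f"expression for {s!r} references unknown symbol {nm!r}")
        expressions[s] = text
        return expr

    for s, text in odes.items():
        ode_funcs[s] = _compile(parse(s, text), states, with_t=True)
    for s, text in algebraic.items():
        residual_funcs[s] = _compile(parse(s, text), states, with_t=False)
    for s, text in explicit.items():
        explicit_funcs[s] = _compile(parse(s, text), states, with_t=False)

    return NetworkModel(
        name=name,
        states=states,
        kinds=kinds,
        params=params,
        ode_funcs=ode_funcs,
        residual_funcs=residual_funcs,
        explicit_funcs=explicit_funcs,
        conserved_totals=[(t, list(m)) for t, m in conserved],
        dependencies=deps,
        initial=dict(initial or {}),
        expressions=expressions,
    )


# ---------------------------------------------------------------------------
# bundled models


def make_toy_model() -> NetworkModel:
    """The three-species linear irreversible pathway source → A → B → C → sink.

    First-order mass action with k2 = 1 s⁻¹, k3 = 10 s⁻¹, k4 = 1 s⁻¹ and a
    switchable zeroth-order source k1 (100 µM s⁻¹ during stimulus, else 0):

        dA/dt = k1 − k2·A,   dB/dt = k2·A − k3·B,   dC/dt = k3·B − k4·C.

    During sustained stimulus the steady state is A = k1/k2 = 100 µM,
    B = (k2/k3)·A = 10 µM, C = (k3/k4)·B = 100 µM, so B is one-tenth of A.
    The B equation equilibrates ten times faster than its neighbours, making
    the A–B pair the canonical "fast" relationship.
    """
    return build_model(
        "toy",
        odes={
            "A": "k1 - k2*A",
            "B": "k2*A - k3*B",
            "C": "k3*B - k4*C",
        },
        params={"k1": 0.0, "k2": 1.0, "k3": 10.0, "k4": 1.0},
        initial={"A": 0.0, "B": 0.0, "C": 0.0},
    )


@dataclass(frozen=True)
class SyntheticCascadeSpec:
    """Specification of a linear mass-action chain X1 → X2 → ... → Xn → sink.

    ``rate_ladder[i]`` (s⁻¹) is the first-order rate draining X_{i+1} (and
    feeding X_{i+2}); ``input_magnitude`` (µM s⁻¹) is the switchable
    zeroth-order source into X1.  The chain's Jacobian is lower-bidiagonal
    with eigenvalues −rate_ladder, so every timescale is known analytically.
    """

    n_species: int
    rate_ladder: tuple[float, ...]
    input_magnitude: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ModelError("n_species must be >= 1")
        if len(self.rate_ladder) != self.n_species:
            raise ModelError("rate_ladder length must equal n_species")
        if any(r <= 0 for r in self.rate_ladder):
            raise ModelError("rate_ladder entries must be positive")
        if self.input_magnitude <= 0:
            raise ModelError("input_magnitude must be positive")


def generate_cascade(spec: SyntheticCascadeSpec) -> NetworkModel:
    """Materialize a :class:`SyntheticCascadeSpec` as a NetworkModel.

    States are named ``X1 .. Xn``; the source parameter is ``u`` (switch it
    with a :class:`~phasereduce.simulate.StimulusProtocol`).  Deterministic:
    the spec fully fixes the model.
    """
    names = [f"X{i+1}" for i in range(spec.n_species)]
    odes = {}
    for i, s in enumerate(names):
        inflow = "u" if i == 0 else f"k{i}*{names[i-1]}"
        odes[s] = f"{inflow} - k{i+1}*{s}"
    params = {"u": 0.0}
    params.update({f"k{i+1}": float(r) for i, r in enumerate(spec.rate_ladder)})
    return build_model(
        f"cascade{spec.n_species}_seed{spec.seed}",
        odes=odes,
        params=params,
        initial={s: 0.0 for s in names},
    )


def random_cascade_spec(
    n_species: int,
    seed: int,
    *,
    log10_rate_range: tuple[float, float] = (-0.5, 2.0),
    input_magnitude: float = 100.0,
) -> SyntheticCascadeSpec:
    """Draw a cascade with rates log-uniform over ``log10_rate_range``.

    The default range spans ~0.3–100 s⁻¹, i.e. up to ~300-fold separation
    between adjacent steps — enough for both fast and slow pairs to occur.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    lo, hi = log10_rate_range
    rates = 10.0 ** rng.uniform(lo, hi, size=n_species)
    return SyntheticCascadeSpec(
        n_species=n_species,
        rate_ladder=tuple(float(r) for r in rates),
        input_magnitude=input_magnitude,
        seed=seed,
    )
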