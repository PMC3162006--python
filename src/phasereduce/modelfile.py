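"""Declarative plain-text model descriptions.

A model file is UTF-8 text with bracketed sections; within a section each
line is ``name = expression`` (or ``name = value``).  Concentrations are in
µM, time in seconds.  Sections:

``[states]``      one ``name = kind`` line per state (ode, implicit_algebraic,
                  explicit_algebraic, parameterized); optional — states
                  default to the kind implied by the section defining them.
``[parameters]``  ``name = number``
``[rates]``       ``state = d[state]/dt expression`` (ode states)
``[algebraic]``   ``state = residual expression`` (implicit states)
``[explicit]``    ``state = expression`` (explicit states)
``[conserved]``   ``total_param = member1 + member2 + ...``
``[initial]``     ``state = number`` resting initial guesses

Expressions use sympy syntax over state and parameter names.  Lines starting
with ``#`` or ``;`` are comments.

A minimal CellML 1.1 loader is provided for models distributed in that
format; it extracts components/variables but refuses documents whose MathML
it cannot map onto this declarative structure, directing users to transcribe
the model into the text format above.
"""

from __future__ import annotations

from pathlib import Path

from .models import ModelError, NetworkModel, build_model

__all__ = ["load_model_file", "dump_model_file", "load_cellml"]

_SECTIONS = ("states", "parameters", "rates", "algebraic", "explicit",
             "conserved", "initial")


def _parse_sections(text: str) -> dict[str, list[tuple[str, str]]]:
    sections: dict[str, list[tuple[str, str]]] = {s: [] for s in _SECTIONS}
    current: str | None = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line[0] in "#;":
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().lower()
            if name not in _SECTIONS:
                raise ModelError(f"line {ln}: unknown section [{name}]")
            current = name
            continue
        if current is None:
            raise ModelError(f"line {ln}: content before any section")
        if "=" not in line:
            raise ModelError(f"line {ln}: expected 'name = expression'")
        key, _, val = line.partition("=")
        sections[current].append((key.strip(), val.strip()))
    return sections


def load_model_file(path, name: str | None = None) -> NetworkModel:
    """Parse a declarative model file into a :class:`NetworkModel`."""
    path = Path(path)
    sec = _parse_sections(path.read_text(encoding="utf-8"))
    params = {}
    for k, v in sec["parameters"]:
        try:
            params[k] = float(v)
        except ValueError:
            raise ModelError(f"parameter {k!r} has non-numeric value {v!r}")
    odes = dict(sec["rates"])
    algebraic = dict(sec["algebraic"])
    explicit = dict(sec["explicit"])
    declared = dict(sec["states"])
    parameterized = [s for s, kind in declared.items() if kind == "parameterized"]
    # consistency of any explicit kind declarations
    for s, kind in declared.items():
        implied = ("ode" if s in odes else
                   "implicit_algebraic" if s in algebraic else
                   "explicit_algebraic" if s in explicit else
                   "parameterized")
        if kind != implied:
            raise ModelError(
                f"state {s!r} declared {kind!r} but defined as {implied!r}")
    conserved = []
    for total, members in sec["conserved"]:
        conserved.append((total, [m.strip() for m in members.split("+")]))
    initial = {}
    for k, v in sec["initial"]:
        initial[k] = float(v)
    return build_model(
        name or path.stem,
        odes=odes,
        algebraic=algebraic,
        explicit=explicit,
        parameterized=parameterized,
        params=params,
        conserved=conserved,
        initial=initial,
    )


def dump_model_file(model: NetworkModel, path) -> None:
    """Write an expression-based model back to the declarative format.

    Only models built symbolically (with recorded expression strings) can be
    serialized; reduced models carrying fitted-relation closures serialize
    their fits separately (see :class:`~phasereduce.clamp.FittedRelation`).
    """
    lines = [f"# model: {model.name}", ""]
    missing = [s for s in model.states
               if model.kinds[s] != "parameterized" and s not in model.expressions]
    if missing:
        raise ModelError(
            f"states {missing} have no expression strings; cannot serialize")
    lines.append("[parameters]")
    for k, v in model.params.items():
        lines.append(f"{k} = {v!r}")
    for section, kind in (("rates", "ode"), ("algebraic", "implicit_algebraic"),
                          ("explicit", "explicit_algebraic")):
        names = [s for s in model.states if model.kinds[s] == kind]
        if names:
            lines += ["", f"[{section}]"]
            lines += [f"{s} = {model.expressions[s]}" for s in names]
    if model.parameterized_states:
        lines += ["", "[states]"]
        lines += [f"{s} = parameterized" for s in model.parameterized_states]
    if model.conserved_totals:
        lines += ["", "[conserved]"]
        lines += [f"{t} = {' + '.join(m)}" for t, m in model.conserved_totals]
    if model.initial:
        lines += ["", "[initial]"]
        lines += [f"{k} = {v!r}" for k, v in model.initial.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_cellml(path) -> NetworkModel:
    """Best-effort CellML 1.1 import.

    Reads the document and enumerates its variables, but full MathML →
    expression translation is not attempted: the loader raises
    :class:`~phasereduce.models.ModelError` listing the variables found so
    the model can be transcribed into the declarative text format.
    """
    from lxml import etree

    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except Exception as e:  # noqa: BLE001 - surface any parse failure uniformly
        raise ModelError(f"cannot parse CellML file {path}: {e}") from e
    ns = {"c": tree.getroot().nsmap.get(None, "")}
    names = [v.get("name") for v in tree.findall(".//c:variable", ns)]
    raise ModelError(
        f"CellML import of {path.name} found {len(names)} variables "
        f"({', '.join(n for n in names[:8] if n)}...) but automatic MathML "
        "translation is not supported; transcribe the model into the "
        "declarative text format (see phasereduce.modelfile)")
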