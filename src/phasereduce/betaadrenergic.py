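"""Cardiac β₁-adrenergic signaling fixture: loaders and scenarios.

The reference application of the reduction workflow is a 25-variable
differential-algebraic model of cardiac β₁-adrenergic signaling (12 ODEs +
13 implicit algebraic equations, Saucerman et al.) together with its 6- and
4-variable reductions.  The governing equations and parameter tables for
those models were published only as supplementary material (Word documents
and a CellML/MATLAB archive) and are not bundled here; this module defines
the loading contract and the five published stimulus scenarios, and raises
an explicit, non-silent signal when the transcription files are absent.

To use a transcription, place declarative model files (see
:mod:`phasereduce.modelfile`) named ``bar_full25.model``,
``bar_reduced6.model`` and ``bar_reduced4.model`` in a directory and point
``PHASEREDUCE_BAR_DIR`` or the ``search_dir`` argument at it.  Loaded models
are validated against the published structure (state counts and the
identity of the retained ODE species).
"""

from __future__ import annotations

import os
from pathlib import Path

from .models import ModelError, NetworkModel
from .modelfile import load_model_file
from .reduction import Scenario, score_reduction
from .simulate import StimulusProtocol

__all__ = [
    "FixtureUnavailableError",
    "load_bar_model",
    "bar_scenarios",
    "reproduce_table1",
    "REDUCED6_ODE_STATES",
    "EXCLUDED_FROM_SCORING",
]

#: ODE species retained by the 6-variable reduction
REDUCED6_ODE_STATES = ("b1ARd", "b1ARp", "Gsa_gtp_tot", "cAMPtot", "PLBp", "TnIp")

#: species excluded from error scoring: fixed under the isoproterenol
#: protocol (Fsk, IBMX, PDE) or removed by the reductions
EXCLUDED_FROM_SCORING = ("Fsk", "IBMX", "PDE", "b1AR_free", "Gsa_gdp", "Gsbg")

_FILES = {
    "full25": "bar_full25.model",
    "reduced6": "bar_reduced6.model",
    "reduced4": "bar_reduced4.model",
}

_EXPECTED = {
    "full25": {"n_states": 25, "n_ode": 12, "n_implicit": 13},
    "reduced6": {"n_ode": 6},
    "reduced4": {"n_ode": 4},
}


class FixtureUnavailableError(FileNotFoundError):
    """The β-adrenergic transcription files are not present.

    Raised explicitly (never a silent fallback) so that analyses requiring
    the fixture report its absence; the synthetic cascade generator covers
    the same analysis stages without it.
    """


def _fixture_dir(search_dir=None) -> Path:
    if search_dir is not None:
        return Path(search_dir)
    env = os.environ.get("PHASEREDUCE_BAR_DIR")
    if env:
        return Path(env)
    return Path(__file__).parent / "data" / "betaadrenergic"


def load_bar_model(variant: str = "full25", search_dir=None) -> NetworkModel:
    """Load a β-adrenergic model variant from its declarative transcription.

    ``variant`` is one of ``full25``, ``reduced6``, ``reduced4``.  Raises
    :class:`FixtureUnavailableError` when the transcription file is missing,
    and :class:`~phasereduce.models.ModelError` when a present file does not
    match the published structure (25 states with 12 ODEs + 13 implicit
    equations; 6 or 4 ODE states for the reductions).
    """
    if variant not in _FILES:
        raise ValueError(f"unknown variant {variant!r}; use one of {list(_FILES)}")
    path = _fixture_dir(search_dir) / _FILES[variant]
    if not path.is_file():
        raise FixtureUnavailableError(
            f"β-adrenergic transcription {path} not found. The governing "
            "equations live in the model's supplementary material and must "
            "be transcribed into the declarative format; see the "
            "phasereduce.betaadrenergic module docstring. Synthetic cascades "
            "(phasereduce.models.generate_cascade) exercise the same "
            "analysis pipeline without this fixture.")
    model = load_model_file(path, name=f"bar_{variant}")
    exp = _EXPECTED[variant]
    if "n_states" in exp and len(model.states) != exp["n_states"]:
        raise ModelError(
            f"{variant} transcription has {len(model.states)} states, "
            f"expected {exp['n_states']}")
    if len(model.ode_states) != exp["n_ode"]:
        raise ModelError(
            f"{variant} transcription has {len(model.ode_states)} ODE states, "
            f"expected {exp['n_ode']}")
    if "n_implicit" in exp and len(model.implicit_states) != exp["n_implicit"]:
        raise ModelError(
            f"{variant} transcription has {len(model.implicit_states)} "
            f"implicit states, expected {exp['n_implicit']}")
    if variant == "reduced6":
        missing = set(REDUCED6_ODE_STATES) - set(model.ode_states)
        if missing:
            raise ModelError(f"reduced6 transcription is missing ODE states "
                             f"{sorted(missing)}")
    return model


def bar_scenarios(*, pp1_baseline: float = 0.89) -> dict[str, Scenario]:
    """The five published stimulus scenarios (400 s on + 400 s off).

    ``iso_1uM`` is the reference protocol used for the reduction itself;
    the other four are the independent perturbation tests: low-dose
    isoproterenol, direct adenylate-cyclase activation by forskolin,
    phosphodiesterase inhibition by IBMX, and transient knockout of protein
    phosphatase-1 (PP1tot driven to 0 from ``pp1_baseline`` µM).
    """

    def proto(param, on, off=0.0):
        return StimulusProtocol(parameter=param, on_value=on, off_value=off,
                                t_on=0.0, t_off=400.0, t_end=800.0)

    return {
        "iso_1uM": Scenario("iso_1uM", proto("Iso", 1.0)),
        "iso_0p05uM": Scenario("iso_0p05uM", proto("Iso", 0.05)),
        "fsk_10uM": Scenario("fsk_10uM", proto("Fsktot", 10.0)),
        "ibmx_100uM": Scenario("ibmx_100uM", proto("IBMXtot", 100.0)),
        "pp1_knockout": Scenario(
            "pp1_knockout", proto("PP1tot", 0.0, off=pp1_baseline)),
    }


def reproduce_table1(search_dir=None):
    """Per-species mean errors of the 6- and 4-variable reductions.

    Runs the reference transient (1 µM isoproterenol, 400 s + 400 s) on the
    full model and both reductions and scores them with the standard
    exclusions.  Returns ``(report_6var, report_4var)``.  Requires the
    transcription fixture; raises :class:`FixtureUnavailableError` otherwise.
    """
    full = load_bar_model("full25", search_dir)
    red6 = load_bar_model("reduced6", search_dir)
    red4 = load_bar_model("reduced4", search_dir)
    protocol = bar_scenarios()["iso_1uM"].protocol
    excluded = list(EXCLUDED_FROM_SCORING)
    return (
        score_reduction(full, red6, protocol, excluded=excluded),
        score_reduction(full, red4, protocol, excluded=excluded),
    )
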