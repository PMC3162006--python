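"""Jacobian-based timescale decomposition at a steady state.

The classical comparator for phase-loop timescale analysis: linearize the
combined ODE + implicit-algebraic system at a steady state, eigendecompose
the Jacobian J = M Λ M⁻¹, and read each mode's timescale off its eigenvalue
as τ = −1/Re(λ).  Rows of the modal matrix M⁻¹ are dynamic modes; after
unit-normalizing each row, the species whose entries exceed a magnitude
threshold (default 0.09) are the mode's dominant participants.  Modes with
τ ≤ 1 ms are labeled algebraic-relationship modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .models import NetworkModel
from .phase import AreaMatrix

__all__ = [
    "JacobianReport",
    "jacobian_at",
    "modal_decomposition",
    "compare_methods",
    "ALGEBRAIC_TIMESCALE_S",
]

#: modes at or below this timescale are reported as algebraic relationships
ALGEBRAIC_TIMESCALE_S = 1e-3


@dataclass
class JacobianReport:
    """Eigen-structure of a Jacobian, slowest mode first.

    ``timescales`` are τᵢ = −1/Re(λᵢ) in seconds; ``modal_rows`` holds the
    unit-normalized rows of M⁻¹ aligned with ``timescales``;
    ``dominant_species`` lists, per mode, the states whose modal-row
    magnitude exceeds the threshold.  Complex-conjugate eigenvalue pairs are
    merged into a single mode with their shared τ and the union of dominant
    species.  ``unreliable`` flags a near-defective eigenvector matrix.
    """

    states: list[str]
    steady_state: dict[str, float]
    eigenvalues: np.ndarray
    timescales: list[float]
    modal_rows: np.ndarray
    dominant_species: list[list[str]]
    magnitude_threshold: float
    unreliable: bool = False
    mode_labels: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Timescale table: timescale_s, dominant_species (comma-joined)."""
        return pd.DataFrame({
            "timescale_s": self.timescales,
            "dominant_species": [",".join(d) for d in self.dominant_species],
            "label": self.mode_labels,
        })

    def to_csv(self, path) -> None:
        self.table().to_csv(path, index=False)

    def fastest_mode_species(self) -> set[str]:
        """Dominant species of the fastest dynamic (non-algebraic) mode."""
        for ts, dom, lab in zip(reversed(self.timescales),
                                reversed(self.dominant_species),
                                reversed(self.mode_labels)):
            if lab != "algebraic":
                return set(dom)
        return set()


def jacobian_at(
    model: NetworkModel,
    state: Mapping[str, float],
    param_overrides: Mapping[str, float] | None = None,
    *,
    ss_tol: float = 1e-6,
) -> np.ndarray:
    """Finite-difference Jacobian of the combined dynamic system.

    Rows/columns follow :attr:`NetworkModel.dynamic_states` (ode states then
    implicit states): row i is ∂Fᵢ/∂yⱼ where F stacks the ODE derivatives
    and the algebraic residuals.  Central differences with a per-state step
    ``h = cbrt(eps)·max(|y|, 1)``; explicit and parameterized states are
    re-evaluated at every perturbation so their sensitivity is folded in.
    ``param_overrides`` fixes the operating-point inputs (e.g. the stimulus
    at its on value) before linearization.  Raises if the supplied state is
    not at steady state to ``ss_tol`` (normalized rate units, s⁻¹).
    """
    if param_overrides:
        model = model.with_params(param_overrides)
    dyn = model.dynamic_states
    v0 = np.array([state[s] for s in dyn], dtype=float)

    def F(v):
        y = model.full_state(dict(zip(dyn, v)))
        return np.concatenate([model.rhs(0.0, y), model.residuals(y)])

    f0 = F(v0)
    scale = np.maximum(np.abs(v0), 1.0)
    if np.max(np.abs(f0) / scale, initial=0.0) > ss_tol:
        raise ValueError(
            f"supplied state is not at steady state (max normalized rate "
            f"{np.max(np.abs(f0) / scale):.3g}/s > {ss_tol:g}/s)")
    n = len(dyn)
    J = np.empty((n, n))
    h0 = np.cbrt(np.finfo(float).eps)
    for j in range(n):
        h = h0 * max(abs(v0[j]), 1.0)
        vp, vm = v0.copy(), v0.copy()
        vp[j] += h
        vm[j] -= h
        J[:, j] = (F(vp) - F(vm)) / (2 * h)
    if not np.all(np.isfinite(J)):
        raise ValueError("non-finite entries in finite-difference Jacobian")
    return J


def modal_decomposition(
    J: np.ndarray,
    states: list[str] | None = None,
    magnitude_threshold: float = 0.09,
    *,
    steady_state: Mapping[str, float] | None = None,
    condition_cap: float = 1e12,
) -> JacobianReport:
    """Eigendecompose J and report modes from slowest to fastest.

    The modal matrix is M⁻¹ (rows = modes); rows are unit-normalized before
    thresholding at ``magnitude_threshold``.  A defective or near-defective
    eigenvector matrix (condition number above ``condition_cap``) flags the
    report unreliable rather than failing.
    """
    J = np.asarray(J, dtype=float)
    n = J.shape[0]
    if J.shape != (n, n):
        raise ValueError("J must be square")
    if states is None:
        states = [f"x{i}" for i in range(n)]
    lam, M = np.linalg.eig(J)
    cond = np.linalg.cond(M)
    unreliable = not np.isfinite(cond) or cond > condition_cap
    Minv = np.linalg.pinv(M) if unreliable else np.linalg.inv(M)

    # merge complex-conjugate pairs: keep one representative per Re/|Im| pair
    order = np.argsort(lam.real)  # most negative (fastest) first
    used = np.zeros(n, dtype=bool)
    modes = []  # (tau, row_magnitudes, eigenvalue)
    for i in order:
        if used[i]:
            continue
        used[i] = True
        row = np.abs(Minv[i])
        if abs(lam[i].imag) > 1e-12:
            for j in order:
                if not used[j] and abs(lam[j].real - lam[i].real) < 1e-9 and \
                        abs(lam[j].imag + lam[i].imag) < 1e-9:
                    used[j] = True
                    row = np.maximum(row, np.abs(Minv[j]))
                    break
        re = lam[i].real
        tau = -1.0 / re if re != 0 else np.inf
        modes.append((float(tau), row, lam[i]))

    # slow -> fast: descending timescale (negative tau = unstable, goes first)
    modes.sort(key=lambda m: (-np.inf if m[0] < 0 else -m[0]))
    timescales, rows, doms, labels, eigs = [], [], [], [], []
    for tau, row, ev in modes:
        nrm = np.linalg.norm(row)
        rown = row / nrm if nrm > 0 else row
        dom = [states[k] for k in np.argsort(-rown)
               if rown[k] > magnitude_threshold]
        timescales.append(tau)
        rows.append(rown)
        doms.append(dom)
        eigs.append(ev)
        labels.append("algebraic" if 0 < tau <= ALGEBRAIC_TIMESCALE_S
                      else ("unstable" if tau < 0 else "dynamic"))
    return JacobianReport(
        states=list(states),
        steady_state=dict(steady_state or {}),
        eigenvalues=np.array(eigs),
        timescales=timescales,
        modal_rows=np.array(rows),
        dominant_species=doms,
        magnitude_threshold=magnitude_threshold,
        unreliable=unreliable,
        mode_labels=labels,
    )


def compare_methods(
    report: JacobianReport,
    am: AreaMatrix,
    classes: Mapping[tuple[str, str], str],
) -> pd.DataFrame:
    """Concordance of the two timescale analyses, per species.

    For each state in both analyses: whether it dominates the fastest
    dynamic Jacobian mode, the class of its fastest direct pair under the
    phase-loop method, and an agreement flag (fast-by-both or by neither).
    """
    fast_jac = report.fastest_mode_species()
    rows = []
    for s in report.states:
        if s not in am.states:
            continue
        pair_classes = {p: c for p, c in classes.items() if s in p}
        if pair_classes:
            best_pair = min(pair_classes, key=lambda p: am.area(*p))
            phase_class = pair_classes[best_pair]
            best_area = am.area(*best_pair)
        else:
            phase_class, best_area = "", np.nan
        jac_fast = s in fast_jac
        phase_fast = phase_class == "fast"
        rows.append({
            "species": s,
            "jacobian_fastest_mode": jac_fast,
            "phase_fastest_pair_class": phase_class,
            "phase_fastest_pair_area": best_area,
            "agree": jac_fast == phase_fast,
        })
    return pd.DataFrame(rows)
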