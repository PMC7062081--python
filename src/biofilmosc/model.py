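"""Core equations of the biofilm oscillator: vector field, steady states,
Jacobians and quasi-steady-state reductions.

The model couples peripheral glutamate ``Gp``, ammonia ``A`` and interior
glutamate ``Gi`` through mass-action kinetics with a single bilinear
consumption term:

    dGp/dt = k1*G_E*Gp - k4*Gp - k2*A*Gp
    dA/dt  = -k3*A + k5*Gi
    dGi/dt = k4*Gp - k5*Gi

With the ``self_amplified`` variant the periphery-to-interior transfer
``k4*Gp`` becomes ``k4*Gi*Gp`` in both equations where it appears.

Biomass grows trilinearly, dB/dt = b*A*Gp*B, as a proxy for amino-acid
synthesis from ammonia and glutamate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Literal

import numpy as np

from .params import ParameterSet, State, as_state

__all__ = [
    "vector_field",
    "biomass_rate",
    "jacobian",
    "steady_states",
    "SteadyState",
    "ReducedModel",
    "qssa_reduce",
    "classify_reduced",
    "eigenvalues_from_jacobian",
    "classify_eigenvalues",
]

#: Relative tolerance deciding whether an eigenvalue pair counts as complex
#: and whether a real part counts as zero (degenerate boundary case).
EIG_TOL = 1e-9


# ----------------------------------------------------------------------
# Vector field and Jacobian
# ----------------------------------------------------------------------
def _rhs(y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Unchecked right-hand side on the (Gp, A, Gi) triple."""
    Gp, A, Gi = y[0], y[1], y[2]
    transfer = p.k4 * Gi * Gp if p.variant == "self_amplified" else p.k4 * Gp
    return np.array(
        [
            p.k1 * p.G_E * Gp - transfer - p.k2 * A * Gp,
            -p.k3 * A + p.k5 * Gi,
            transfer - p.k5 * Gi,
        ]
    )


def vector_field(state: State | Iterable[float], params: ParameterSet) -> np.ndarray:
    """Time derivatives (dGp/dt, dA/dt, dGi/dt) in mmol/(l h).

    Raises ``ValueError`` for non-finite or negative concentrations.
    """
    s = as_state(state)
    return _rhs(s.concentrations(), params)


def biomass_rate(state: State | Iterable[float], params: ParameterSet) -> float:
    """Biomass growth rate dB/dt = b*A*Gp*B in cells/(l h).

    The state must carry biomass ``B``.
    """
    s = as_state(state)
    if not s.has_biomass:
        raise ValueError("state has no biomass component B")
    return params.b * s.A * s.Gp * s.B


def _jac(y: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Unchecked 3x3 Jacobian at the (Gp, A, Gi) triple."""
    Gp, A, Gi = y[0], y[1], y[2]
    if p.variant == "self_amplified":
        return np.array(
            [
                [p.k1 * p.G_E - p.k4 * Gi - p.k2 * A, -p.k2 * Gp, -p.k4 * Gp],
                [0.0, -p.k3, p.k5],
                [p.k4 * Gi, 0.0, p.k4 * Gp - p.k5],
            ]
        )
    return np.array(
        [
            [p.k1 * p.G_E - p.k4 - p.k2 * A, -p.k2 * Gp, 0.0],
            [0.0, -p.k3, p.k5],
            [p.k4, 0.0, -p.k5],
        ]
    )


def jacobian(state: State | Iterable[float], params: ParameterSet) -> np.ndarray:
    """Exact 3x3 Jacobian of the vector field; rows/columns ordered (Gp, A, Gi)."""
    y = np.asarray(
        state.concentrations() if isinstance(state, State) else state, dtype=float
    )
    if y.shape[-1] == 4:
        y = y[:3]
    if not np.all(np.isfinite(y)):
        raise ValueError("state must be finite")
    return _jac(y, params)


def eigenvalues_from_jacobian(J: np.ndarray) -> np.ndarray:
    """Eigenvalues of a 3x3 matrix via its characteristic polynomial.

    The coefficients (trace, sum of principal minors, determinant) are
    assembled exactly from the matrix entries; the cubic is then solved
    numerically.  This keeps the node/focus distinction stable under
    round-off near the real/complex transition.
    """
    J = np.asarray(J, dtype=float)
    tr = np.trace(J)
    m2 = (
        J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
        + J[0, 0] * J[2, 2] - J[0, 2] * J[2, 0]
        + J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1]
    )
    det = np.linalg.det(J)
    roots = np.roots([1.0, -tr, m2, -det])
    return roots[np.argsort(roots.real)]


def classify_eigenvalues(eigs: np.ndarray, tol: float = EIG_TOL) -> str:
    """Classify a fixed point from its eigenvalues.

    Returns one of ``stable-node``, ``stable-focus``, ``unstable-node``,
    ``unstable-focus``, ``saddle`` or ``degenerate``.  An eigenvalue is
    treated as complex when |Im| > tol*|lambda| and a real part as zero
    when below the same relative threshold, so boundary cases (a
    bifurcation point hit exactly) come back ``degenerate`` rather than
    being forced into a generic class.
    """
    eigs = np.asarray(eigs, dtype=complex)
    scale = max(np.abs(eigs).max(), 1.0)
    complex_mask = np.abs(eigs.imag) > tol * np.maximum(np.abs(eigs), 1e-300)
    re = eigs.real
    if np.any(np.abs(re) <= tol * scale):
        return "degenerate"
    has_complex = bool(np.any(complex_mask))
    if np.all(re < 0):
        return "stable-focus" if has_complex else "stable-node"
    if np.all(re > 0):
        return "unstable-focus" if has_complex else "unstable-node"
    # mixed signs: an unstable focus has the complex pair unstable;
    # otherwise (real directions of both signs) it is a saddle
    if has_complex and np.all(re[complex_mask] > 0):
        return "unstable-focus"
    return "saddle"


# ----------------------------------------------------------------------
# Steady states
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SteadyState:
    """A fixed point with its spectral classification.

    ``physical`` is False when the analytic branch has non-positive
    concentrations (below the transcritical threshold the non-trivial
    branch crosses into the negative octant); the branch is still
    returned so bifurcation scans can follow it through the crossing.
    """

    kind: Literal["trivial", "non-trivial"]
    concentrations: np.ndarray
    eigenvalues: np.ndarray
    classification: str
    physical: bool

    @property
    def Gp(self) -> float:
        return float(self.concentrations[0])

    @property
    def A(self) -> float:
        return float(self.concentrations[1])

    @property
    def Gi(self) -> float:
        return float(self.concentrations[2])

    @property
    def stable(self) -> bool:
        return self.classification.startswith("stable")


def ntss_concentrations(params: ParameterSet) -> np.ndarray:
    """Closed-form non-trivial steady state (Gp, A, Gi).

    For the baseline model,

        Gp_ss = (k1*G_E - k4) * k3 / (k2 * k4)
        A_ss  = (k1*G_E - k4) / k2
        Gi_ss = (k1*G_E - k4) * k3 / (k2 * k5)

    all linear in G_E.  For the self-amplified transfer variant the
    interior balance pins Gp_ss = k5/k4 instead.
    """
    p = params
    if p.variant == "self_amplified":
        denom = p.k3 * p.k4 + p.k2 * p.k5
        Gi = p.k1 * p.G_E * p.k3 / denom
        return np.array([p.k5 / p.k4, p.k5 / p.k3 * Gi, Gi])
    k = p.k  # k1*G_E - k4
    return np.array([k * p.k3 / (p.k2 * p.k4), k / p.k2, k * p.k3 / (p.k2 * p.k5)])


def _make_steady_state(kind: str, y: np.ndarray, params: ParameterSet) -> SteadyState:
    eigs = eigenvalues_from_jacobian(_jac(y, params))
    return SteadyState(
        kind=kind,  # type: ignore[arg-type]
        concentrations=y,
        eigenvalues=eigs,
        classification=classify_eigenvalues(eigs),
        physical=bool(np.all(y >= 0)),
    )


def steady_states(params: ParameterSet) -> tuple[SteadyState, SteadyState]:
    """The trivial (origin) and non-trivial steady states with eigenvalues.

    The non-trivial branch is flagged ``physical=False`` (not suppressed)
    when k1*G_E <= k4 leaves it with non-positive concentrations.
    """
    tss = _make_steady_state("trivial", np.zeros(3), params)
    ntss = _make_steady_state("non-trivial", ntss_concentrations(params), params)
    return tss, ntss


# ----------------------------------------------------------------------
# Quasi-steady-state reduction
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ReducedModel:
    """Two-variable model obtained by adiabatic elimination of one species.

    Eliminating ``Gi`` (fast interior glutamate, i.e. glutamate
    dehydrogenase overexpressed) slaves it to Gi = (k4/k5)*Gp and leaves

        dGp/dt = (k1*G_E - k4)*Gp - k2*A*Gp
        dA/dt  = -k3*A + k4*Gp

    Eliminating ``A`` (fast ammonia loss) slaves it to A = (k5/k3)*Gi.
    ``variables`` names the two retained variables in order.
    """

    eliminated: Literal["Gi", "A"]
    params: ParameterSet
    variables: tuple[str, str]

    @property
    def k(self) -> float:
        """Aggregate constant k1*G_E - k4 (1/h)."""
        return self.params.k

    # -- algebraic slave relation ------------------------------------
    def slave(self, retained: np.ndarray | float) -> np.ndarray | float:
        """Quasi-steady value of the eliminated variable.

        For ``eliminated='Gi'`` the argument is Gp; for ``eliminated='A'``
        it is Gi.
        """
        p = self.params
        if self.eliminated == "Gi":
            return p.k4 / p.k5 * np.asarray(retained, dtype=float)
        return p.k5 / p.k3 * np.asarray(retained, dtype=float)

    # -- reduced vector field ----------------------------------------
    def rhs(self, y: np.ndarray) -> np.ndarray:
        p = self.params
        if self.eliminated == "Gi":
            Gp, A = y
            return np.array([self.k * Gp - p.k2 * A * Gp, -p.k3 * A + p.k4 * Gp])
        Gp, Gi = y
        return np.array(
            [self.k * Gp - p.k2 * (p.k5 / p.k3) * Gi * Gp, p.k4 * Gp - p.k5 * Gi]
        )

    def jacobian(self, y: np.ndarray) -> np.ndarray:
        p = self.params
        if self.eliminated == "Gi":
            Gp, A = y
            return np.array(
                [[self.k - p.k2 * A, -p.k2 * Gp], [p.k4, -p.k3]]
            )
        Gp, Gi = y
        c = p.k2 * p.k5 / p.k3
        return np.array([[self.k - c * Gi, -c * Gp], [p.k4, -p.k5]])

    # -- fixed points -------------------------------------------------
    def steady_states(self) -> tuple[np.ndarray, np.ndarray]:
        """(trivial, non-trivial) fixed points of the reduced system.

        The non-trivial point coincides with the corresponding
        components of the full-model non-trivial steady state.
        """
        full = ntss_concentrations(self.params.replace(variant="baseline"))
        if self.eliminated == "Gi":
            ntss = np.array([full[0], full[1]])
        else:
            ntss = np.array([full[0], full[2]])
        return np.zeros(2), ntss

    def ntss_eigenvalues(self) -> np.ndarray:
        """Closed-form eigenvalues at the non-trivial fixed point.

        For the Gi-eliminated system the characteristic equation is
        lambda^2 + k3*lambda + (k1*G_E - k4)*k3 = 0, giving

            lambda_{1,2} = -k3/2 +- sqrt(k3^2/4 - (k1*G_E - k4)*k3)

        (and the analogous expression with k5 for A elimination).
        """
        p = self.params
        decay = p.k3 if self.eliminated == "Gi" else p.k5
        disc = complex(decay**2 / 4.0 - self.k * decay)
        root = np.sqrt(disc)
        return np.array([-decay / 2.0 - root, -decay / 2.0 + root])


def qssa_reduce(
    params: ParameterSet, eliminated: Literal["Gi", "A"] = "Gi"
) -> ReducedModel:
    """Eliminate a fast variable by the quasi-steady-state approximation.

    ``eliminated='Gi'`` models overexpressed glutamate dehydrogenase
    (large k5); ``eliminated='A'`` models very fast ammonia loss
    (large k3).  The reduction is exact in the corresponding limit.
    """
    if eliminated not in ("Gi", "A"):
        raise ValueError(f"eliminated must be 'Gi' or 'A', got {eliminated!r}")
    if params.variant != "baseline":
        raise ValueError("QSSA reduction is defined for the baseline transfer term only")
    variables = ("Gp", "A") if eliminated == "Gi" else ("Gp", "Gi")
    return ReducedModel(eliminated=eliminated, params=params, variables=variables)


@dataclass(frozen=True)
class ReducedClassification:
    case: Literal["a", "b", "c", "degenerate"]
    label: str
    eigenvalues: np.ndarray


def classify_reduced(
    params: ParameterSet, eliminated: Literal["Gi", "A"] = "Gi", tol: float = EIG_TOL
) -> ReducedClassification:
    """Classify the reduced system's non-trivial fixed point.

    With k = k1*G_E - k4 and d the retained first-order decay constant
    (k3 for Gi elimination), the three regimes are

        (a) k < 0        : saddle point (the trivial state is the attractor)
        (b) 0 < k < d/4  : stable node, monotone relaxation
        (c) k > d/4      : stable focus, damped oscillations

    A two-variable mass-action system with at most bilinear terms cannot
    sustain a limit cycle, so case (c) is as oscillatory as the reduced
    model gets; the boundaries k = 0 and k = d/4 are reported as
    ``degenerate`` (within a relative tolerance on the discriminant)
    rather than forced into a case.
    """
    red = qssa_reduce(params, eliminated)
    eigs = red.ntss_eigenvalues()
    p = params
    decay = p.k3 if eliminated == "Gi" else p.k5
    k = red.k
    disc = decay**2 / 4.0 - k * decay
    scale = max(abs(decay**2 / 4.0), abs(k * decay), 1.0)
    if abs(k) <= tol * max(abs(p.k1 * p.G_E), abs(p.k4)) or abs(disc) <= tol * scale:
        return ReducedClassification("degenerate", "degenerate", eigs)
    if k < 0:
        return ReducedClassification("a", "saddle", eigs)
    if disc > 0:
        return ReducedClassification("b", "stable-node", eigs)
    return ReducedClassification("c", "stable-focus", eigs)
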