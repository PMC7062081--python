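"""Parameter recovery from observed trajectories by trajectory matching.

The estimation surface follows the model/results idiom: a
:class:`TrajectoryCalibration` is built from the observed data, its
:meth:`~TrajectoryCalibration.fit` runs multi-start bounded least
squares and returns a :class:`CalibrationResults` carrying the
estimates, Gauss-Newton standard errors, diagnostics and a
``summary()`` table.

The objective is the sum over observed variables and times of squared
residuals between the observations and a model simulation started from
the first observation (concentrations are fitted directly, not logs:
they span only about one order of magnitude here).  Box bounds are
required for all free parameters — without them the product k1*G_E can
drift unidentifiably — and k1 and G_E are never allowed to be free
simultaneously, since only their product enters the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dynamics import IntegrationError, Trajectory, simulate
from .params import VARIABLES, ParameterSet

__all__ = ["TrajectoryCalibration", "CalibrationResults", "fit"]

#: Default box bounds as multiples of the starting value of each free
#: parameter (a truth-scale prior supplied by the caller).
DEFAULT_BOUND_FACTORS = (0.1, 10.0)


class TrajectoryCalibration:
    """Least-squares calibration of rate constants to a time series.

    Parameters
    ----------
    observed : Trajectory
        The data; its columns name the observed variables (a subset of
        Gp, A, Gi).  Should cover at least ~3 oscillation periods for
        the oscillatory regime.
    free : sequence of str
        Names of the parameters to estimate (non-empty subset of
        k1, k2, k3, k4, k5, G_E, b; k1 and G_E not both).
    start : ParameterSet
        Values for the fixed parameters and starting scale for the free
        ones (the caller's prior).
    bounds : dict, optional
        ``{name: (lo, hi)}`` box bounds per free parameter; defaults to
        ``(0.1, 10) x start``.
    init_state : sequence of float, optional
        Initial concentrations for the model simulation.  By default
        the first observation supplies the observed components and the
        model steady state is only used for never-observed components;
        pass explicitly to override (the initial state is not fitted).
    rtol, atol : float
        Integrator tolerances used inside the objective.
    """

    def __init__(
        self,
        observed: Trajectory,
        free: Sequence[str],
        start: ParameterSet,
        bounds: dict[str, tuple[float, float]] | None = None,
        init_state: Sequence[float] | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ):
        free = tuple(free)
        if not free:
            raise ValueError("free parameter subset must be non-empty")
        valid = {"k1", "k2", "k3", "k4", "k5", "G_E", "b"}
        unknown = set(free) - valid
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        if "k1" in free and "G_E" in free:
            raise ValueError(
                "k1 and G_E cannot both be free: only their product k1*G_E "
                "enters the dynamics, so they are not jointly identifiable"
            )
        if "b" in free and "B" not in observed.columns:
            raise ValueError("b is only identifiable from biomass observations")
        bad = [c for c in observed.columns if c not in VARIABLES + ("B",)]
        if bad:
            raise ValueError(f"unknown observed columns: {bad}")

        self.observed = observed
        self.free = free
        self.start = start
        self.rtol = rtol
        self.atol = atol

        if bounds is None:
            lo_f, hi_f = DEFAULT_BOUND_FACTORS
            bounds = {
                n: (lo_f * getattr(start, n), hi_f * getattr(start, n)) for n in free
            }
        missing = set(free) - set(bounds)
        if missing:
            raise ValueError(f"bounds missing for free parameters: {sorted(missing)}")
        for n in free:
            lo, hi = bounds[n]
            if not (0 < lo < hi):
                raise ValueError(f"bounds for {n} must satisfy 0 < lo < hi")
        self.bounds = {n: (float(bounds[n][0]), float(bounds[n][1])) for n in free}

        if init_state is None:
            y0 = np.array(
                [float(self.observed[v][0]) if v in observed.columns else float("nan")
                 for v in VARIABLES]
            )
            if np.any(np.isnan(y0)):
                # unobserved components start at the prior's steady state
                from .model import ntss_concentrations

                ss = ntss_concentrations(start)
                y0 = np.where(np.isnan(y0), ss, y0)
            init_state = y0
        self.init_state = np.asarray(init_state, dtype=float)

        self._obs_cols = tuple(c for c in observed.columns if c != "B")
        self._obs_idx = [VARIABLES.index(c) for c in self._obs_cols]
        self._dt = float(np.min(np.diff(observed.times)))

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, free: Sequence[str], start: ParameterSet, **kwargs
    ) -> "TrajectoryCalibration":
        """Build from a ``time,Gp,A,Gi`` table (any variable subset)."""
        return cls(Trajectory.from_dataframe(df), free, start, **kwargs)

    # ------------------------------------------------------------------
    def _params_from_vector(self, x: np.ndarray) -> ParameterSet:
        return self.start.replace(**dict(zip(self.free, map(float, x))))

    def _simulated(self, p: ParameterSet, n: int) -> np.ndarray:
        times = self.observed.times[:n]
        traj = simulate(
            p, np.clip(self.init_state, 0.0, None),
            t_end=float(times[-1]), dt_out=self._dt, rtol=self.rtol, atol=self.atol,
        )
        sim = np.column_stack(
            [np.interp(times, traj.times, traj.states[:, i]) for i in self._obs_idx]
        )
        return sim

    def residuals(self, x: np.ndarray, n: int | None = None) -> np.ndarray:
        """Stacked residuals (observation - model) over variables and times.

        ``n`` restricts to the first n observation times (used by the
        progressive-window fit stages); default is the full record.
        """
        n = self.observed.times.size if n is None else n
        try:
            p = self._params_from_vector(x)
            sim = self._simulated(p, n)
        except (IntegrationError, ValueError):
            # an infeasible draw: steer the optimizer away, do not abort
            return np.full(n * len(self._obs_cols), 1e6)
        obs = np.column_stack([self.observed[c][:n] for c in self._obs_cols])
        return (obs - sim).ravel()

    def objective(self, x: np.ndarray | ParameterSet) -> float:
        """Residual sum of squares at a parameter vector or ParameterSet."""
        if isinstance(x, ParameterSet):
            x = x.values(self.free)
        r = self.residuals(np.asarray(x, dtype=float))
        return float(r @ r)

    # ------------------------------------------------------------------
    def fit(
        self,
        n_restarts: int = 5,
        seed: int = 0,
        window_fractions: Sequence[float] = (0.1, 0.3, 0.6, 1.0),
    ) -> "CalibrationResults":
        """Multi-start bounded least squares; returns the best restart.

        Starting points are log-uniform draws within the box bounds from
        a generator seeded with ``seed`` (log-uniform, because rate
        constants live on a ratio scale).  Each restart solves a
        progression of trust-region-reflective least-squares problems on
        growing prefixes of the record (``window_fractions`` of the
        observation times, warm-starting each stage from the previous
        one).  The short first window sees only the initial transient,
        whose fit landscape is free of the phase-mismatch local minima
        that trap full-window fits of oscillatory data; the final stage
        always uses the full record.  The restart with the smallest
        full-window residual sum of squares wins.
        """
        if n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        n_times = self.observed.times.size
        windows = sorted({max(8, int(round(f * n_times))) for f in window_fractions})
        if not windows or windows[-1] != n_times:
            windows.append(n_times)
        rng = np.random.default_rng(seed)
        lo = np.array([self.bounds[n][0] for n in self.free])
        hi = np.array([self.bounds[n][1] for n in self.free])
        starts = np.exp(
            rng.uniform(np.log(lo), np.log(hi), size=(n_restarts, len(self.free)))
        )

        best = None
        n_ok = 0
        for x0 in starts:
            x = x0
            sol = None
            try:
                for n in windows:
                    sol = least_squares(
                        lambda v, n=n: self.residuals(v, n),
                        x, bounds=(lo, hi), x_scale=np.sqrt(lo * hi),
                        xtol=1e-10, ftol=1e-10, gtol=1e-10,
                    )
                    x = sol.x
            except Exception:
                continue
            if sol.status > 0:
                n_ok += 1
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("every calibration restart raised; no estimate available")

        estimates = dict(zip(self.free, map(float, best.x)))
        rss = float(2.0 * best.cost)
        n_obs = self.observed.times.size * len(self._obs_cols)
        se = _gauss_newton_se(best.jac, rss, n_obs, len(self.free))
        return CalibrationResults(
            model=self,
            params=self._params_from_vector(best.x),
            estimates=estimates,
            stderr=dict(zip(self.free, se)),
            rss=rss,
            n_obs=n_obs,
            converged=n_ok > 0 and best.status > 0,
            n_restarts=n_restarts,
            n_restarts_converged=n_ok,
            optimizer_status=int(best.status),
        )


def _gauss_newton_se(
    jac: np.ndarray, rss: float, n_obs: int, n_free: int
) -> np.ndarray:
    """Approximate standard errors from the Gauss-Newton covariance
    sigma^2 (J^T J)^-1 with sigma^2 = rss / (n - p); NaN when singular."""
    dof = max(n_obs - n_free, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (rss / dof)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n_free, np.nan)


@dataclass(frozen=True)
class CalibrationResults:
    """Estimates, uncertainties and diagnostics from a calibration fit."""

    model: TrajectoryCalibration = field(repr=False)
    params: ParameterSet
    estimates: dict[str, float]
    stderr: dict[str, float]
    rss: float
    n_obs: int
    converged: bool
    n_restarts: int
    n_restarts_converged: int
    optimizer_status: int

    @property
    def free(self) -> tuple[str, ...]:
        return self.model.free

    def relative_errors(self, truth: ParameterSet) -> dict[str, float]:
        """|estimate - truth| / truth per free parameter."""
        return {
            n: abs(self.estimates[n] - getattr(truth, n)) / getattr(truth, n)
            for n in self.free
        }

    def residuals(self) -> np.ndarray:
        return self.model.residuals(np.array([self.estimates[n] for n in self.free]))

    def residuals_frame(self) -> pd.DataFrame:
        r = self.residuals().reshape(-1, len(self.model._obs_cols))
        df = pd.DataFrame(r, columns=[f"resid_{c}" for c in self.model._obs_cols])
        df.insert(0, "time", self.model.observed.times)
        return df

    def summary(self, truth: ParameterSet | None = None) -> str:
        """Human-readable fit report."""
        lines = [
            "Trajectory calibration results",
            "==============================",
            f"observed variables : {', '.join(self.model._obs_cols)}",
            f"observations       : {self.n_obs}"
            f"  (n_times={self.model.observed.times.size})",
            f"free parameters    : {', '.join(self.free)}",
            f"restarts converged : {self.n_restarts_converged}/{self.n_restarts}",
            f"converged          : {self.converged}",
            f"residual SS        : {self.rss:.6g}",
            f"residual RMS       : {math.sqrt(self.rss / self.n_obs):.6g}",
            "",
            f"{'parameter':<10}{'estimate':>12}{'std err':>12}{'bounds':>22}"
            + ("" if truth is None else f"{'truth':>12}{'rel err':>10}"),
        ]
        for n in self.free:
            lo, hi = self.model.bounds[n]
            row = (
                f"{n:<10}{self.estimates[n]:>12.5g}{self.stderr[n]:>12.3g}"
                f"{f'[{lo:.3g}, {hi:.3g}]':>22}"
            )
            if truth is not None:
                rel = self.relative_errors(truth)[n]
                row += f"{getattr(truth, n):>12.5g}{rel:>10.2%}"
            lines.append(row)
        return "\n".join(lines)

    def to_keyvalue(self, path: str | Path) -> None:
        """Export as flat key-value text (plus use residuals_frame for CSV)."""
        kv = {
            "converged": self.converged,
            "rss": self.rss,
            "n_obs": self.n_obs,
            "n_restarts": self.n_restarts,
            "n_restarts_converged": self.n_restarts_converged,
        }
        for n in self.free:
            kv[f"estimate_{n}"] = self.estimates[n]
            kv[f"stderr_{n}"] = self.stderr[n]
        Path(path).write_text(
            "\n".join(f"{k}: {v}" for k, v in kv.items()) + "\n"
        )


def fit(
    observed: Trajectory,
    free: Sequence[str],
    start: ParameterSet,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    window_fractions: Sequence[float] = (0.1, 0.3, 0.6, 1.0),
    **kwargs,
) -> CalibrationResults:
    """One-call convenience wrapper around :class:`TrajectoryCalibration`."""
    return TrajectoryCalibration(observed, free, start, bounds=bounds, **kwargs).fit(
        n_restarts=n_restarts, seed=seed, window_fractions=window_fractions
    )
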