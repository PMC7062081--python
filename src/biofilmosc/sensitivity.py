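"""Local sensitivity analysis of the non-trivial steady state.

The steady-state concentrations are ratios of monomials in the rate
constants times the aggregate k1*G_E - k4, so their derivatives have
simple closed forms.  They are derived symbolically once (eliminating
transcription errors across the 3x6 table) and evaluated numerically;
an independent central-difference path serves as an oracle.

The biomass conversion factor ``b`` does not enter the steady-state
concentrations and is therefore excluded from the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import sympy as sp

from .dynamics import simulate, summarize_oscillation
from .model import ntss_concentrations
from .params import ParameterSet

__all__ = ["SensitivityTable", "analytic_sensitivities", "numeric_sensitivities"]

#: Parameters the steady state depends on, in table column order.
SENS_PARAMS = ("k1", "k2", "k3", "k4", "k5", "G_E")

#: Concentration row labels.
SENS_ROWS = ("Gp_ss", "A_ss", "Gi_ss")


@dataclass(frozen=True)
class SensitivityTable:
    """Unscaled and scaled steady-state sensitivities.

    ``unscaled`` holds dC/dp (mixed units); ``scaled`` holds the
    dimensionless elasticities (p/C)*dC/dp.  Rows are the three
    steady-state concentrations, columns the parameters k1..k5, G_E.
    """

    unscaled: pd.DataFrame = field(repr=False)
    scaled: pd.DataFrame = field(repr=False)
    params: ParameterSet | None = None

    def max_scaled(self) -> tuple[float, str, str]:
        """Largest scaled sensitivity and its (row, column) location."""
        arr = self.scaled.to_numpy()
        i, j = np.unravel_index(np.argmax(arr), arr.shape)
        return float(arr[i, j]), str(self.scaled.index[i]), str(self.scaled.columns[j])

    def to_csv(self, path: str | Path) -> None:
        """Export both forms as one long CSV with a ``scaled`` boolean column."""
        frames = []
        for scaled_flag, df in ((False, self.unscaled), (True, self.scaled)):
            long = df.reset_index(names="concentration").melt(
                id_vars="concentration", var_name="parameter", value_name="sensitivity"
            )
            long["scaled"] = scaled_flag
            frames.append(long)
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.10g"
        )


@lru_cache(maxsize=1)
def _symbolic_derivatives():
    """Lambdified dC/dp for every concentration and parameter, built once."""
    syms = sp.symbols("k1 k2 k3 k4 k5 G_E", positive=True)
    k1, k2, k3, k4, k5, G_E = syms
    k = k1 * G_E - k4
    conc = {
        "Gp_ss": k * k3 / (k2 * k4),
        "A_ss": k / k2,
        "Gi_ss": k * k3 / (k2 * k5),
    }
    funcs = {}
    for row, expr in conc.items():
        for p_sym, p_name in zip(syms, SENS_PARAMS):
            funcs[(row, p_name)] = sp.lambdify(syms, sp.diff(expr, p_sym), "numpy")
    return funcs


def _require_physical(params: ParameterSet) -> np.ndarray:
    ss = ntss_concentrations(params)
    if ss.min() <= 0:
        raise ValueError(
            "non-trivial steady state is non-physical (k1*G_E <= k4); "
            "sensitivities are undefined"
        )
    return ss


def _build_table(
    params: ParameterSet, unscaled: np.ndarray, ss: np.ndarray
) -> SensitivityTable:
    unscaled_df = pd.DataFrame(unscaled, index=list(SENS_ROWS), columns=list(SENS_PARAMS))
    p_vals = params.values(SENS_PARAMS)
    scaled_df = unscaled_df * p_vals[np.newaxis, :] / ss[:, np.newaxis]
    return SensitivityTable(unscaled=unscaled_df, scaled=scaled_df, params=params)


def analytic_sensitivities(params: ParameterSet) -> SensitivityTable:
    """Closed-form dC/dp and (p/C)*dC/dp at the non-trivial steady state.

    Requires a physical steady state (k1*G_E > k4).  Because k1 and G_E
    enter only through their product, their scaled sensitivities are
    identical: k1*G_E/(k1*G_E - k4) for every concentration.
    """
    if params.variant != "baseline":
        raise ValueError("sensitivity table is defined for the baseline model")
    ss = _require_physical(params)
    funcs = _symbolic_derivatives()
    args = tuple(params.values(SENS_PARAMS))
    unscaled = np.array(
        [[funcs[(row, p)](*args) for p in SENS_PARAMS] for row in SENS_ROWS],
        dtype=float,
    )
    return _build_table(params, unscaled, ss)


def numeric_sensitivities(
    params: ParameterSet,
    rel_step: float = 1e-6,
    mode: str = "steady_state",
    transient: float = 10.0,
    t_end: float = 35.0,
) -> SensitivityTable:
    """Central-difference sensitivities; the independent check on the algebra.

    ``mode='steady_state'`` differences the closed-form concentrations;
    ``mode='average'`` differences long-time cycle averages from
    simulation, which coincide with the steady state by the
    average-equality property of this model class.
    """
    if mode not in ("steady_state", "average"):
        raise ValueError("mode must be 'steady_state' or 'average'")
    ss = _require_physical(params)

    def concentrations(p: ParameterSet) -> np.ndarray:
        if mode == "steady_state":
            return ntss_concentrations(p)
        traj = simulate(p, (1.0, 1.0, 1.0), t_end=t_end)
        summ = summarize_oscillation(traj, transient=transient)
        return np.array([summ.cycle_averages[v] for v in ("Gp", "A", "Gi")])

    unscaled = np.empty((3, len(SENS_PARAMS)))
    for j, name in enumerate(SENS_PARAMS):
        p0 = float(getattr(params, name))
        h = rel_step * p0
        hi = concentrations(params.replace(**{name: p0 + h}))
        lo = concentrations(params.replace(**{name: p0 - h}))
        unscaled[:, j] = (hi - lo) / (2.0 * h)
    return _build_table(params, unscaled, ss)
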