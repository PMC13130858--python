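"""Activation-parameter arithmetic and Arrhenius / van 't Hoff analysis.

Given an activation free energy ΔG‡(T) and a directly averaged activation
enthalpy ΔH‡ at the same temperature, the entropic part follows by
difference, −TΔS‡ = ΔG‡ − ΔH‡.  The multi-temperature alternative is the
computational Arrhenius plot: ordinary least squares of ΔG‡/T on 1/T,
whose slope is ΔH‡ and intercept −ΔS‡ (both assumed T-independent over the
span of the fit).  Local tangent lines drawn with the per-temperature
direct ΔH‡ values diagnose curvature, since d(ΔG/T)/d(1/T) = ΔH.

Units: kcal/mol for energies, Kelvin for temperatures,
R = 1.98720425e-3 kcal/(mol·K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "R_KCAL",
    "KCAL_TO_AMU_A2_PS2",
    "beta",
    "ActivationParameters",
    "ArrheniusFit",
    "LocalSlopeLine",
    "entropy_by_difference",
    "arrhenius_fit",
    "local_slope_lines",
    "standard_state_correction",
    "summarize_activation",
    "make_activation_parameters",
]

#: Gas constant in kcal/(mol K).
R_KCAL: float = 1.98720425e-3

#: 1 kcal/mol expressed in amu Å²/ps² (for Langevin velocities).
KCAL_TO_AMU_A2_PS2: float = 418.4


def beta(temperature: float) -> float:
    """Inverse temperature 1/(R·T) in mol/kcal."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (R_KCAL * temperature)


@dataclass(frozen=True)
class ActivationParameters:
    """Activation parameters at one temperature (kcal/mol, K).

    The identity ΔG‡ = ΔH‡ − TΔS‡ holds by construction.  ``method``
    records provenance: "direct" (single-T averaging) or "arrhenius".
    """

    T: float
    dG: float
    dH: float
    tds: float
    dG_sem: Optional[float] = None
    dH_sem: Optional[float] = None
    tds_sem: Optional[float] = None
    method: str = "direct"

    def __post_init__(self) -> None:
        if abs(self.dG - (self.dH - self.tds)) > 1e-9:
            raise ValueError(
                f"inconsistent activation parameters: dG={self.dG} != dH-TdS={self.dH - self.tds}"
            )


def make_activation_parameters(
    dG: float,
    dH: float,
    T: float,
    dG_sem: Optional[float] = None,
    dH_sem: Optional[float] = None,
    method: str = "direct",
) -> ActivationParameters:
    """Build ActivationParameters with TΔS‡ filled in by difference."""
    tds, _ = entropy_by_difference(dG, dH, T)
    tds_sem = None
    if dG_sem is not None and dH_sem is not None:
        tds_sem = math.hypot(dG_sem, dH_sem)
    return ActivationParameters(
        T=T, dG=dG, dH=dH, tds=tds, dG_sem=dG_sem, dH_sem=dH_sem, tds_sem=tds_sem, method=method
    )


def entropy_by_difference(
    dG: float,
    dH: float,
    T: float,
    dG_sem: Optional[float] = None,
    dH_sem: Optional[float] = None,
):
    """Entropic activation terms from −TΔS‡ = ΔG‡ − ΔH‡ at temperature T.

    Returns (TΔS‡ [kcal/mol], ΔS‡ [kcal/mol/K]); with both input s.e.m.
    values present, returns ((TΔS‡, sem), ΔS‡) uncertainty by quadrature.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    tds = dH - dG
    ds = tds / T
    if dG_sem is not None and dH_sem is not None:
        return (tds, math.hypot(dG_sem, dH_sem)), ds
    return tds, ds


@dataclass(frozen=True)
class ArrheniusFit:
    """Linear fit of ΔG‡/T against 1/T.

    slope = ΔH‡ (kcal/mol), intercept = −ΔS‡ (kcal/mol/K); standard
    errors are the asymptotic ones from the regression covariance (NaN for
    an exact two-point solve, where they are undefined).
    """

    temperatures: np.ndarray
    dG: np.ndarray
    sem: Optional[np.ndarray]
    dH: float
    dS: float
    dH_se: float
    dS_se: float
    residuals: np.ndarray
    weighted: bool = False

    def predict_dG(self, T) -> np.ndarray:
        """ΔG‡(T) = ΔH‡ − T·ΔS‡ reconstructed from the fit."""
        return self.dH - np.asarray(T, dtype=float) * self.dS

    def tds(self, T: float) -> float:
        """TΔS‡ at a given temperature from the fitted ΔS‡."""
        return T * self.dS

    def params(self, T: float) -> ActivationParameters:
        return ActivationParameters(
            T=T,
            dG=float(self.predict_dG(T)),
            dH=self.dH,
            tds=self.tds(T),
            dG_sem=None,
            dH_sem=self.dH_se if np.isfinite(self.dH_se) else None,
            tds_sem=T * self.dS_se if np.isfinite(self.dS_se) else None,
            method="arrhenius",
        )


def arrhenius_fit(
    points: Sequence[tuple],
    weighted: bool = False,
) -> ArrheniusFit:
    """Fit ΔG‡/T = ΔH‡·(1/T) − ΔS‡ by (weighted) least squares.

    ``points`` is a sequence of (T, ΔG‡) or (T, ΔG‡, sem) tuples with
    distinct temperatures.  The default fit is unweighted; ``weighted=True``
    uses 1/sem² weights (requires sem for every point).  Two points give
    the exact solve with undefined (NaN) standard errors.
    """
    if len(points) < 2:
        raise ValueError("arrhenius_fit needs at least 2 points")
    temps = np.array([p[0] for p in points], dtype=float)
    dg = np.array([p[1] for p in points], dtype=float)
    sems = None
    if all(len(p) >= 3 and p[2] is not None for p in points):
        sems = np.array([p[2] for p in points], dtype=float)
    if len(np.unique(temps)) != len(temps):
        raise ValueError("duplicate temperatures in Arrhenius fit")

    x = 1.0 / temps
    y = dg / temps
    X = sm.add_constant(x)
    if weighted:
        if sems is None:
            raise ValueError("weighted fit requires an s.e.m. for every point")
        # y = dG/T, so its sem scales as sem/T
        model = sm.WLS(y, X, weights=(temps / sems) ** 2)
    else:
        model = sm.OLS(y, X)
    res = model.fit()
    intercept, slope = res.params
    if len(points) == 2:
        se_i, se_s = math.nan, math.nan
    else:
        se_i, se_s = res.bse
    return ArrheniusFit(
        temperatures=temps,
        dG=dg,
        sem=sems,
        dH=float(slope),
        dS=float(-intercept),
        dH_se=float(se_s),
        dS_se=float(se_i),
        residuals=np.asarray(res.resid),
        weighted=weighted,
    )


@dataclass(frozen=True)
class LocalSlopeLine:
    """Tangent line at one direct-calculation point in (1/T, ΔG‡/T) space."""

    T: float
    x0: float  # 1/T
    y0: float  # dG/T
    slope: float  # direct dH at this T

    def y_at(self, x) -> np.ndarray:
        return self.y0 + self.slope * (np.asarray(x, dtype=float) - self.x0)


def local_slope_lines(params_by_T: Sequence[ActivationParameters]):
    """Per-temperature tangent lines from direct ΔH‡ values.

    Since d(ΔG/T)/d(1/T) = ΔH, each direct calculation fixes the local
    slope of the Arrhenius plot at its own temperature.  Returns the lines
    and a curvature diagnostic: the spread (max−min) of local slopes and
    their standard deviation, NaN for a single point.
    """
    lines = [
        LocalSlopeLine(T=p.T, x0=1.0 / p.T, y0=p.dG / p.T, slope=p.dH) for p in params_by_T
    ]
    slopes = np.array([ln.slope for ln in lines])
    if len(lines) > 1:
        curvature = {"slope_spread": float(np.ptp(slopes)), "slope_std": float(np.std(slopes, ddof=1))}
    else:
        curvature = {"slope_spread": math.nan, "slope_std": math.nan}
    return lines, curvature


def standard_state_correction(dG: float, conc: float, T: float):
    """Correct a bimolecular ΔG‡ to a reference concentration.

    Treating the second reactant at concentration ``conc`` (mol/L, e.g.
    55 M for water as the reaction partner) rather than the 1 M standard
    state adds ΔΔG = −RT·ln(conc/1 M) to the barrier, equivalent to a
    rate ``conc``× faster.  Returns (corrected ΔG‡, rate factor).
    """
    if conc <= 0:
        raise ValueError(f"concentration must be positive, got {conc}")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T}")
    ddg = -R_KCAL * T * math.log(conc)
    return dG + ddg, conc


def summarize_activation(table: Sequence[ActivationParameters]) -> pd.DataFrame:
    """Summary table over temperatures and methods.

    Returns a DataFrame with one row per entry (T, method, ΔG‡, ΔH‡, TΔS‡
    and s.e.m. columns) plus "mean" rows per method (arithmetic mean of
    ΔH‡ and TΔS‡ over temperatures).  When both a direct and an arrhenius
    entry exist at the same temperature, a direct-minus-arrhenius delta
    row is appended.
    """
    if len(table) == 0:
        raise ValueError("empty activation-parameter table")
    rows = [
        {
            "T": p.T,
            "method": p.method,
            "dG": p.dG,
            "dH": p.dH,
            "tds": p.tds,
            "dG_sem": p.dG_sem,
            "dH_sem": p.dH_sem,
            "tds_sem": p.tds_sem,
        }
        for p in table
    ]
    df = pd.DataFrame(rows)
    extra = []
    for method, grp in df.groupby("method"):
        extra.append(
            {
                "T": math.nan,
                "method": f"{method}-mean",
                "dG": grp["dG"].mean(),
                "dH": grp["dH"].mean(),
                "tds": grp["tds"].mean(),
            }
        )
    direct = df[df["method"] == "direct"].set_index("T")
    arrh = df[df["method"] == "arrhenius"].set_index("T")
    for T in sorted(set(direct.index) & set(arrh.index)):
        extra.append(
            {
                "T": T,
                "method": "direct-minus-arrhenius",
                "dG": direct.loc[T, "dG"] - arrh.loc[T, "dG"],
                "dH": direct.loc[T, "dH"] - arrh.loc[T, "dH"],
                "tds": direct.loc[T, "tds"] - arrh.loc[T, "tds"],
            }
        )
    return pd.concat([df, pd.DataFrame(extra)], ignore_index=True)
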