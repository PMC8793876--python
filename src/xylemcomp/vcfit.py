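"""Vulnerability-curve fitting: PLC, sigmoid (P50, S) and specific conductivity.

The percentage loss of conductance for a branch spun at decreasing xylem
pressures P is modelled as

    PLC(P) = 100 / (1 + exp(S/25 * (P - P50)))

so that PLC(P50) = 50 and the slope of the curve at the inflection point
is -S (% per MPa; PLC rises as P becomes more negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ConductanceSeries",
    "VCFit",
    "compute_plc",
    "fit_vc",
    "predict_plc",
    "compute_ks",
    "fit_branches",
    "species_means",
    "read_curves_csv",
]


@dataclass
class ConductanceSeries:
    """One branch's centrifuge protocol record.

    ``pressures`` are in MPa, non-positive and strictly decreasing;
    ``conductances`` is a (n_steps, n_replicates) array (replicates may
    contain NaN for missing measurements). ``length`` in m, ``area``
    (sapwood) in m^2.
    """

    branch_id: str
    species: str
    pressures: np.ndarray
    conductances: np.ndarray
    length: float = 0.27
    area: float = 1e-5

    def __post_init__(self):
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.conductances = np.atleast_2d(np.asarray(self.conductances, dtype=float))
        if self.pressures.ndim != 1 or len(self.pressures) < 4:
            raise ValueError("need at least 4 pressure steps")
        if np.any(self.pressures > 0):
            raise ValueError("xylem pressures must be <= 0 MPa")
        if np.any(np.diff(self.pressures) >= 0):
            raise ValueError("pressures must be strictly decreasing")
        if self.conductances.shape[0] != len(self.pressures):
            raise ValueError("conductance rows must match pressure steps")
        k = self.conductances[np.isfinite(self.conductances)]
        if np.any(k < 0):
            raise ValueError("conductances must be >= 0")
        if not (self.length > 0 and self.area > 0):
            raise ValueError("length and sapwood area must be positive")

    def replicate_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.conductances, axis=1)


@dataclass
class VCFit:
    """Fitted sigmoid vulnerability curve for one branch."""

    p50: float
    s: float
    kmax: float = np.nan
    ks: float = np.nan
    sse: float = np.nan
    converged: bool = True
    fitted_plc: np.ndarray | None = field(default=None, repr=False)
    low_information: bool = False
    branch_id: str = ""
    species: str = ""

    def predict(self, pressure) -> np.ndarray:
        return predict_plc(self, pressure)


def compute_plc(series: ConductanceSeries, kmax_mode: str = "first") -> tuple[np.ndarray, float]:
    """Per-step PLC (%) and the reference conductance kmax.

    ``kmax_mode='first'`` (default) takes the replicate mean at the
    least-negative pressure step — the measurement closest to zero
    pressure; ``'max'`` takes the maximum replicate mean over all steps.
    PLC is clamped to [0, 100] (a replicate mean above kmax counts as 0
    loss).
    """
    kbar = series.replicate_means()
    if kmax_mode == "first":
        kmax = kbar[0]
    elif kmax_mode == "max":
        kmax = float(np.nanmax(kbar))
    else:
        raise ValueError(f"unknown kmax_mode {kmax_mode!r}")
    if not np.isfinite(kmax) or kmax <= 0:
        raise ValueError(f"branch {series.branch_id}: kmax = {kmax} is unusable")
    plc = 100.0 * (1.0 - kbar / kmax)
    return np.clip(plc, 0.0, 100.0), float(kmax)


def _sigmoid(p: np.ndarray, p50: float, s: float) -> np.ndarray:
    z = s / 25.0 * (p - p50)
    # exp overflow is harmless here but noisy; clip the argument
    return 100.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def predict_plc(fit: VCFit, pressure) -> np.ndarray | float:
    """Evaluate the fitted sigmoid at xylem pressure(s) in MPa."""
    p = np.asarray(pressure, dtype=float)
    out = _sigmoid(p, fit.p50, fit.s)
    return float(out) if np.isscalar(pressure) else out


def fit_vc(
    pressures,
    plc,
    branch_id: str = "",
    species: str = "",
    max_starts: int = 3,
) -> VCFit:
    """Bounded nonlinear least squares of the sigmoid model.

    P50 is constrained to [min(P) - 2, -0.1] MPa and S to (0, 500].
    Initial P50 is the linear interpolation of the pressure at PLC = 50,
    initial S the secant slope magnitude between the 20% and 80%
    crossings.  On non-convergence the fit is retried from jittered
    starts and, failing that, returned flagged rather than raising.
    """
    p = np.asarray(pressures, dtype=float)
    y = np.asarray(plc, dtype=float)
    if len(p) < 4:
        raise ValueError("need at least 4 points to fit")
    if np.any(y < -1e-9) or np.any(y > 100 + 1e-9):
        raise ValueError("PLC values must lie in [0, 100]")
    y = np.clip(y, 0.0, 100.0)
    low_info = not (y.min() <= 20.0 and y.max() >= 80.0)

    lo, hi = (min(p.min() - 2.0, -0.1), 1e-6), (-0.1, 500.0)

    # initial guesses from the empirical crossings
    order = np.argsort(p)[::-1]  # from least to most negative
    ps, ys = p[order], y[order]

    def crossing(level: float) -> float:
        idx = np.where(ys >= level)[0]
        if len(idx) == 0:
            return ps[-1]
        j = idx[0]
        if j == 0 or ys[j] == ys[j - 1]:
            return ps[j]
        f = (level - ys[j - 1]) / (ys[j] - ys[j - 1])
        return ps[j - 1] + f * (ps[j] - ps[j - 1])

    p50_0 = float(np.clip(crossing(50.0), lo[0], hi[0]))
    p20, p80 = crossing(20.0), crossing(80.0)
    if p80 < p20:  # pressure drops while PLC rises
        s0 = 60.0 / abs(p80 - p20)
    else:
        s0 = 30.0
    s0 = float(np.clip(s0, 1.0, hi[1]))

    def residuals(theta):
        return _sigmoid(p, theta[0], theta[1]) - y

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_starts):
        if attempt == 0:
            x0 = [p50_0, s0]
        else:
            x0 = [
                float(np.clip(p50_0 + rng.normal(0, 0.5), lo[0], hi[0])),
                float(np.clip(s0 * np.exp(rng.normal(0, 0.5)), 1.0, hi[1])),
            ]
        res = least_squares(residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        sse = float(2 * res.cost)
        if best is None or sse < best[1]:
            best = (res, sse)
        if res.success and sse < best[1] * (1 + 1e-9):
            break
    res, sse = best
    p50_hat, s_hat = float(res.x[0]), float(res.x[1])
    return VCFit(
        p50=p50_hat,
        s=s_hat,
        sse=sse,
        converged=bool(res.success),
        fitted_plc=_sigmoid(p, p50_hat, s_hat),
        low_information=low_info,
        branch_id=branch_id,
        species=species,
    )


def compute_ks(kmax: float, length: float, area: float, mode: str = "standard") -> float:
    """Specific hydraulic conductivity from maximum conductance.

    ``mode='standard'``: Ks = kmax * L / A (conductance times length per
    sapwood area, the physically standard specific conductivity).
    ``mode='literal'``: Ks = kmax / (L * A), the reading "divided by
    sample length and sapwood area" taken verbatim.  The two differ by a
    factor L^2.
    """
    if not (kmax > 0 and length > 0 and area > 0):
        raise ValueError("kmax, length, and area must all be positive")
    if mode == "standard":
        return kmax * length / area
    if mode == "literal":
        return kmax / (length * area)
    raise ValueError(f"unknown ks mode {mode!r}")


def fit_branch(
    series: ConductanceSeries,
    ks_mode: str = "standard",
    kmax_mode: str = "first",
    include_reference: bool = False,
) -> VCFit:
    """PLC computation + sigmoid fit + Ks for one branch.

    With ``kmax_mode='first'`` the first step defines kmax, so its PLC is
    identically 0 and carries no curve information; it is excluded from
    the fit by default (kept when fewer than 5 steps are available).
    """
    plc, kmax = compute_plc(series, kmax_mode=kmax_mode)
    skip = 1 if (not include_reference and kmax_mode == "first" and len(plc) >= 5) else 0
    fit = fit_vc(
        series.pressures[skip:], plc[skip:], branch_id=series.branch_id, species=series.species
    )
    fit.kmax = kmax
    fit.ks = compute_ks(kmax, series.length, series.area, mode=ks_mode)
    return fit


def fit_branches(
    series_list: list[ConductanceSeries], ks_mode: str = "standard", kmax_mode: str = "first"
) -> pd.DataFrame:
    """Fit every branch; returns one row per branch."""
    rows = []
    for s in series_list:
        f = fit_branch(s, ks_mode=ks_mode, kmax_mode=kmax_mode)
        rows.append(
            {
                "branch_id": f.branch_id,
                "species": f.species,
                "P50_MPa": f.p50,
                "S_pct_per_MPa": f.s,
                "kmax": f.kmax,
                "Ks": f.ks,
                "SSE": f.sse,
                "converged": f.converged,
                "low_information": f.low_information,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["ks_mode"] = ks_mode
    return out


def species_means(branch_fits: pd.DataFrame) -> pd.DataFrame:
    """Equal-weight per-species means of branch-level fits.

    Adds ``P50_abs_MPa``, the sign convention used by all downstream
    comparative statistics.
    """
    cols = ["P50_MPa", "S_pct_per_MPa", "kmax", "Ks"]
    g = branch_fits.groupby("species")[cols].mean()
    g["P50_abs_MPa"] = g["P50_MPa"].abs()
    g["n_branches"] = branch_fits.groupby("species").size()
    return g.reset_index()


def read_curves_csv(path) -> list[ConductanceSeries]:
    """Load branches from a long-format CSV.

    Expected columns: branch_id, species, pressure_MPa, k_rep1..k_repN,
    length_m, sapwood_area_m2 (one row per pressure step).
    """
    df = pd.read_csv(path)
    krep = [c for c in df.columns if c.startswith("k_rep")]
    if not krep:
        raise ValueError("no replicate conductance columns (k_rep*) found")
    out = []
    for bid, grp in df.groupby("branch_id", sort=False):
        grp = grp.sort_values("pressure_MPa", ascending=False)
        out.append(
            ConductanceSeries(
                branch_id=str(bid),
                species=str(grp["species"].iloc[0]),
                pressures=grp["pressure_MPa"].to_numpy(),
                conductances=grp[krep].to_numpy(),
                length=float(grp["length_m"].iloc[0]),
                area=float(grp["sapwood_area_m2"].iloc[0]),
            )
        )
    return out
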