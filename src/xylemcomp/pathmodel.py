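"""Recursive path analysis over standardized observed traits.

A model is a set of linear equations "endogenous ~ predictor + ..."
forming a DAG.  Each equation is estimated by OLS on z-standardized
data (ML-equivalent for recursive models with uncorrelated residuals).
Fit is judged by the likelihood-ratio chi-square comparing the implied
covariance Sigma(theta) with the sample covariance S:

    F_ML = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p,   chi2 = (N - 1) F_ML

with df = p(p+1)/2 minus free parameters (path coefficients, residual
variances, and the saturated exogenous covariance block).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from xylemcomp.compstats import TraitTable, _ols

__all__ = ["PathSpec", "PathFit", "fit_path_model", "effects_decomposition", "parse_spec_text"]


@dataclass
class PathSpec:
    """Ordered regression equations defining a recursive (DAG) path model."""

    equations: list[tuple[str, list[str]]]  # (endogenous, predictors)

    def __post_init__(self):
        endo = [e for e, _ in self.equations]
        if len(set(endo)) != len(endo):
            raise ValueError("each endogenous variable may appear once on the left-hand side")
        self._check_dag()

    @property
    def endogenous(self) -> list[str]:
        return [e for e, _ in self.equations]

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for e, preds in self.equations:
            for v in preds + [e]:
                seen.setdefault(v)
        return list(seen)

    @property
    def exogenous(self) -> list[str]:
        endo = set(self.endogenous)
        return [v for v in self.variables if v not in endo]

    def edges(self) -> list[tuple[str, str]]:
        return [(p, e) for e, preds in self.equations for p in preds]

    def _check_dag(self) -> None:
        # Kahn's algorithm over the edge list
        nodes = set(self.variables)
        out: dict[str, set[str]] = {v: set() for v in nodes}
        indeg = {v: 0 for v in nodes}
        for src, dst in self.edges():
            if dst not in out[src]:
                out[src].add(dst)
                indeg[dst] += 1
        queue = [v for v in nodes if indeg[v] == 0]
        seen = 0
        while queue:
            v = queue.pop()
            seen += 1
            for w in out[v]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    queue.append(w)
        if seen != len(nodes):
            raise ValueError("path specification contains a cycle (model must be recursive)")


def parse_spec_text(text: str) -> PathSpec:
    """Parse equations like ``VE ~ TO + MF`` (one per line, '#' comments)."""
    eqs = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "~" not in line:
            raise ValueError(f"line {lineno}: expected 'lhs ~ rhs', got {line!r}")
        lhs, rhs = line.split("~", 1)
        preds = [tok.strip() for tok in rhs.split("+") if tok.strip()]
        if not lhs.strip() or not preds:
            raise ValueError(f"line {lineno}: empty side in {line!r}")
        eqs.append((lhs.strip(), preds))
    if not eqs:
        raise ValueError("empty path specification")
    return PathSpec(eqs)


# preset arrow structures for the two bundled hydraulic outcome models
P50_MODEL = (
    "TO ~ DT_um + DPA_um\n"
    "MF ~ DPM_um + DT_um\n"
    "VE ~ TO + MF\n"
    "R_PA_MPa_s_m3 ~ DPA_um + Tw_um\n"
    "P50_abs_MPa ~ VE + R_PA_MPa_s_m3\n"
)
KS_MODEL = (
    "R_PA_MPa_s_m3 ~ DPA_um + Tw_um\n"
    "Ks ~ Dh_um + TD_per_mm2 + Tw_um + R_PA_MPa_s_m3\n"
)


@dataclass
class PathFit:
    spec: PathSpec
    coefficients: pd.DataFrame  # rows: (endogenous, predictor, estimate, se, t, p)
    residual_variances: dict[str, float]
    exogenous_cov: pd.DataFrame
    chi2: float
    df: int
    p_value: float
    n: int
    implied_cov: pd.DataFrame = field(repr=False, default=None)
    sample_cov: pd.DataFrame = field(repr=False, default=None)

    def edge_coefficient(self, src: str, dst: str) -> float:
        m = self.coefficients
        row = m[(m["endogenous"] == dst) & (m["predictor"] == src)]
        return float(row["estimate"].iloc[0]) if len(row) else 0.0


def fit_path_model(table: TraitTable, spec: PathSpec) -> PathFit:
    """Estimate a recursive path model on z-standardized complete cases."""
    variables = spec.variables
    missing = [v for v in variables if v not in table.traits]
    if missing:
        raise ValueError(f"variables not in trait table: {missing}")
    D = table.data[variables].dropna()
    n = len(D)
    if n < len(variables) + 2:
        raise ValueError(f"need >= {len(variables) + 2} complete cases, have {n}")
    Z = (D - D.mean()) / D.std(ddof=1)
    p = len(variables)
    idx = {v: i for i, v in enumerate(variables)}

    B = np.zeros((p, p))  # B[dst, src] = path coefficient
    resid_var: dict[str, float] = {}
    rows = []
    for endo, preds in spec.equations:
        X = Z[preds].to_numpy(dtype=float)
        y = Z[endo].to_numpy(dtype=float)
        beta, rss, se, df_resid = _ols(X, y)
        # ML residual variance (divide by n) to match the Wishart likelihood
        resid_var[endo] = rss / n
        for i, pr in enumerate(preds):
            est, s = beta[1 + i], se[1 + i]
            t = est / s if s > 0 else np.nan
            rows.append(
                {
                    "endogenous": endo,
                    "predictor": pr,
                    "estimate": est,
                    "se": s,
                    "t": t,
                    "p": 2 * stats.t.sf(abs(t), df_resid) if np.isfinite(t) else np.nan,
                }
            )
            B[idx[endo], idx[pr]] = est

    # Psi: residual variances for endogenous, sample covariances (ML, /n) among exogenous
    Zv = Z.to_numpy(dtype=float)
    S_ml = (Zv.T @ Zv) / n - np.outer(Zv.mean(0), Zv.mean(0))
    exog = spec.exogenous
    Psi = np.zeros((p, p))
    for a in exog:
        for b in exog:
            Psi[idx[a], idx[b]] = S_ml[idx[a], idx[b]]
    for e, v in resid_var.items():
        Psi[idx[e], idx[e]] = v

    Iminus = np.eye(p) - B
    try:
        A = np.linalg.inv(Iminus)
    except np.linalg.LinAlgError as e:  # cannot happen for a DAG, defensive
        raise ValueError("singular (I - B); model is not recursive") from e
    Sigma = A @ Psi @ A.T

    sign_S, logdet_S = np.linalg.slogdet(S_ml)
    sign_Sig, logdet_Sig = np.linalg.slogdet(Sigma)
    if sign_S <= 0:
        raise ValueError("singular sample covariance (collinear or constant traits)")
    if sign_Sig <= 0:
        raise ValueError("singular implied covariance; check the exogenous block")
    f_ml = logdet_Sig + np.trace(S_ml @ np.linalg.inv(Sigma)) - logdet_S - p
    chi2 = max((n - 1) * f_ml, 0.0)

    n_edges = len(spec.edges())
    q = len(exog)
    free = n_edges + len(spec.endogenous) + q * (q + 1) // 2
    df = p * (p + 1) // 2 - free
    if df < 0:
        raise ValueError(f"negative degrees of freedom ({df}); model is over-parameterized")
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    if df == 0:
        chi2 = 0.0 if chi2 < 1e-8 else chi2

    return PathFit(
        spec=spec,
        coefficients=pd.DataFrame(rows),
        residual_variances=resid_var,
        exogenous_cov=pd.DataFrame(
            S_ml[np.ix_([idx[a] for a in exog], [idx[b] for b in exog])], index=exog, columns=exog
        ),
        chi2=float(chi2),
        df=int(df),
        p_value=p_value,
        n=n,
        implied_cov=pd.DataFrame(Sigma, index=variables, columns=variables),
        sample_cov=pd.DataFrame(S_ml, index=variables, columns=variables),
    )


def effects_decomposition(fit: PathFit, outcome: str) -> pd.DataFrame:
    """Direct, indirect and total effects of every variable on ``outcome``.

    direct = edge coefficient into the outcome (0 if absent); indirect =
    sum over all directed paths of length >= 2 of the product of edge
    coefficients; total = direct + indirect.  Computed from the matrix
    series (I - B)^-1 = I + B + B^2 + ...
    """
    variables = fit.spec.variables
    if outcome not in variables:
        raise ValueError(f"outcome {outcome!r} not in the model")
    p = len(variables)
    idx = {v: i for i, v in enumerate(variables)}
    B = np.zeros((p, p))
    for (src, dst) in fit.spec.edges():
        B[idx[dst], idx[src]] = fit.edge_coefficient(src, dst)
    total_mat = np.linalg.inv(np.eye(p) - B) - np.eye(p)
    rows = []
    for v in variables:
        if v == outcome:
            continue
        direct = B[idx[outcome], idx[v]]
        total = total_mat[idx[outcome], idx[v]]
        rows.append(
            {"variable": v, "direct": direct, "indirect": total - direct, "total": total}
        )
    return pd.DataFrame(rows).set_index("variable")
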