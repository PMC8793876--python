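"""Comparative statistics over a species trait table and a phylogeny.

Implements the full battery used downstream: Pearson correlation
matrices, Felsenstein independent contrasts and through-origin contrast
correlations, Blomberg's K with a tip-shuffle permutation test, one-way
ANOVA with Tukey HSD and compact letter display, correlation-matrix PCA,
VIF screening, and exhaustive-AICc multimodel selection with
zero-substitution averaging and variable importance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from xylemcomp.treeio import PhyloTree, phylo_vcv

__all__ = [
    "TraitTable",
    "ContrastSet",
    "SignalResult",
    "AnovaTukeyResult",
    "ModelSelectionResult",
    "pearson_matrix",
    "pic",
    "independent_contrasts",
    "resolve_polytomies",
    "blomberg_k",
    "anova_tukey",
    "compact_letters",
    "pca",
    "vif",
    "aicc_model_selection",
]


@dataclass
class TraitTable:
    """Species x trait matrix with optional units.

    ``data`` is indexed by unique species names; values are finite floats
    or NaN (explicitly missing).
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species: {dups}")
        with np.errstate(invalid="ignore"):
            bad = ~(np.isfinite(self.data.to_numpy(dtype=float)) | self.data.isna().to_numpy())
        if bad.any():
            raise ValueError("trait table contains non-finite, non-missing values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, species_col: str = "species", units=None) -> "TraitTable":
        return cls(df.set_index(species_col).astype(float), units=units or {})

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, trait: str, species_order: list[str]) -> np.ndarray:
        return self.data.loc[species_order, trait].to_numpy(dtype=float)


def _match_tree_table(tree: PhyloTree, table: TraitTable) -> list[str]:
    tips = set(tree.tip_labels())
    sp = set(table.species)
    if tips != sp:
        raise ValueError(
            f"tree/table species mismatch; only in tree: {sorted(tips - sp)}, "
            f"only in table: {sorted(sp - tips)}"
        )
    return tree.tip_labels()


# ---------------------------------------------------------------------------
# correlations

def pearson_matrix(table: TraitTable, traits: list[str] | None = None, alpha: float = 0.05):
    """Pairwise complete-case Pearson r with two-sided t-test p-values.

    Returns (r, p, n) DataFrames.  Pairs with < 3 complete cases or a
    constant trait get NaN with the reason recorded in ``r.attrs``.
    """
    cols = traits or table.traits
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    reasons = {}
    X = table.data[cols].to_numpy(dtype=float)
    for i in range(k):
        r[i, i], p[i, i], n[i, i] = 1.0, 0.0, int(np.isfinite(X[:, i]).sum())
        for j in range(i + 1, k):
            mask = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            m = int(mask.sum())
            n[i, j] = n[j, i] = m
            if m < 3:
                reasons[(cols[i], cols[j])] = f"only {m} complete cases"
                continue
            x, y = X[mask, i], X[mask, j]
            if np.std(x) == 0 or np.std(y) == 0:
                reasons[(cols[i], cols[j])] = "constant trait"
                continue
            rr, pp = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    ndf = pd.DataFrame(n, index=cols, columns=cols)
    rdf.attrs["missing_reasons"] = reasons
    rdf.attrs["alpha"] = alpha
    return rdf, pdf, ndf


# ---------------------------------------------------------------------------
# independent contrasts

@dataclass
class ContrastSet:
    trait: str
    contrasts: np.ndarray  # standardized, one per internal node
    variances: np.ndarray  # sum of adjusted child branch lengths
    node_order: list[int]  # internal node ids, postorder


def resolve_polytomies(tree: PhyloTree, strict: bool = False) -> PhyloTree:
    """Arbitrary zero-length binary resolution of multifurcations."""
    if tree.is_binary():
        return tree
    if strict:
        raise ValueError("tree contains polytomies (strict mode)")
    warnings.warn("polytomies resolved arbitrarily with zero-length branches", stacklevel=2)
    parent = list(tree.parent)
    length = list(tree.length)
    children = [list(c) for c in tree.children]
    labels = dict(tree.labels)
    for node in range(len(parent)):
        while len(children[node]) > 2:
            # pull the last two children under a new zero-length node
            a = children[node].pop()
            b = children[node].pop()
            nid = len(parent)
            parent.append(node)
            length.append(0.0)
            children.append([b, a])
            parent[a] = parent[b] = nid
            children[node].append(nid)
    out = PhyloTree(parent, length, children, labels, root=tree.root)
    out.validate()
    return out


def independent_contrasts(tree: PhyloTree, values: dict[str, float], trait: str = "") -> ContrastSet:
    """Felsenstein pruning: standardized contrasts at each internal node.

    ``values`` maps tip label -> trait value.  The tree must be binary
    (resolve polytomies first).
    """
    if not tree.is_binary():
        tree = resolve_polytomies(tree)
    x = np.zeros(tree.n_nodes)
    v = np.array(tree.length, dtype=float)
    contrasts, variances, nodes = [], [], []
    for node in tree.postorder():
        kids = tree.children[node]
        if not kids:
            x[node] = values[tree.labels[node]]
            continue
        i, j = kids
        denom = v[i] + v[j]
        if denom <= 0:
            raise ValueError(f"zero contrast variance at node {node} (zero-length cherry)")
        contrasts.append((x[i] - x[j]) / np.sqrt(denom))
        variances.append(denom)
        nodes.append(node)
        x[node] = (x[i] / v[i] + x[j] / v[j]) / (1.0 / v[i] + 1.0 / v[j])
        v[node] += v[i] * v[j] / denom
    return ContrastSet(trait, np.array(contrasts), np.array(variances), nodes)


def pic(tree: PhyloTree, table: TraitTable, trait_x: str, trait_y: str):
    """PIC correlation of two traits: through-origin r over contrast pairs.

    Returns (r, p, ContrastSet_x, ContrastSet_y); p is two-sided from a t
    distribution with n_contrasts - 1 degrees of freedom.
    """
    order = _match_tree_table(tree, table)
    btree = resolve_polytomies(tree)
    vx = dict(zip(order, table.values_for(trait_x, order)))
    vy = dict(zip(order, table.values_for(trait_y, order)))
    cx = independent_contrasts(btree, vx, trait_x)
    cy = independent_contrasts(btree, vy, trait_y)
    c1, c2 = cx.contrasts, cy.contrasts
    denom = np.sqrt(np.sum(c1**2) * np.sum(c2**2))
    if denom == 0:
        return np.nan, np.nan, cx, cy
    r = float(np.sum(c1 * c2) / denom)
    df = len(c1) - 1
    r_ = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_ * np.sqrt(df / (1 - r_**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p, cx, cy


def pic_matrix(tree: PhyloTree, table: TraitTable, traits: list[str] | None = None):
    """All-pairs PIC correlations; returns (r, p) DataFrames."""
    cols = traits or table.traits
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(k):
            for j in range(i + 1, k):
                rr, pp, _, _ = pic(tree, table, cols[i], cols[j])
                r[i, j] = r[j, i] = rr
                p[i, j] = p[j, i] = pp
    return pd.DataFrame(r, index=cols, columns=cols), pd.DataFrame(p, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# Blomberg's K

@dataclass
class SignalResult:
    trait: str
    k: float
    p_value: float
    n_perm: int
    seed: int | None
    mse_observed: float


def _k_statistic(X: np.ndarray, Vinv: np.ndarray, expected_ratio: float) -> np.ndarray:
    """Blomberg's K for each row of X (vectorized over permutations)."""
    n = X.shape[1]
    ones = np.ones(n)
    w = Vinv @ ones
    denom_a = ones @ w
    a_hat = (X @ w) / denom_a
    R = X - a_hat[:, None]
    mse0 = np.einsum("ij,ij->i", R, R) / (n - 1)
    mse = np.einsum("ij,jk,ik->i", R, Vinv, R) / (n - 1)
    return (mse0 / mse) / expected_ratio, mse


def blomberg_k(
    tree: PhyloTree,
    table: TraitTable,
    trait: str,
    n_perm: int = 999,
    seed: int | None = None,
    prune: list[str] | None = None,
) -> SignalResult:
    """Blomberg's K with a tip-shuffle permutation test on the GLS MSE.

    K compares the tip variance around the phylogenetic mean with the
    Brownian-motion (GLS) variance, scaled by its expectation under BM;
    K ~ 1 for a Brownian trait, ~ 0 for no signal.  The permutation p is
    the observed-inclusive rank of the observed MSE among ``n_perm``
    shuffles of the tip values (smaller MSE = stronger signal).
    """
    if prune:
        tree = tree.prune_tips(prune)
    order = _match_tree_table(tree, table)
    x = table.values_for(trait, order)
    if np.any(~np.isfinite(x)):
        raise ValueError(f"trait {trait!r} has missing values; complete cases required")
    vcv = phylo_vcv(tree)
    V = vcv.matrix
    # vcv tip order equals tree.tip_labels() == order
    n = len(x)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular phylogenetic covariance (zero-length cherries?)") from e
    ones = np.ones(n)
    denom_a = ones @ Vinv @ ones
    expected_ratio = (np.trace(V) - n / denom_a) / (n - 1)
    k_obs, mse_obs = _k_statistic(x[None, :], Vinv, expected_ratio)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    _, mse_perm = _k_statistic(perms, Vinv, expected_ratio)
    p = (1 + int(np.sum(mse_perm <= mse_obs[0]))) / (n_perm + 1)
    return SignalResult(trait, float(k_obs[0]), float(p), n_perm, seed, float(mse_obs[0]))


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD

@dataclass
class AnovaTukeyResult:
    factor: str
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise_p: pd.DataFrame
    letters: dict[str, str]
    excluded_groups: list[str]


def compact_letters(groups: list[str], sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Greedy insert-absorb compact letter display.

    Groups sharing a letter are not significantly different; ties are
    broken by the given group order.
    """
    sets: list[set[str]] = [set(groups)]
    for a, b in sorted(sig_pairs):
        new_sets = []
        for s in sets:
            if a in s and b in s:
                new_sets.extend([s - {a}, s - {b}])
            else:
                new_sets.append(s)
        # drop empties and duplicates, absorb proper subsets
        uniq: list[set[str]] = []
        for s in new_sets:
            if s and s not in uniq:
                uniq.append(s)
        sets = [s for s in uniq if not any(s < t for t in uniq)]
    # stable letter order: sort sets by earliest member in group order
    pos = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(pos[g] for g in s))
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out = {g: "" for g in groups}
    for letter, s in zip(alphabet, sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def anova_tukey(values, groups, alpha: float = 0.05, factor: str = "group") -> AnovaTukeyResult:
    """One-way ANOVA with Tukey-Kramer HSD and compact letters.

    Groups with a single observation are excluded with a warning.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float), "g": list(groups)}).dropna()
    sizes = df.groupby("g").size()
    excluded = sizes[sizes < 2].index.tolist()
    if excluded:
        warnings.warn(f"groups with < 2 observations excluded: {excluded}", stacklevel=2)
        df = df[~df["g"].isin(excluded)]
    names = list(dict.fromkeys(df["g"]))  # preserve first-appearance order
    if len(names) < 2:
        raise ValueError("need at least 2 groups with >= 2 observations")
    samples = [df.loc[df["g"] == g, "y"].to_numpy() for g in names]
    n_tot = sum(len(s) for s in samples)
    k = len(names)
    pw = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    sig = set()
    if df["y"].nunique() == 1:  # all observations identical: no variance anywhere
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = stats.f_oneway(*samples)
        thsd = stats.tukey_hsd(*samples)
        for i in range(k):
            for j in range(i + 1, k):
                pp = thsd.pvalue[i, j]
                pw.iloc[i, j] = pw.iloc[j, i] = pp
                if pp < alpha:
                    sig.add(tuple(sorted((names[i], names[j]))))
    letters = compact_letters(names, sig)
    return AnovaTukeyResult(
        factor=factor,
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=n_tot - k,
        p_value=float(p_val),
        pairwise_p=pw,
        letters=letters,
        excluded_groups=excluded,
    )


# ---------------------------------------------------------------------------
# PCA on the correlation matrix

def pca(table: TraitTable, traits: list[str] | None = None):
    """PCA of standardized traits (complete cases).

    Returns (loadings, scores, variance_fractions); loadings columns are
    orthonormal eigenvectors of the trait correlation matrix, ordered by
    decreasing eigenvalue with a deterministic sign convention.
    """
    cols = traits or table.traits
    X = table.data[cols].dropna()
    constant = [c for c in cols if X[c].std(ddof=1) == 0]
    if constant:
        warnings.warn(f"constant traits dropped from PCA: {constant}", stacklevel=2)
        cols = [c for c in cols if c not in constant]
        X = X[cols]
    if X.shape[0] < len(cols) + 1:
        raise ValueError(f"need >= {len(cols) + 1} complete cases, have {X.shape[0]}")
    Z = (X - X.mean()) / X.std(ddof=1)
    C = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(C)
    idx = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[idx], eigvec[:, idx]
    # sign convention: largest-magnitude loading positive
    for j in range(eigvec.shape[1]):
        m = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[m, j] < 0:
            eigvec[:, j] *= -1
    names = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=cols, columns=names)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=X.index, columns=names)
    frac = pd.Series(np.clip(eigval, 0, None) / eigval.sum(), index=names)
    return loadings, scores, frac


# ---------------------------------------------------------------------------
# OLS helpers, VIF and AICc model selection

def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares with intercept; returns (beta, rss, se, df_resid)."""
    n = len(y)
    A = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    rss = float(resid @ resid)
    df_resid = n - A.shape[1]
    if df_resid > 0 and rank == A.shape[1]:
        sigma2 = rss / df_resid
        cov = sigma2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
    else:
        se = np.full(A.shape[1], np.nan)
    return beta, rss, se, df_resid


def vif(table: TraitTable, predictors: list[str], threshold: float = 5.0):
    """Variance inflation factors; returns a Series plus flags >= threshold."""
    X = table.data[predictors].dropna()
    if X.shape[0] < len(predictors) + 2:
        raise ValueError("insufficient complete cases for VIF")
    out = {}
    for j, name in enumerate(predictors):
        others = [c for c in predictors if c != name]
        if not others:
            out[name] = 1.0
            continue
        y = X[name].to_numpy(dtype=float)
        _, rss, _, _ = _ols(X[others].to_numpy(dtype=float), y)
        tss = float(np.sum((y - y.mean()) ** 2))
        if tss == 0:
            out[name] = np.nan
            continue
        r2 = 1 - rss / tss
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out, name="VIF")
    s.attrs["flagged"] = [k for k, v in out.items() if not np.isfinite(v) or v >= threshold]
    return s


@dataclass
class ModelSelectionResult:
    response: str
    candidates: list[str]
    models: pd.DataFrame  # one row per submodel
    selected: pd.DataFrame  # rows with delta < threshold
    averaged_coef: pd.Series
    averaged_se: pd.Series
    importance: pd.Series  # renormalized weight mass within the selected set
    importance_all: pd.Series  # Akaike-weight sum over ALL candidate models
    p_values: pd.Series
    delta_threshold: float
    n: int


def aicc_model_selection(
    table: TraitTable,
    response: str,
    candidates: list[str],
    delta_threshold: float = 2.0,
    standardize: bool = True,
) -> ModelSelectionResult:
    """Exhaustive OLS submodel enumeration ranked by AICc.

    All ``2^p`` submodels (including intercept-only) are fitted on
    complete cases.  ``logLik = -n/2 [ln(2 pi) + ln(RSS/n) + 1]``;
    ``k`` counts slopes + intercept + residual variance.  Akaike weights
    are computed over all submodels; models with ``dAICc < threshold``
    form the selected set.  Averaged coefficients use zero-substitution
    over the selected set with renormalized weights; importance of a
    variable is the renormalized weight mass of selected models
    containing it.
    """
    cols = [response] + list(candidates)
    D = table.data[cols].dropna()
    n = len(D)
    if n < len(candidates) + 2:
        raise ValueError("insufficient complete cases")
    if standardize:
        D = (D - D.mean()) / D.std(ddof=1)
    y = D[response].to_numpy(dtype=float)

    rows = []
    coef_store: list[dict[str, tuple[float, float]]] = []
    for subset in itertools.chain.from_iterable(
        itertools.combinations(candidates, r) for r in range(len(candidates) + 1)
    ):
        X = D[list(subset)].to_numpy(dtype=float)
        k = len(subset) + 2  # slopes + intercept + variance
        if n - k - 1 <= 0:
            warnings.warn(f"model {subset} dropped: n - k - 1 <= 0", stacklevel=2)
            continue
        beta, rss, se, _ = _ols(X, y)
        loglik = -n / 2.0 * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
        aicc = -2 * loglik + 2 * k + 2.0 * k * (k + 1) / (n - k - 1)
        rows.append(
            {
                "predictors": subset,
                "k": k,
                "logLik": loglik,
                "AICc": aicc,
                "intercept": beta[0],
                **{v: beta[1 + i] for i, v in enumerate(subset)},
            }
        )
        coef_store.append({v: (beta[1 + i], se[1 + i]) for i, v in enumerate(subset)})
    models = pd.DataFrame(rows)
    models["delta"] = models["AICc"] - models["AICc"].min()
    rel = np.exp(-models["delta"] / 2.0)
    models["weight"] = rel / rel.sum()
    order = np.argsort(models["AICc"].to_numpy(), kind="stable")
    models = models.iloc[order].reset_index(drop=True)
    coef_store = [coef_store[i] for i in order]

    sel_mask = models["delta"] < delta_threshold
    selected = models[sel_mask].copy()
    w = selected["weight"].to_numpy()
    w_norm = w / w.sum()

    avg_coef, avg_se, importance, importance_all, pvals = {}, {}, {}, {}, {}
    sel_coefs = [coef_store[i] for i in np.where(sel_mask.to_numpy())[0]]
    all_w = models["weight"].to_numpy()
    for v in candidates:
        importance_all[v] = float(
            np.sum(all_w[[v in preds for preds in models["predictors"]]])
        )
    for v in candidates:
        betas = np.array([c.get(v, (0.0, 0.0))[0] for c in sel_coefs])
        ses = np.array([c.get(v, (0.0, 0.0))[1] for c in sel_coefs])
        b_avg = float(np.sum(w_norm * betas))
        # full-average (zero-substitution) unconditional SE
        se_avg = float(np.sum(w_norm * np.sqrt(ses**2 + (betas - b_avg) ** 2)))
        imp = float(np.sum(w_norm[[v in c for c in sel_coefs]]))
        avg_coef[v] = b_avg
        avg_se[v] = se_avg
        importance[v] = imp
        if se_avg > 0:
            pvals[v] = float(2 * stats.norm.sf(abs(b_avg) / se_avg))
        else:
            pvals[v] = np.nan if b_avg == 0 else 0.0
    return ModelSelectionResult(
        response=response,
        candidates=list(candidates),
        models=models,
        selected=selected,
        averaged_coef=pd.Series(avg_coef),
        averaged_se=pd.Series(avg_se),
        importance=pd.Series(importance),
        importance_all=pd.Series(importance_all),
        p_values=pd.Series(pvals),
        delta_threshold=delta_threshold,
        n=n,
    )
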