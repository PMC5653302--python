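"""Variable selection and variance partitioning of richness drivers.

Richness is regressed on standardized predictors organised in ecological
groups (soil, land use, climate, geomorphology, space).  Explained variance
is measured by Ezekiel's adjusted R²; unique and shared fractions across
groups come from inclusion–exclusion over all subset regressions (with a
univariate response, redundancy analysis reduces exactly to multiple linear
regression).  Marginal (unique) effects are tested by Freedman–Lane
permutation of reduced-model residuals.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "standardize",
    "adjusted_r2",
    "SelectionResult",
    "select_variables",
    "forward_select",
    "select_spatial",
    "PartitionResult",
    "variance_partition",
    "significance_stars",
]


def standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every column to mean 0, sd 1 (ddof 1)."""
    sd = X.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant column(s): {list(sd.index[sd == 0])}")
    return (X - X.mean()) / sd


def _r2(X: np.ndarray, y: np.ndarray) -> float:
    """R² of OLS with intercept; robust to rank deficiency (lstsq)."""
    n = len(y)
    Xc = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        return 0.0
    return 1.0 - float(resid @ resid) / tss


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel's correction: 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _ols_bic_r2adj(X: np.ndarray, y: np.ndarray):
    """(BIC, R²adj, R²) under the Gaussian form n ln(RSS/n) + k ln(n),
    k counting intercept, slopes and the error variance."""
    n = len(y)
    p = X.shape[1] if X.ndim == 2 else 0
    r2 = _r2(X, y)
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = max((1.0 - r2) * tss, 1e-300)
    k = p + 2
    bic = n * math.log(rss / n) + k * math.log(n)
    return bic, adjusted_r2(r2, n, p), r2


# ---------------------------------------------------------------------------
# Two-step environmental variable selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    selected: list
    best_bic_subset: list
    best_r2adj_subset: list
    subset_table: pd.DataFrame        # best model per size, both criteria
    forward_trace: pd.DataFrame


def _enumerate_subsets(X: pd.DataFrame, y: np.ndarray, max_size: int | None):
    """Best subset per size by BIC and by R²adj via exhaustive enumeration
    with Gram-matrix solves (p <= 20)."""
    cols = list(X.columns)
    p = len(cols)
    if p > 20:
        raise ValueError("exhaustive enumeration limited to p <= 20 predictors")
    max_size = max_size or p
    Xn = X.to_numpy()
    n = len(y)
    ones = np.ones((n, 1))
    Z = np.hstack([ones, Xn])
    G = Z.T @ Z
    gy = Z.T @ y
    yy = float(y @ y)
    tss = float(np.sum((y - y.mean()) ** 2))

    rows = []
    best_per_size: dict[int, dict] = {}
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(range(p), size):
            idx = np.r_[0, np.array(combo) + 1]
            Gs = G[np.ix_(idx, idx)]
            try:
                beta = np.linalg.solve(Gs, gy[idx])
            except np.linalg.LinAlgError:
                continue
            rss = max(yy - float(beta @ gy[idx]), 1e-300)
            r2 = 1.0 - rss / tss
            k = size + 2
            bic = n * math.log(rss / n) + k * math.log(n)
            r2a = adjusted_r2(r2, n, size)
            rec = {"size": size, "subset": combo, "bic": bic, "r2adj": r2a, "r2": r2}
            cur = best_per_size.get(size)
            if cur is None:
                best_per_size[size] = {"bic": rec, "r2adj": rec}
            else:
                if bic < cur["bic"]["bic"]:
                    cur["bic"] = rec
                if r2a > cur["r2adj"]["r2adj"]:
                    cur["r2adj"] = rec
    for size, d in sorted(best_per_size.items()):
        for crit in ("bic", "r2adj"):
            r = d[crit]
            rows.append(
                {
                    "size": size,
                    "criterion": crit,
                    "variables": tuple(cols[i] for i in r["subset"]),
                    "bic": r["bic"],
                    "r2adj": r["r2adj"],
                    "r2": r["r2"],
                }
            )
    table = pd.DataFrame(rows)
    return table, cols


def select_variables(
    X: pd.DataFrame,
    y,
    alpha: float = 0.05,
    max_size: int | None = None,
) -> SelectionResult:
    """Two-step predictor selection.

    Step 1 (coarse): exhaustive best-subset enumeration scored by BIC and
    adjusted R²; the retained pool is the union of the global best-BIC and
    best-R²adj subsets.  Step 2: forward selection over the pool maximizing
    adjusted R², with the double stopping rule — stop when the best
    candidate's marginal p-value exceeds ``alpha`` or the running adjusted
    R² would exceed that of the full pool model.
    """
    y = np.asarray(y, dtype=float)
    table, cols = _enumerate_subsets(X, y, max_size)
    bic_best = table.loc[table["bic"].idxmin(), "variables"]
    r2_best = table.loc[table["r2adj"].idxmax(), "variables"]
    pool = [c for c in cols if c in set(bic_best) | set(r2_best)]
    if not pool:
        logger.warning("no candidate improves over the intercept-only model")
        return SelectionResult([], list(bic_best), list(r2_best), table,
                               pd.DataFrame())
    _, r2adj_full, _ = _ols_bic_r2adj(X[pool].to_numpy(), y)
    selected, trace = forward_select(X[pool], y, alpha=alpha,
                                     r2adj_cap=r2adj_full)
    return SelectionResult(
        selected=selected,
        best_bic_subset=list(bic_best),
        best_r2adj_subset=list(r2_best),
        subset_table=table,
        forward_trace=trace,
    )


def forward_select(
    X: pd.DataFrame,
    y,
    alpha: float = 0.05,
    r2adj_cap: float | None = None,
) -> tuple[list, pd.DataFrame]:
    """Forward selection maximizing adjusted R² with the double stopping
    rule (candidate p-value > alpha, or adjusted R² above ``r2adj_cap``)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    remaining = list(X.columns)
    selected: list = []
    rows = []
    current_r2 = 0.0
    while remaining:
        best = None
        for c in remaining:
            cand = selected + [c]
            r2 = _r2(X[cand].to_numpy(), y)
            if best is None or r2 > best[1]:
                best = (c, r2)
        c, r2 = best
        p_sel = len(selected)
        # marginal partial F test of the added variable
        df2 = n - p_sel - 2
        if df2 <= 0:
            break
        f = (r2 - current_r2) / max(1.0 - r2, 1e-300) * df2
        pval = float(stats.f.sf(f, 1, df2))
        r2a = adjusted_r2(r2, n, p_sel + 1)
        if pval > alpha:
            break
        if r2adj_cap is not None and r2a > r2adj_cap + 1e-12:
            break
        selected.append(c)
        remaining.remove(c)
        rows.append({"variable": c, "r2": r2, "r2adj": r2a, "p_value": pval})
        current_r2 = r2
    if not selected:
        logger.warning("forward selection retained no variables")
    return selected, pd.DataFrame(rows)


def select_spatial(
    residuals,
    basis,
    alpha: float = 0.05,
) -> tuple[list, pd.DataFrame]:
    """Forward-select PCNM descriptors on environmental-model residuals.

    Descriptors are orthonormal, so each one's contribution equals its
    squared correlation with the residuals; this identity is verified
    internally (1e-8) as a guard on the basis.
    """
    from .pcnm import SpatialBasis

    vectors = basis.selected_vectors() if isinstance(basis, SpatialBasis) else basis
    residuals = np.asarray(residuals, dtype=float)
    selected, trace = forward_select(vectors, residuals, alpha=alpha)
    if len(trace):
        r = residuals - residuals.mean()
        contrib = np.diff(np.r_[0.0, trace["r2"].to_numpy()])
        for var, c in zip(trace["variable"], contrib):
            v = vectors[var].to_numpy()
            corr2 = float(np.corrcoef(v, r)[0, 1] ** 2)
            if abs(corr2 - c) > 1e-8:
                logger.warning(
                    "descriptor %s: contribution %.3e != squared correlation %.3e "
                    "(basis not orthogonal to residual path?)", var, c, corr2,
                )
    return selected, trace


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class PartitionResult:
    """Adjusted-R² decomposition across predictor groups.

    ``fractions`` maps each nonempty frozenset of group names to its
    exclusive (unique or shared) adjusted-R² fraction; slightly negative
    values are an adjusted-R² artifact and are reported unclipped.
    """

    fractions: dict
    total: float
    residual: float
    group_pvalues: dict
    variable_table: pd.DataFrame
    n_perm: int

    @property
    def unique(self) -> dict:
        return {next(iter(s)): v for s, v in self.fractions.items() if len(s) == 1}

    @property
    def shared_total(self) -> float:
        """Sum of all shared fractions, reported as the 'interactions' part."""
        return float(sum(v for s, v in self.fractions.items() if len(s) > 1))

    def to_dict(self) -> dict:
        return {
            "unique": self.unique,
            "shared": {"+".join(sorted(s)): v for s, v in self.fractions.items()
                       if len(s) > 1},
            "interactions": self.shared_total,
            "total": self.total,
            "residual": self.residual,
            "group_p_values": self.group_pvalues,
        }


def variance_partition(
    y,
    groups: dict[str, pd.DataFrame],
    n_perm: int = 1000,
    seed: int | None = 0,
    permute_variables: bool = False,
    pool_sizes: dict[str, int] | None = None,
) -> PartitionResult:
    """Partition the variance of ``y`` among named predictor groups.

    For every nonempty union of groups the adjusted R² is computed; unique
    and shared fractions follow by inclusion–exclusion (Möbius inversion of
    ``h(T) = R²adj(all) − R²adj(all \\ T)``).  The marginal (unique)
    significance of each group is assessed by Freedman–Lane permutation:
    residuals of the reduced model (without the tested group) are permuted
    ``n_perm`` times and the semi-partial R² recomputed.  The variable
    table reports, per predictor, its unique explained variance within the
    full model and its standardized coefficient (permutation p-values per
    variable when ``permute_variables``).

    ``pool_sizes`` counters forward-selection bias: when a group's columns
    were selected from a larger candidate pool (PCNM descriptors,
    typically), passing the pool size makes Ezekiel's correction charge
    the full pool rather than the selected subset.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    gnames = list(groups)
    for g, df in groups.items():
        if len(df) != n:
            raise ValueError(f"group {g!r} row count differs from y")
    pool_sizes = pool_sizes or {}

    def effective_p(subset) -> int:
        return sum(
            max(pool_sizes.get(g, 0), np.asarray(groups[g]).shape[1])
            for g in subset
        )

    def design(subset) -> np.ndarray:
        if not subset:
            return np.empty((n, 0))
        return np.hstack([np.asarray(groups[g], dtype=float) for g in subset])

    def r2adj_of(subset) -> float:
        X = design(subset)
        if X.shape[1] == 0:
            return 0.0
        return adjusted_r2(_r2(X, y), n, effective_p(subset))

    f = {frozenset(s): r2adj_of(s)
         for r in range(len(gnames) + 1)
         for s in itertools.combinations(gnames, r)}
    allg = frozenset(gnames)
    total = f[allg]

    def h(T: frozenset) -> float:
        return total - f[allg - T]

    fractions: dict[frozenset, float] = {}
    for r in range(1, len(gnames) + 1):
        for s in itertools.combinations(gnames, r):
            S = frozenset(s)
            val = 0.0
            for r2_ in range(1, len(s) + 1):
                for t in itertools.combinations(s, r2_):
                    val += (-1) ** (len(S) - len(t)) * h(frozenset(t))
            fractions[S] = val

    # Freedman–Lane permutation of the reduced model per group
    rng = np.random.default_rng(seed)
    pvals = {}
    for g in gnames:
        reduced = [x for x in gnames if x != g]
        Xr = design(reduced)
        Xf = design(gnames)
        r2_full = _r2(Xf, y)
        r2_red = _r2(Xr, y)
        stat_obs = r2_full - r2_red
        # reduced-model fit
        Xr1 = np.column_stack([np.ones(n), Xr])
        beta, *_ = np.linalg.lstsq(Xr1, y, rcond=None)
        fitted = Xr1 @ beta
        resid = y - fitted
        geq = 1
        for _ in range(n_perm):
            ystar = fitted + rng.permutation(resid)
            geq += (_r2(Xf, ystar) - _r2(Xr, ystar)) >= stat_obs
        pvals[g] = geq / (n_perm + 1.0)

    # per-variable marginal fractions and standardized coefficients
    Xall = pd.concat(
        [pd.DataFrame(np.asarray(groups[g], dtype=float),
                      columns=[f"{c}" for c in getattr(groups[g], "columns",
                                                       range(np.asarray(groups[g]).shape[1]))])
         for g in gnames],
        axis=1,
    )
    var_group = {c: g for g in gnames for c in getattr(groups[g], "columns",
                                                       range(np.asarray(groups[g]).shape[1]))}
    cols = list(Xall.columns)
    Xn = Xall.to_numpy()
    r2adj_all = adjusted_r2(_r2(Xn, y), n, Xn.shape[1])
    ysd = y.std(ddof=1)
    Z1 = np.column_stack([np.ones(n), Xn])
    beta_all, *_ = np.linalg.lstsq(Z1, y, rcond=None)
    rows = []
    for j, c in enumerate(cols):
        keep = [i for i in range(len(cols)) if i != j]
        r2adj_wo = adjusted_r2(_r2(Xn[:, keep], y), n, len(keep))
        std_coef = beta_all[j + 1] * Xall[c].std(ddof=1) / ysd if ysd > 0 else 0.0
        row = {
            "variable": c,
            "group": var_group[c],
            "unique_variance": r2adj_all - r2adj_wo,
            "std_coefficient": std_coef,
        }
        if permute_variables:
            stat_obs = _r2(Xn, y) - _r2(Xn[:, keep], y)
            Xr1 = np.column_stack([np.ones(n), Xn[:, keep]])
            b, *_ = np.linalg.lstsq(Xr1, y, rcond=None)
            fitted = Xr1 @ b
            resid = y - fitted
            geq = 1
            for _ in range(n_perm):
                ystar = fitted + rng.permutation(resid)
                geq += (_r2(Xn, ystar) - _r2(Xn[:, keep], ystar)) >= stat_obs
            row["p_value"] = geq / (n_perm + 1.0)
            row["stars"] = significance_stars(row["p_value"])
        rows.append(row)
    vtab = pd.DataFrame(rows)

    return PartitionResult(
        fractions=fractions,
        total=total,
        residual=1.0 - total,
        group_pvalues=pvals,
        variable_table=vtab,
        n_perm=n_perm,
    )
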