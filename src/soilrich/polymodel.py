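"""Polynomial predictive model of soil bacterial richness.

Covers the full predictive-modelling chain: collinearity screening
(pairwise correlation and variance inflation factors), representative
calibration/validation splitting with the Kennard–Stone algorithm,
exhaustive best-subset search scored by BIC and adjusted R², ordinary
least-squares fitting of polynomial term designs with normality
(Shapiro–Wilk) and homoskedasticity (Breusch–Pagan) diagnostics, global
sensitivity through standardized regression coefficients (SRC =
(sigma_X / sigma_Y) * beta), and prediction with training-envelope flags.

The bundled reference model carries the published functional form of the
national richness model — {1, pH^4, clay^2, clay^2*C:N, clay^3*C:N,
(C:N)^2 * x} — with coefficients flagged provisional: the printed constants
are internally inconsistent and are shipped for structural use only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .terms import parse_term, term_to_string, evaluate_term

logger = logging.getLogger(__name__)

__all__ = [
    "CollinearityReport",
    "collinearity_filter",
    "SplitSpec",
    "kennard_stone_split",
    "random_split",
    "search_models",
    "PolynomialModel",
    "fit_polynomial",
    "polynomial_degree_ladder",
    "src_sensitivity",
    "REFERENCE_RICHNESS_MODEL_TERMS",
    "reference_richness_model",
    "predict_richness",
]

#: BIC convention used throughout: n*ln(RSS/n) + k*ln(n) with k counting the
#: intercept, the slopes and the error variance.
BIC_CONVENTION = "n*ln(RSS/n) + k*ln(n), k = n_coefficients + 1 (error variance)"


# ---------------------------------------------------------------------------
# Collinearity filtering
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    correlation: pd.DataFrame
    vif: pd.Series                  # VIFs of the kept set
    kept: list
    dropped: list                   # (variable, reason) in drop order


def _vifs(X: pd.DataFrame) -> pd.Series:
    out = {}
    Xn = X.to_numpy()
    n = len(X)
    for j, c in enumerate(X.columns):
        others = np.delete(Xn, j, axis=1)
        Z = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(Z, Xn[:, j], rcond=None)
        resid = Xn[:, j] - Z @ beta
        tss = float(np.sum((Xn[:, j] - Xn[:, j].mean()) ** 2))
        r2 = 0.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def collinearity_filter(
    X: pd.DataFrame,
    r_max: float = 0.7,
    vif_max: float = 4.0,
) -> tuple[CollinearityReport, pd.DataFrame]:
    """Screen predictors for collinearity.

    First iteratively drops the variable with the highest VIF until all
    VIF <= ``vif_max`` (ties: first in column order); then resolves
    remaining ``|r| > r_max`` pairs by dropping the member with the larger
    mean absolute correlation.  Deterministic; raises if the cascade would
    drop everything.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if len(X) <= X.shape[1]:
        raise ValueError("need n > p observations")
    work = X.copy()
    dropped: list[tuple[str, str]] = []
    while work.shape[1] >= 2:
        v = _vifs(work)
        if v.max() <= vif_max:
            break
        worst = v.index[int(np.argmax(v.to_numpy()))]
        dropped.append((worst, f"VIF {v[worst]:.3g} > {vif_max}"))
        work = work.drop(columns=[worst])
    while work.shape[1] >= 2:
        corr = work.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.to_numpy().max() <= r_max:
            break
        i, j = np.unravel_index(int(np.argmax(corr.to_numpy())), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a, mean_b = corr[a].mean(), corr[b].mean()
        worst = a if mean_a >= mean_b else b
        dropped.append((worst, f"|r| {corr.iloc[i, j]:.3g} > {r_max}"))
        work = work.drop(columns=[worst])
    if work.shape[1] == 0:
        raise ValueError(f"all variables dropped; cascade: {dropped}")
    report = CollinearityReport(
        correlation=X.corr(),
        vif=_vifs(work) if work.shape[1] >= 2 else pd.Series({work.columns[0]: 1.0}),
        kept=list(work.columns),
        dropped=dropped,
    )
    return report, work


# ---------------------------------------------------------------------------
# Kennard–Stone splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    modeling: np.ndarray
    validation: np.ndarray
    fraction: float
    algorithm: str = "kennard_stone"


def kennard_stone_split(X, fraction: float = 0.9) -> SplitSpec:
    """Kennard–Stone max–min selection of a representative modeling subset.

    Distances are Euclidean on standardized columns.  The two mutually
    farthest points seed the set; each step adds the point maximizing its
    minimum distance to the selected set, until ``round(fraction * n)``
    points are chosen.  Ties break to the lowest index.
    """
    X = pd.DataFrame(X)
    n = len(X)
    if n < 2:
        raise ValueError("need at least 2 points")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    n_select = int(round(fraction * n))
    n_select = min(max(n_select, 1), n)
    sd = X.std(ddof=1).replace(0.0, 1.0)
    Z = ((X - X.mean()) / sd).to_numpy()
    D = cdist(Z, Z)
    # seed: the two mutually farthest points (lowest-index pair on ties)
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    selected = [min(i, j), max(i, j)] if n_select >= 2 else [min(i, j)]
    mind = D[:, selected].min(axis=1)
    mind[selected] = -1.0
    while len(selected) < n_select:
        nxt = int(np.argmax(mind))        # argmax returns the lowest index on ties
        selected.append(nxt)
        mind = np.minimum(mind, D[:, nxt])
        mind[nxt] = -1.0
    model_idx = np.array(sorted(selected))
    val_idx = np.setdiff1d(np.arange(n), model_idx)
    return SplitSpec(modeling=model_idx, validation=val_idx, fraction=fraction)


def random_split(n: int, fraction: float = 0.9, seed=None) -> SplitSpec:
    """Purely random split of the same shape, for comparison."""
    rng = np.random.default_rng(seed)
    n_select = int(round(fraction * n))
    model_idx = np.sort(rng.choice(n, size=n_select, replace=False))
    return SplitSpec(
        modeling=model_idx,
        validation=np.setdiff1d(np.arange(n), model_idx),
        fraction=fraction,
        algorithm="random",
    )


# ---------------------------------------------------------------------------
# Exhaustive subset search
# ---------------------------------------------------------------------------

def search_models(X: pd.DataFrame, y, max_size: int | None = None):
    """Exhaustive best-subset search scored by BIC and adjusted R².

    Returns ``(table, best)`` where ``table`` holds the best model per size
    under each criterion (with a membership matrix over variables) and
    ``best`` maps criterion -> variable tuple of the global winner.
    """
    from .varpart import _enumerate_subsets

    y = np.asarray(y, dtype=float)
    table, cols = _enumerate_subsets(X, y, max_size)
    for c in cols:
        table[f"in:{c}"] = table["variables"].map(lambda v, c=c: c in v)
    best = {
        "bic": tuple(table.loc[table["bic"].idxmin(), "variables"]),
        "r2adj": tuple(table.loc[table["r2adj"].idxmax(), "variables"]),
    }
    return table, best


# ---------------------------------------------------------------------------
# Polynomial fitting
# ---------------------------------------------------------------------------

@dataclass
class PolynomialModel:
    """Fitted polynomial regression with diagnostics and sensitivity."""

    terms: list                      # canonical term strings, "1" first
    coefficients: np.ndarray
    std_errors: np.ndarray
    r2: float
    r2adj: float
    bic: float
    bic_convention: str
    shapiro_p: float
    sigma_y: float
    sigma_terms: np.ndarray
    breusch_pagan_p: float
    n_obs: int
    training_ranges: dict = field(default_factory=dict)
    dropped_terms: list = field(default_factory=list)
    provisional: bool = False

    def design(self, data) -> np.ndarray:
        return np.column_stack([evaluate_term(t, data) for t in self.terms])

    def predict(self, data, with_flags: bool = False):
        """Exact term-wise evaluation; optionally flag covariates outside
        the training envelope (prediction proceeds regardless)."""
        M = self.design(data)
        if not np.all(np.isfinite(M)):
            raise ValueError("non-finite input")
        pred = M @ self.coefficients
        if not with_flags:
            return pred
        flags = np.zeros(len(pred), dtype=bool)
        for var, (lo, hi) in self.training_ranges.items():
            if var in data:
                v = np.asarray(data[var], dtype=float)
                flags |= (v < lo) | (v > hi)
        return pred, flags

    @property
    def src(self) -> pd.DataFrame:
        """Standardized regression coefficients, |SRC| descending."""
        vals = []
        for t, b, s in zip(self.terms, self.coefficients, self.sigma_terms):
            if t == "1":
                continue
            src = 0.0 if (s == 0 or self.sigma_y == 0) else s / self.sigma_y * b
            vals.append({"term": t, "src": src, "coefficient": b,
                         "zero_variance": s == 0})
        out = pd.DataFrame(vals)
        return out.reindex(out["src"].abs().sort_values(ascending=False).index)

    def to_dict(self) -> dict:
        return {
            "terms": self.terms,
            "coefficients": list(map(float, self.coefficients)),
            "std_errors": list(map(float, self.std_errors)),
            "r2": self.r2,
            "r2adj": self.r2adj,
            "bic": self.bic,
            "bic_convention": self.bic_convention,
            "shapiro_p": self.shapiro_p,
            "breusch_pagan_p": self.breusch_pagan_p,
            "n_obs": self.n_obs,
            "provisional": self.provisional,
            "src": self.src.to_dict("records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_polynomial(
    data,
    y,
    terms,
    max_degree: int = 5,
) -> PolynomialModel:
    """Ordinary least squares on an explicit polynomial term design.

    ``terms`` is a list of term strings (``"pH^4"``, ``"clay^2*CN_ratio"``);
    an intercept is always included.  Aliased (rank-deficient) terms are
    dropped with a warning.  Residual diagnostics: Shapiro–Wilk normality
    and Breusch–Pagan homoskedasticity.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    y = np.asarray(y, dtype=float)
    n = len(y)
    canon = ["1"] + [
        term_to_string(parse_term(t)) for t in terms
        if term_to_string(parse_term(t)) != "1"
    ]
    for t in canon[1:]:
        deg = sum(p for _, p in parse_term(t))
        if deg > max_degree:
            raise ValueError(f"term {t!r} exceeds max degree {max_degree}")
    M = np.column_stack([evaluate_term(t, data) for t in canon])

    # greedy alias removal keeps the earliest independent terms
    keep, dropped = [0], []
    for j in range(1, M.shape[1]):
        trial = keep + [j]
        if np.linalg.matrix_rank(M[:, trial]) == len(trial):
            keep.append(j)
        else:
            dropped.append(canon[j])
    if dropped:
        logger.warning("dropping aliased term(s): %s", dropped)
    canon = [canon[j] for j in keep]
    M = M[:, keep]

    res = sm.OLS(y, M).fit()
    rss = max(float(res.ssr), 1e-300)
    k = M.shape[1] + 1
    bic = n * math.log(rss / n) + k * math.log(n)
    resid = np.asarray(res.resid)
    shapiro_p = float(stats.shapiro(resid).pvalue) if 3 <= n <= 5000 else float(
        stats.normaltest(resid).pvalue
    )
    try:
        bp_p = float(het_breuschpagan(resid, M)[1])
    except (ValueError, np.linalg.LinAlgError):
        bp_p = float("nan")
    variables = sorted({v for t in canon for v, _ in parse_term(t)})
    ranges = {}
    for v in variables:
        col = np.asarray(data[v], dtype=float)
        ranges[v] = (float(col.min()), float(col.max()))
    return PolynomialModel(
        terms=canon,
        coefficients=np.asarray(res.params),
        std_errors=np.asarray(res.bse),
        r2=float(res.rsquared),
        r2adj=float(res.rsquared_adj),
        bic=bic,
        bic_convention=BIC_CONVENTION,
        shapiro_p=shapiro_p,
        breusch_pagan_p=bp_p,
        sigma_y=float(np.std(y, ddof=1)),
        sigma_terms=np.std(M, axis=0, ddof=1),
        n_obs=n,
        training_ranges=ranges,
        dropped_terms=dropped,
    )


def polynomial_degree_ladder(
    data,
    y,
    variable: str = "pH",
    degrees=range(1, 6),
) -> pd.DataFrame:
    """Single-variable polynomial fits of increasing degree.

    Returns one row per degree with R², adjusted R² and BIC — the classic
    complexity ladder used to pick the pH-only model degree.
    """
    rows = []
    for d in degrees:
        terms = [f"{variable}^{k}" if k > 1 else variable for k in range(1, d + 1)]
        m = fit_polynomial(data, y, terms, max_degree=max(degrees))
        rows.append({"degree": d, "r2": m.r2, "r2adj": m.r2adj, "bic": m.bic})
    return pd.DataFrame(rows)


def src_sensitivity(model: PolynomialModel, data=None) -> pd.DataFrame:
    """Per-term standardized regression coefficients (|SRC| descending).

    With ``data`` given, the term standard deviations are recomputed on that
    dataset; otherwise the stored training sigmas are used.
    """
    if data is None:
        return model.src
    rows = []
    y_sd = model.sigma_y
    for t, b in zip(model.terms, model.coefficients):
        if t == "1":
            continue
        s = float(np.std(evaluate_term(t, data), ddof=1))
        src = 0.0 if (s == 0 or y_sd == 0) else s / y_sd * b
        rows.append({"term": t, "src": src, "coefficient": b, "zero_variance": s == 0})
    out = pd.DataFrame(rows)
    return out.reindex(out["src"].abs().sort_values(ascending=False).index)


# ---------------------------------------------------------------------------
# Reference model
# ---------------------------------------------------------------------------

#: Functional form of the published national richness model.
REFERENCE_RICHNESS_MODEL_TERMS = (
    "1", "pH^4", "clay^2", "clay^2*CN_ratio", "clay^3*CN_ratio", "CN_ratio^2*x_km",
)

#: Published coefficients in term order.  PROVISIONAL: the printed equation
#: carries an orphan additive constant (folded into the intercept here) and
#: does not evaluate to richness in the observed range at typical national
#: covariate values; ship the functional form, trust the numbers only as
#: structure.
_REFERENCE_COEFFICIENTS = np.array(
    [1044.0 + 0.0597, 3.305, -0.0457, 0.00298, -1.54e-6, 2.336e-5]
)


def reference_richness_model() -> PolynomialModel:
    """The bundled reference model (functional form; provisional numbers)."""
    from .synthetic import DEFAULT_COVARIATES, DEFAULT_DOMAIN

    ranges = {
        "pH": (DEFAULT_COVARIATES["pH"].min, DEFAULT_COVARIATES["pH"].max),
        "clay": (DEFAULT_COVARIATES["clay"].min, DEFAULT_COVARIATES["clay"].max),
        "CN_ratio": (DEFAULT_COVARIATES["CN_ratio"].min,
                     DEFAULT_COVARIATES["CN_ratio"].max),
        "x_km": (DEFAULT_DOMAIN[0], DEFAULT_DOMAIN[1]),
    }
    k = len(REFERENCE_RICHNESS_MODEL_TERMS)
    return PolynomialModel(
        terms=list(REFERENCE_RICHNESS_MODEL_TERMS),
        coefficients=_REFERENCE_COEFFICIENTS.copy(),
        std_errors=np.full(k, np.nan),
        r2=float("nan"),
        r2adj=float("nan"),
        bic=float("nan"),
        bic_convention=BIC_CONVENTION,
        shapiro_p=float("nan"),
        breusch_pagan_p=float("nan"),
        sigma_y=float("nan"),
        sigma_terms=np.full(k, np.nan),
        n_obs=0,
        training_ranges=ranges,
        provisional=True,
    )


def predict_richness(model_or_reference, covariates, with_flags: bool = True):
    """Predict richness from covariates with out-of-envelope flags.

    ``model_or_reference`` is a fitted :class:`PolynomialModel` or the
    string ``"reference"`` for the bundled reference form.  Inputs outside
    the training (or national summary) ranges are flagged, never refused.
    """
    model = (
        reference_richness_model()
        if isinstance(model_or_reference, str) and model_or_reference == "reference"
        else model_or_reference
    )
    return model.predict(covariates, with_flags=with_flags)
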