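"""Partial least squares regression core for field-based QSAR.

The estimator follows the classical chemometrics workflow used with
lattice descriptors:

1. *Column filtering* ("minimum sigma"): lattice columns whose standard
   deviation across compounds falls below a threshold (default
   2.0 kcal/mol) carry little information and are dropped before
   regression.
2. *Block scaling* (CoMFA-STD): surviving columns are mean-centred and
   each field block is scaled so every field contributes equal total
   variance, preventing fields with larger numeric ranges from dominating
   the latent variables.  The response is centred only.
3. *NIPALS PLS*: latent variables are extracted iteratively with
   deflation; regression coefficients are back-transformed to original
   descriptor units so that predictions and contour maps live in response
   units.

Model selection uses leave-one-out or leave-group-out cross-validation:
q^2 = 1 - PRESS / sum((y - ybar)^2), SEP = sqrt(PRESS / (n - c - 1)), and
a parsimony rule that only accepts an extra latent variable while it
improves q^2 by more than 10% (relative).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fields import FieldBlock

__all__ = [
    "PreprocessState",
    "FitStats",
    "CVStats",
    "FieldPLS",
    "PLSFitResults",
    "preprocess",
    "nipals_fit",
    "predict",
    "cross_validate",
    "select_components",
    "fit_statistics",
    "regression_stats",
]

DEFAULT_MIN_VARIATION = 2.0  # kcal/mol, minimum column sigma


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessState:
    """Column filter, centring and block-scaling state of a fitted model."""

    mask: np.ndarray                 # (p,) bool, retained columns
    col_means: np.ndarray            # (p_kept,)
    col_scales: np.ndarray           # (p_kept,) multiplicative block-scale factor
    col_sd: np.ndarray               # (p_kept,) original-unit column sd
    y_mean: float
    field_slices: dict[str, slice] | None = None  # slices into the FULL column space

    @property
    def n_columns(self) -> int:
        return self.mask.size

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mask.size:
            raise ValueError(
                f"column count {X.shape[1]} does not match model space {self.mask.size}"
            )
        return (X[:, self.mask] - self.col_means) * self.col_scales


def _resolve(block: FieldBlock | np.ndarray, field_slices=None):
    if isinstance(block, FieldBlock):
        return block.matrix, block.field_slices()
    return np.asarray(block, dtype=float), field_slices


def preprocess(
    block: FieldBlock | np.ndarray,
    y: np.ndarray,
    min_variation: float = DEFAULT_MIN_VARIATION,
    field_slices: Mapping[str, slice] | None = None,
) -> tuple[np.ndarray, np.ndarray, PreprocessState]:
    """Filter, centre and block-scale a descriptor matrix.

    Columns with sample standard deviation below ``min_variation`` are
    dropped.  Each field block is scaled so its retained columns sum to
    unit total variance (equal-field-variance convention); with no field
    structure the whole matrix is treated as one block.  Returns the
    transformed matrix, the centred response and the reusable state.
    """
    X, slices = _resolve(block, field_slices)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to preprocess")
    if X.shape[0] != y.size:
        raise ValueError("X and y row counts differ")

    sd_full = X.std(axis=0, ddof=1)
    mask = sd_full >= min_variation
    if not mask.any():
        raise ValueError(
            f"all {X.shape[1]} columns filtered out at min sigma {min_variation}"
        )
    kept = np.flatnonzero(mask)
    Xk = X[:, kept]
    means = Xk.mean(axis=0)
    sd = sd_full[kept]

    scales = np.ones(kept.size)
    if slices:
        for sl in slices.values():
            in_field = (kept >= (sl.start or 0)) & (kept < sl.stop)
            if not in_field.any():
                continue
            total_var = float((sd[in_field] ** 2).sum())
            if total_var > 0:
                scales[in_field] = 1.0 / np.sqrt(total_var)
    else:
        total_var = float((sd**2).sum())
        if total_var > 0:
            scales[:] = 1.0 / np.sqrt(total_var)

    state = PreprocessState(
        mask=mask,
        col_means=means,
        col_scales=scales,
        col_sd=sd,
        y_mean=float(y.mean()),
        field_slices=dict(slices) if slices else None,
    )
    return (Xk - means) * scales, y - state.y_mean, state


# ---------------------------------------------------------------------------
# NIPALS
# ---------------------------------------------------------------------------

def _nipals(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """NIPALS latent-variable extraction on centred data.

    Returns (W, P, q, T, achieved) where columns of W are weights, P
    loadings, q the response loadings and T the mutually orthogonal score
    vectors.  Extraction stops early (achieved < n_components) once the
    response is fully deflated.
    """
    Xd = X.copy()
    yd = y.astype(float).copy()
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    y_scale = float(np.linalg.norm(y)) or 1.0

    achieved = 0
    for a in range(n_components):
        if np.linalg.norm(yd) < 1e-12 * y_scale:
            break  # response exhausted; nothing left to model
        u = yd
        w = Xd.T @ u
        nw = np.linalg.norm(w)
        if nw < 1e-14:
            break
        w /= nw
        t = Xd @ w
        for _ in range(max_iter):
            qa = float(t @ yd) / float(t @ t)
            u = yd * qa
            w_new = Xd.T @ u
            nw = np.linalg.norm(w_new)
            if nw < 1e-14:
                break
            w_new /= nw
            t_new = Xd @ w_new
            if np.linalg.norm(w_new - w) < tol:
                w, t = w_new, t_new
                break
            w, t = w_new, t_new
        else:
            raise RuntimeError(
                f"NIPALS failed to converge for component {a + 1} "
                f"after {max_iter} iterations at tol {tol}"
            )
        tt = float(t @ t)
        if tt < 1e-14:
            break
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t) / tt
        Xd -= np.outer(t, p_a)
        yd = yd - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        achieved = a + 1

    return (W[:, :achieved], P[:, :achieved], q[:achieved], T[:, :achieved], achieved)


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """PLS regression vector in the (centred, scaled) descriptor space."""
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitStats:
    r2: float
    see: float
    f_ratio: float
    field_contrib: dict[str, float]  # percent, sums to 100


@dataclass
class CVStats:
    q2_by_components: list[float]
    sep_by_components: list[float]
    chosen_components: int
    fold_predictions: np.ndarray  # (n, max_components)
    scheme: str
    seed: int | None = None

    @property
    def q2(self) -> float:
        return self.q2_by_components[self.chosen_components - 1]

    @property
    def sep(self) -> float:
        return self.sep_by_components[self.chosen_components - 1]


class FieldPLS:
    """PLS regression model for a compounds-by-lattice descriptor block.

    Parameters
    ----------
    y : array-like
        Response (pEC50) per compound.
    block : FieldBlock or ndarray
        Descriptor matrix; a FieldBlock carries its own field structure,
        a bare matrix may be given field structure via ``field_slices``.
    min_variation : float
        Minimum column sigma; columns below it are dropped (2.0 kcal/mol
        is the conventional energy-field default, similarity indices
        usually warrant 0).
    """

    def __init__(
        self,
        y,
        block: FieldBlock | np.ndarray,
        field_slices: Mapping[str, slice] | None = None,
        min_variation: float = DEFAULT_MIN_VARIATION,
        max_iter: int = 500,
        tol: float = 1e-12,
    ):
        self.y = np.asarray(y, dtype=float).ravel()
        self.block = block
        X, slices = _resolve(block, field_slices)
        if X.shape[0] != self.y.size:
            raise ValueError("response length does not match descriptor rows")
        self.X = X
        self.field_slices = dict(slices) if slices else None
        self.min_variation = min_variation
        self.max_iter = max_iter
        self.tol = tol

    @property
    def nobs(self) -> int:
        return self.y.size

    def fit(self, n_components: int) -> "PLSFitResults":
        if n_components < 0:
            raise ValueError("n_components must be >= 0")
        limit = min(self.nobs - 1, self.X.shape[1])
        if n_components > limit:
            raise ValueError(
                f"n_components {n_components} exceeds min(rows-1, columns) = {limit}"
            )
        Xs, yc, state = preprocess(
            self.block, self.y, self.min_variation, self.field_slices
        )
        W, P, q, T, achieved = _nipals(Xs, yc, n_components, self.max_iter, self.tol)
        b_scaled = _coefficients(W, P, q)
        # back to original descriptor units, full column space
        coef = np.zeros(state.n_columns)
        coef[state.mask] = b_scaled * state.col_scales
        intercept = state.y_mean - float(
            coef[state.mask] @ state.col_means
        )
        return PLSFitResults(
            model=self,
            state=state,
            n_components=achieved,
            requested_components=n_components,
            coefficients=coef,
            intercept=intercept,
            scores=T,
            weights=W,
            loadings=P,
            y_loadings=q,
        )

    def cross_validate(
        self,
        max_components: int = 10,
        scheme: str = "loo",
        n_groups: int = 10,
        seed: int | None = None,
    ) -> CVStats:
        return cross_validate(
            self.y,
            self.block,
            max_components=max_components,
            scheme=scheme,
            n_groups=n_groups,
            seed=seed,
            min_variation=self.min_variation,
            field_slices=self.field_slices,
        )


@dataclass
class PLSFitResults:
    """Fitted PLS model: coefficients in original descriptor units."""

    model: FieldPLS
    state: PreprocessState
    n_components: int
    requested_components: int
    coefficients: np.ndarray  # full column space; filtered columns are 0
    intercept: float
    scores: np.ndarray
    weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    _stats: FitStats | None = dc_field(default=None, repr=False)

    # ---- prediction --------------------------------------------------
    def predict(self, X_new: np.ndarray | FieldBlock) -> np.ndarray:
        X = X_new.matrix if isinstance(X_new, FieldBlock) else np.asarray(X_new, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.coefficients.size:
            raise ValueError(
                f"column count {X.shape[1]} does not match model space "
                f"{self.coefficients.size}"
            )
        return X @ self.coefficients + self.intercept

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.X)

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    # ---- statistics --------------------------------------------------
    @property
    def stats(self) -> FitStats:
        if self._stats is None:
            self._stats = fit_statistics(self)
        return self._stats

    @property
    def rsquared(self) -> float:
        return self.stats.r2

    @property
    def see(self) -> float:
        return self.stats.see

    @property
    def fvalue(self) -> float:
        return self.stats.f_ratio

    @property
    def field_contributions(self) -> dict[str, float]:
        return self.stats.field_contrib

    def summary(self) -> str:
        s = self.stats
        lines = [
            "PLS regression results",
            "=" * 46,
            f"{'No. observations':<28}{self.model.nobs:>18}",
            f"{'Components':<28}{self.n_components:>18}",
            f"{'Columns (kept/total)':<28}"
            f"{f'{int(self.state.mask.sum())}/{self.state.mask.size}':>18}",
            f"{'r2':<28}{s.r2:>18.3f}",
            f"{'SEE':<28}{s.see:>18.3f}",
            f"{'F':<28}{s.f_ratio:>18.3f}",
        ]
        if s.field_contrib:
            lines.append("-" * 46)
            lines.append("Field contributions (%)")
            for name, pct in s.field_contrib.items():
                lines.append(f"  {name:<26}{pct:>18.1f}")
        lines.append("=" * 46)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spec-level functional surface
# ---------------------------------------------------------------------------

def nipals_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    min_variation: float = 0.0,
    field_slices: Mapping[str, slice] | None = None,
) -> PLSFitResults:
    """Fit a PLS model on a bare matrix (filter threshold 0 by default)."""
    return FieldPLS(
        y, np.asarray(X, float), field_slices=field_slices, min_variation=min_variation
    ).fit(n_components)


def predict(results: PLSFitResults, X_new: np.ndarray) -> np.ndarray:
    return results.predict(X_new)


def select_components(q2_by_components: Sequence[float]) -> int:
    """Parsimonious component count from a q^2 sequence.

    Starting from one component, the next count is adopted only while its
    relative q^2 gain over the current choice exceeds 10%; ties favour
    fewer components.
    """
    q2 = list(q2_by_components)
    if not q2:
        raise ValueError("empty q2 sequence")
    chosen = 0
    for i in range(1, len(q2)):
        gain = q2[i] - q2[chosen]
        if gain > 0.10 * abs(q2[chosen]) and gain > 0:
            chosen = i
        else:
            break
    return chosen + 1


def cross_validate(
    y: np.ndarray,
    block: FieldBlock | np.ndarray,
    max_components: int = 10,
    scheme: str = "loo",
    n_groups: int = 10,
    seed: int | None = None,
    min_variation: float = DEFAULT_MIN_VARIATION,
    field_slices: Mapping[str, slice] | None = None,
) -> CVStats:
    """Leave-one-out or leave-group-out cross-validation.

    Preprocessing (column filter, centring, block scaling) is refit
    inside every fold; held-out compounds are predicted from models they
    never touched.  q^2 is referenced to the full-sample response mean.
    """
    y = np.asarray(y, dtype=float).ravel()
    X, slices = _resolve(block, field_slices)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 compounds to cross-validate")
    max_components = min(max_components, n - 2, X.shape[1])

    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme in ("groups", "group", "lgo"):
        if n_groups > n:
            raise ValueError(f"group count {n_groups} exceeds {n} compounds")
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        folds = [np.sort(g) for g in np.array_split(order, n_groups)]
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    preds = np.full((n, max_components), np.nan)
    for held in folds:
        train = np.setdiff1d(np.arange(n), held)
        Xs, yc, state = preprocess(
            X[train], y[train], min_variation, slices
        )
        W, P, q, T, achieved = _nipals(Xs, yc, max_components)
        for c in range(1, max_components + 1):
            cc = min(c, achieved)
            b = _coefficients(W[:, :cc], P[:, :cc], q[:cc])
            coef = np.zeros(state.n_columns)
            coef[state.mask] = b * state.col_scales
            intercept = state.y_mean - float(coef[state.mask] @ state.col_means)
            preds[held, c - 1] = X[held] @ coef + intercept

    ss_tot = float(((y - y.mean()) ** 2).sum())
    q2_list, sep_list = [], []
    for c in range(1, max_components + 1):
        press = float(((y - preds[:, c - 1]) ** 2).sum())
        q2_list.append(1.0 - press / ss_tot)
        dof = n - c - 1
        sep_list.append(float(np.sqrt(press / dof)) if dof > 0 else float("nan"))
    chosen = select_components(q2_list)
    return CVStats(
        q2_by_components=q2_list,
        sep_by_components=sep_list,
        chosen_components=chosen,
        fold_predictions=preds,
        scheme=scheme,
        seed=seed,
    )


def regression_stats(
    actual: np.ndarray, predicted: np.ndarray, n_components: int
) -> tuple[float, float, float]:
    """(r2, SEE, F) for an (actual, predicted) pair at c latent variables.

    SEE = sqrt(SSres / (n - c - 1)); F = (r2/c) / ((1-r2)/(n-c-1)).
    """
    a = np.asarray(actual, float).ravel()
    p = np.asarray(predicted, float).ravel()
    if a.size != p.size:
        raise ValueError("actual/predicted length mismatch")
    n, c = a.size, n_components
    if n <= c + 1:
        raise ValueError(f"degrees of freedom exhausted: n={n}, components={c}")
    ss_res = float(((a - p) ** 2).sum())
    ss_tot = float(((a - a.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant response: r2 undefined")
    r2 = 1.0 - ss_res / ss_tot
    see = float(np.sqrt(ss_res / (n - c - 1)))
    f = (r2 / c) / ((1.0 - r2) / (n - c - 1)) if r2 < 1.0 else float("inf")
    return r2, see, f


def fit_statistics(results: PLSFitResults) -> FitStats:
    """Fit statistics and per-field contribution percentages."""
    y = results.model.y
    fitted = results.fittedvalues
    c = max(results.n_components, 1)
    r2, see, f = regression_stats(y, fitted, c)

    contrib: dict[str, float] = {}
    state = results.state
    kept = np.flatnonzero(state.mask)
    weight = np.abs(results.coefficients[kept]) * state.col_sd
    if state.field_slices:
        for name, sl in state.field_slices.items():
            in_field = (kept >= (sl.start or 0)) & (kept < sl.stop)
            contrib[name] = float(weight[in_field].sum())
    else:
        contrib["all"] = float(weight.sum())
    total = sum(contrib.values())
    if total > 0:
        contrib = {k: 100.0 * v / total for k, v in contrib.items()}
    else:
        contrib = {k: 0.0 for k in contrib}
    return FitStats(r2=r2, see=see, f_ratio=f, field_contrib=contrib)
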