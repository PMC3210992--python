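"""Model validation: bootstrap, progressive scrambling, external test set.

Three complementary checks of a field-PLS model:

* **Bootstrap** — refit on resamples drawn with replacement to gauge the
  stability of r2 and SEE.

* **Progressive scrambling** — partially scramble the response at
  increasing strength, tracking how cross-validated predictivity decays
  as the scrambled response decorrelates from the original
  (r2_yy' = squared Pearson correlation between original and perturbed
  responses).  Cubic fits of q^2 and SDEP against r2_yy' are read off at
  a critical point (default r2_yy' = 0.85): Q^2 estimates predictivity
  with redundancy removed, cSDEP the corresponding error, and the slope
  dq^2/dr2_yy' measures stability (near 1 = stable; > 1.2 = unstable).

* **Predictive r^2** — external-test-set statistic
  r2_pred = 1 - PRESS/SD, where PRESS sums squared test-set prediction
  errors and SD sums squared deviations of the test activities from the
  *training-set* mean activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .fields import FieldBlock
from .pls import DEFAULT_MIN_VARIATION, FieldPLS, _coefficients, _nipals, preprocess, _resolve

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapResult",
    "ScramblingResult",
    "PredictiveResult",
    "bootstrap_validate",
    "progressive_scrambling",
    "fit_scrambling_curves",
    "r2_pred",
]

DEFAULT_SCRAMBLING_LEVELS = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


@dataclass(frozen=True)
class BootstrapResult:
    runs: int
    r2_mean: float
    r2_sd: float
    see_mean: float
    see_sd: float
    seed: int | None


@dataclass(frozen=True)
class ScramblingResult:
    r2_yy: np.ndarray       # per draw
    q2: np.ndarray          # per draw
    sdep: np.ndarray        # per draw
    a_coeffs: np.ndarray    # cSDEP cubic a0..a3 (ascending powers)
    b_coeffs: np.ndarray    # q^2 cubic b0..b3 (ascending powers)
    critical_point: float
    Q2: float
    cSDEP: float
    slope: float            # dq^2/dr2_yy' at the critical point
    seed: int | None


@dataclass(frozen=True)
class PredictiveResult:
    press: float
    sd: float
    r2_pred: float
    n_test: int


# ---------------------------------------------------------------------------


def bootstrap_validate(
    y: np.ndarray,
    block: FieldBlock | np.ndarray,
    n_components: int,
    runs: int = 10,
    seed: int | None = None,
    min_variation: float = DEFAULT_MIN_VARIATION,
    field_slices: Mapping[str, slice] | None = None,
) -> BootstrapResult:
    """Row-resampling bootstrap of the non-validated fit statistics.

    Each run resamples compounds with replacement to the original n,
    refits (preprocessing included) and records the in-sample r2 and SEE.
    Degenerate resamples (constant response) are redrawn and logged.
    """
    y = np.asarray(y, dtype=float).ravel()
    X, slices = _resolve(block, field_slices)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 compounds to bootstrap")
    if runs < 2:
        raise ValueError("need at least 2 bootstrap runs for a standard deviation")
    rng = np.random.default_rng(seed)

    r2s, sees = [], []
    for run in range(runs):
        for attempt in range(100):
            idx = rng.integers(0, n, n)
            if np.ptp(y[idx]) > 1e-12:
                break
            logger.info("bootstrap run %d: degenerate resample redrawn", run)
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        model = FieldPLS(
            y[idx], X[idx], field_slices=slices, min_variation=min_variation
        )
        res = model.fit(min(n_components, n - 2))
        r2s.append(res.rsquared)
        sees.append(res.see)

    return BootstrapResult(
        runs=runs,
        r2_mean=float(np.mean(r2s)),
        r2_sd=float(np.std(r2s, ddof=1)),
        see_mean=float(np.mean(sees)),
        see_sd=float(np.std(sees, ddof=1)),
        seed=seed,
    )


def _partial_scramble(y: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Scramble a fraction of the response entries among themselves."""
    y = y.copy()
    n = y.size
    k = int(round(fraction * n))
    if k >= 2:
        pick = rng.choice(n, size=k, replace=False)
        y[pick] = y[rng.permutation(pick)]
    return y


def _loo_press(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    min_variation: float,
    slices: Mapping[str, slice] | None,
) -> float:
    n = y.size
    press = 0.0
    for i in range(n):
        train = np.delete(np.arange(n), i)
        Xs, yc, state = preprocess(X[train], y[train], min_variation, slices)
        W, P, q, T, achieved = _nipals(Xs, yc, n_components)
        b = _coefficients(W, P, q)
        coef = np.zeros(state.n_columns)
        coef[state.mask] = b * state.col_scales
        intercept = state.y_mean - float(coef[state.mask] @ state.col_means)
        press += (y[i] - (X[i] @ coef + intercept)) ** 2
    return float(press)


def fit_scrambling_curves(
    r2_yy: np.ndarray,
    q2: np.ndarray,
    sdep: np.ndarray,
    critical_point: float = 0.85,
    seed: int | None = None,
) -> ScramblingResult:
    """Cubic least-squares fits of q^2 and SDEP versus r2_yy'.

    Evaluates Q^2 and cSDEP at the critical point and the analytical
    slope b1 + 2 b2 x + 3 b3 x^2 of the q^2 cubic there.
    """
    r2_yy = np.asarray(r2_yy, float)
    q2 = np.asarray(q2, float)
    sdep = np.asarray(sdep, float)
    if r2_yy.size < 4:
        raise ValueError("need at least 4 draws to fit a cubic")
    # ascending-power coefficients
    b = np.polynomial.polynomial.polyfit(r2_yy, q2, 3)
    a = np.polynomial.polynomial.polyfit(r2_yy, sdep, 3)
    x = critical_point
    Q2 = float(b[0] + b[1] * x + b[2] * x**2 + b[3] * x**3)
    cSDEP = float(a[0] + a[1] * x + a[2] * x**2 + a[3] * x**3)
    slope = float(b[1] + 2 * b[2] * x + 3 * b[3] * x**2)
    return ScramblingResult(
        r2_yy=r2_yy, q2=q2, sdep=sdep, a_coeffs=a, b_coeffs=b,
        critical_point=x, Q2=Q2, cSDEP=cSDEP, slope=slope, seed=seed,
    )


def progressive_scrambling(
    y: np.ndarray,
    block: FieldBlock | np.ndarray,
    n_components: int,
    levels: Sequence[float] = DEFAULT_SCRAMBLING_LEVELS,
    reps: int = 3,
    seed: int | None = None,
    critical_point: float = 0.85,
    min_variation: float = DEFAULT_MIN_VARIATION,
    field_slices: Mapping[str, slice] | None = None,
) -> ScramblingResult:
    """Progressive response scrambling at increasing perturbation strength.

    For each level a fraction of response entries is scrambled within a
    seeded permutation (``reps`` draws per level); for each draw the
    model is LOO-cross-validated on the perturbed response and the pair
    (r2_yy', q^2) recorded, then cubic curves are fit and read off at the
    critical point.
    """
    y = np.asarray(y, dtype=float).ravel()
    X, slices = _resolve(block, field_slices)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = y.size
    ss_y = float(((y - y.mean()) ** 2).sum())
    if ss_y == 0:
        raise ValueError("constant response cannot be scrambled")

    r2_list, q2_list, sdep_list = [], [], []
    for lam in levels:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"scrambling level {lam} outside [0, 1]")
        for _ in range(reps):
            yp = _partial_scramble(y, lam, rng)
            denom = y.std() * yp.std()
            r2yy = float(np.corrcoef(y, yp)[0, 1] ** 2) if denom > 0 else 0.0
            press = _loo_press(X, yp, n_components, min_variation, slices)
            ss_p = float(((yp - yp.mean()) ** 2).sum())
            q2_list.append(1.0 - press / ss_p)
            sdep_list.append(float(np.sqrt(press / n)))
            r2_list.append(r2yy)

    r2_arr = np.array(r2_list)
    if r2_arr.min() > 0.95:
        raise ValueError(
            "perturbation too weak: every draw kept r2_yy' > 0.95; "
            "use stronger scrambling levels"
        )
    return fit_scrambling_curves(
        r2_arr, np.array(q2_list), np.array(sdep_list), critical_point, seed
    )


def r2_pred(
    test_actual: np.ndarray,
    test_predicted: np.ndarray,
    train_mean: float,
) -> PredictiveResult:
    """External-test-set predictive r^2 = 1 - PRESS/SD.

    ``SD`` references the *training-set* mean activity; a negative value
    means the model predicts the test compounds worse than that mean.
    """
    a = np.asarray(test_actual, float).ravel()
    p = np.asarray(test_predicted, float).ravel()
    if a.size != p.size:
        raise ValueError("actual/predicted length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 test compounds")
    press = float(((a - p) ** 2).sum())
    sd = float(((a - train_mean) ** 2).sum())
    if sd == 0:
        raise ValueError("SD is zero: test activities all equal the training mean")
    return PredictiveResult(press=press, sd=sd, r2_pred=1.0 - press / sd, n_test=a.size)
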