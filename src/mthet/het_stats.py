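"""Heteroplasmy segregation statistics.

Core quantities used throughout the package:

* heteroplasmy shift ``h - h0``: a germ cell's (or pup's) heteroplasmy
  minus the maternal reference value (an ear biopsy taken when the cells
  were collected);
* transformed shift ``h' = ln(h(1-h0) / (h0(1-h)))``: the logit
  difference, whose sign says whether ``h`` moved up or down relative to
  ``h0`` and whose magnitude is comparable across mothers with different
  starting heteroplasmies;
* normalized variance ``V'(h) = Var(h) / (mu(1-mu))``: 0 when all cells
  share one heteroplasmy, 1 at complete fixation (all cells at 0 or 1).

Plus the regression/testing layer: mother->offspring transmission OLS,
maternal-age regression on transformed shifts, and t tests between
developmental stages with Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import (
    BoundaryError,
    DegenerateInputError,
    InsufficientDataError,
    RankDeficiencyError,
)

__all__ = [
    "heteroplasmy_shift",
    "transformed_shift",
    "normalized_variance",
    "fit_transmission",
    "age_effect",
    "compare_stages",
    "TransmissionFit",
    "RegressionReport",
    "StageTestReport",
]

#: developmental stages of the oocyte records, in order
STAGES = ("primordial", "primary", "secondary", "antral", "ovulated")


def heteroplasmy_shift(h, h0):
    """Heteroplasmy shift: cell (or offspring) value minus maternal reference."""
    h = np.asarray(h, dtype=float)
    h0 = np.asarray(h0, dtype=float)
    if np.any((h < 0) | (h > 1)) or np.any((h0 < 0) | (h0 > 1)):
        raise BoundaryError("heteroplasmy fractions must lie in [0, 1]")
    out = h - h0
    return float(out) if out.ndim == 0 else out


def transformed_shift(h, h0, boundary: str = "error", eps: float = 1e-4):
    """Transformed heteroplasmy shift ``ln(h(1-h0) / (h0(1-h)))``.

    Antisymmetric under swapping ``h`` and ``h0``; positive iff
    ``h > h0``.  Values at the boundaries 0/1 are undefined; the default
    policy raises, ``boundary="clamp"`` instead pulls them to
    ``[eps, 1-eps]`` (clamping distorts tails, so it is opt-in).
    """
    h = np.asarray(h, dtype=float)
    h0 = np.asarray(h0, dtype=float)
    at_edge = (h <= 0) | (h >= 1) | (h0 <= 0) | (h0 >= 1)
    if np.any(at_edge):
        if boundary == "error":
            raise BoundaryError(
                "transformed shift needs h, h0 strictly inside (0, 1); "
                "pass boundary='clamp' to clamp at eps"
            )
        if boundary != "clamp":
            raise ValueError(f"unknown boundary policy {boundary!r}")
        h = np.clip(h, eps, 1 - eps)
        h0 = np.clip(h0, eps, 1 - eps)
    out = np.log(h * (1 - h0)) - np.log(h0 * (1 - h))
    return float(out) if out.ndim == 0 else out


def normalized_variance(hs, ddof: int = 0) -> float:
    """Normalized heteroplasmy variance ``V'(h) = Var(h) / (mu(1 - mu))``.

    With the population-variance convention (``ddof=0``, the default)
    ``V'`` is exactly 1 for a sample containing only 0s and 1s and can
    never exceed 1; with ``ddof=1`` sample values slightly above 1 are
    possible and are returned as-is.
    """
    hs = np.asarray(hs, dtype=float)
    if hs.size < 2:
        raise InsufficientDataError("need >=2 values for a variance")
    mu = hs.mean()
    if not (0.0 < mu < 1.0):
        raise DegenerateInputError(f"mean heteroplasmy {mu} is 0 or 1")
    return float(hs.var(ddof=ddof) / (mu * (1.0 - mu)))


@dataclass
class RegressionReport:
    """OLS summary: point estimates, 95% CIs, p-values, residual info."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    slope_p: float
    n: int
    n_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci": list(self.slope_ci),
            "intercept_ci": list(self.intercept_ci),
            "slope_p": self.slope_p,
            "n": self.n,
            "n_dropped": self.n_dropped,
        }


@dataclass
class TransmissionFit:
    """Mother->offspring transmission regression plus per-mother shifts."""

    regression: RegressionReport
    per_mother: pd.DataFrame = field(repr=False)
    #: slope < 1 with intercept > 0: shifts positive at low maternal
    #: heteroplasmy and negative at high — the signature of selection
    selection_signature: bool = False

    @property
    def crossing_h0(self) -> float:
        """Maternal heteroplasmy at which the mean shift changes sign."""
        return self.regression.intercept / (1.0 - self.regression.slope)


def _ols_report(x: np.ndarray, y: np.ndarray, n_dropped: int = 0) -> RegressionReport:
    if np.ptp(x) == 0:
        raise RankDeficiencyError("predictor has no variation")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionReport(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        slope_p=float(fit.pvalues[1]),
        n=len(x),
        n_dropped=n_dropped,
    )


def fit_transmission(pairs: pd.DataFrame) -> TransmissionFit:
    """OLS of offspring heteroplasmy on maternal heteroplasmy.

    ``pairs`` needs columns ``mother_h0`` and ``offspring_h`` (fractions);
    an optional ``mother_id`` groups the per-mother mean-shift table
    (otherwise mothers are identified by their ``mother_h0`` value).
    Under faithful 1:1 transmission the fit is the identity line; slope
    below 1 with positive intercept means low-heteroplasmy mothers hand
    up-shifted levels to their pups and high-heteroplasmy mothers
    down-shifted ones.
    """
    if len(pairs) < 3:
        raise InsufficientDataError("need >=3 mother-offspring pairs")
    x = pairs["mother_h0"].to_numpy(dtype=float)
    y = pairs["offspring_h"].to_numpy(dtype=float)
    reg = _ols_report(x, y)
    key = "mother_id" if "mother_id" in pairs.columns else "mother_h0"
    shifts = pairs.assign(shift=y - x)
    agg = {"mean_shift": ("shift", "mean"), "sem_shift": ("shift", "sem"),
           "n": ("shift", "size")}
    if key != "mother_h0":
        agg["mother_h0"] = ("mother_h0", "mean")
    per_mother = shifts.groupby(key, sort=True).agg(**agg).reset_index()
    sig = reg.slope < 1.0 and reg.intercept > 0.0
    return TransmissionFit(regression=reg, per_mother=per_mother, selection_signature=sig)


def age_effect(pairs: pd.DataFrame, boundary: str = "error") -> RegressionReport:
    """OLS of the transformed heteroplasmy shift on maternal age.

    Rows with missing age are dropped (count reported in ``n_dropped``).
    A flat slope (large p) means the transmitted shift does not change
    with how old the mother was at delivery.
    """
    if "maternal_age" not in pairs.columns:
        raise InsufficientDataError("no maternal_age column")
    keep = pairs.dropna(subset=["maternal_age"])
    n_dropped = len(pairs) - len(keep)
    if len(keep) < 3:
        raise InsufficientDataError("need >=3 pairs with maternal age")
    hprime = transformed_shift(
        keep["offspring_h"].to_numpy(float),
        keep["mother_h0"].to_numpy(float),
        boundary=boundary,
    )
    return _ols_report(keep["maternal_age"].to_numpy(float), np.asarray(hprime),
                       n_dropped=n_dropped)


@dataclass
class StageTestReport:
    """t-test results with raw and Bonferroni-adjusted p-values."""

    one_sample: pd.DataFrame
    two_sample: pd.DataFrame
    corrections: int

    def to_dict(self) -> dict:
        return {
            "corrections": self.corrections,
            "one_sample": self.one_sample.to_dict(orient="records"),
            "two_sample": self.two_sample.to_dict(orient="records"),
        }


def bonferroni(p, corrections: int):
    """Adjusted p-value: ``min(1, p * corrections)``."""
    return np.minimum(1.0, np.asarray(p, dtype=float) * corrections)


def compare_stages(groups: dict[str, np.ndarray], corrections: int | None = None,
                   pairs: list[tuple[str, str]] | None = None) -> StageTestReport:
    """One- and two-sample t tests on transformed shifts between stages.

    Each group's mean is tested against 0 (one-sample) and every
    requested pair of groups against each other (two-sample, default:
    all pairs in order).  ``corrections`` defaults to the total number
    of tests performed; adjusted p-values are ``min(1, raw * corrections)``.
    """
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise InsufficientDataError(f"group {k!r} needs >=2 values")
        if v.std() == 0:
            raise DegenerateInputError(f"group {k!r} has zero variance")
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    n_tests = len(names) + len(pairs)
    if corrections is None:
        corrections = n_tests
    one = []
    for k in names:
        t, praw = sps.ttest_1samp(arrays[k], 0.0)
        one.append({"group": k, "mean": float(arrays[k].mean()), "t": float(t),
                    "p_raw": float(praw),
                    "p_adj": float(bonferroni(praw, corrections))})
    two = []
    for a, b in pairs:
        t, praw = sps.ttest_ind(arrays[a], arrays[b], equal_var=False)
        two.append({"group_a": a, "group_b": b,
                    "mean_diff": float(arrays[a].mean() - arrays[b].mean()),
                    "t": float(t), "p_raw": float(praw),
                    "p_adj": float(bonferroni(praw, corrections))})
    return StageTestReport(one_sample=pd.DataFrame(one),
                           two_sample=pd.DataFrame(two),
                           corrections=corrections)
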