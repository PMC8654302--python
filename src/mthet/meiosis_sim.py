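"""Heteroplasmy segregation during spermatogenesis.

Meiosis partitions a primary spermatocyte's (4N) mitochondrial pool over
two successive divisions with no intervening mtDNA replication, so each
division is modelled as an independent symmetric binomial split of the
mutant and wild-type pools: ``m' ~ Binomial(m, 1/2)``,
``w' ~ Binomial(w, 1/2)``.  One step predicts secondary spermatocytes
(2C), two steps predict spermatids (1C).  Starting states are drawn from
a kernel density estimate fitted to measured 4N cells in
mutant/wild-type copy-number space, so the prediction uses the empirical
joint distribution rather than a parametric assumption.

Partitioning preserves mean heteroplasmy (up to an O(1/N) ratio bias)
and strictly inflates its normalized variance — the vegetative
segregation expected when no selection acts in the male germ line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError, InvalidParameterError
from .het_stats import normalized_variance

__all__ = ["partition", "fit_density", "CopyNumberKDE", "simulate_meiosis",
           "MeiosisPrediction"]

log = logging.getLogger(__name__)

PLOIDIES = ("4N", "2N", "1N")


def partition(m, w, steps: int, rng: np.random.Generator):
    """Symmetric binomial partition of (m, w), applied ``steps`` times.

    Accepts scalars or arrays; zero counts propagate as zeros.
    """
    if steps < 1:
        raise InvalidParameterError("steps must be >= 1")
    scalar = np.ndim(m) == 0
    m = np.asarray(m, dtype=np.int64)
    w = np.asarray(w, dtype=np.int64)
    for _ in range(steps):
        m = np.asarray(rng.binomial(m, 0.5))
        w = np.asarray(rng.binomial(w, 0.5))
    if scalar:
        return int(m), int(w)
    return m, w


class CopyNumberKDE:
    """Gaussian KDE over (mutant, wild-type) copy numbers of 4N cells.

    The KDE lives in ``log10(1 + count)`` coordinates because copy
    numbers span orders of magnitude; draws are back-transformed,
    rounded to integers and truncated at zero.  ``pdf`` returns the
    density on the original count scale (Jacobian included).
    """

    def __init__(self, m: np.ndarray, w: np.ndarray, bw_method=None):
        self.m = np.asarray(m, dtype=float)
        self.w = np.asarray(w, dtype=float)
        self._z = np.log10(1.0 + np.vstack([self.m, self.w]))
        stds = self._z.std(axis=1, ddof=1)
        self._kde = None
        if np.all(stds > 0):
            try:
                self._kde = gaussian_kde(self._z, bw_method=bw_method)
            except np.linalg.LinAlgError:
                pass  # singular covariance (e.g. perfectly correlated data)
        if self._kde is None:
            # degenerate data: product-kernel fallback with Scott's factor
            # per dimension; a zero-variance dimension stays exact
            self._factor = self._z.shape[1] ** (-1.0 / 6.0)
            self._sigmas = self._factor * stds

    @property
    def bandwidth_factor(self) -> float:
        return float(self._kde.factor) if self._kde is not None else self._factor

    def pdf(self, m, w) -> np.ndarray:
        if self._kde is None:
            raise InsufficientDataError(
                "density undefined for degenerate 4N data (zero variance)")
        m = np.asarray(m, dtype=float)
        w = np.asarray(w, dtype=float)
        z = np.log10(1.0 + np.vstack([m.ravel(), w.ravel()]))
        dens = self._kde(z)
        jac = 1.0 / ((1.0 + m.ravel()) * (1.0 + w.ravel()) * np.log(10.0) ** 2)
        return (dens * jac).reshape(m.shape)

    def _resample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self._kde is not None:
            return self._kde.resample(n, seed=rng)
        idx = rng.integers(0, self._z.shape[1], size=n)
        return (self._z[:, idx]
                + self._sigmas[:, None] * rng.standard_normal((2, n)))

    def sample(self, n: int, rng: np.random.Generator,
               max_redraws: int = 100) -> tuple[np.ndarray, np.ndarray, int]:
        """Draw ``n`` integer (m, w) states; empty cells (m+w=0) are redrawn.

        Returns (m, w, n_redrawn).
        """
        need = n
        ms, ws = [], []
        redrawn = 0
        for _ in range(max_redraws):
            z = self._resample(need, rng)
            mm = np.round(10.0 ** z[0] - 1.0).astype(np.int64)
            ww = np.round(10.0 ** z[1] - 1.0).astype(np.int64)
            mm = np.clip(mm, 0, None)
            ww = np.clip(ww, 0, None)
            ok = (mm + ww) > 0
            redrawn += int((~ok).sum())
            ms.append(mm[ok])
            ws.append(ww[ok])
            need -= int(ok.sum())
            if need == 0:
                break
        if need > 0:
            raise InsufficientDataError("KDE keeps producing empty cells")
        if redrawn:
            log.info("redrew %d empty KDE draws", redrawn)
        return np.concatenate(ms), np.concatenate(ws), redrawn


def fit_density(records_4N: pd.DataFrame, bw_method=None) -> CopyNumberKDE:
    """Fit the 4N copy-number KDE from a sperm-record table.

    ``records_4N`` needs integer columns ``m`` and ``w``; rows whose
    ploidy column (if present) is not ``4N`` are ignored.
    """
    df = records_4N
    if "ploidy" in df.columns:
        df = df[df["ploidy"] == "4N"]
    if len(df) < 10:
        raise InsufficientDataError(f"need >=10 4N records, got {len(df)}")
    return CopyNumberKDE(df["m"].to_numpy(float), df["w"].to_numpy(float),
                         bw_method=bw_method)


@dataclass
class MeiosisPrediction:
    """Predicted post-meiotic copy-number/heteroplasmy samples + summaries."""

    samples: dict[str, pd.DataFrame]
    summary: pd.DataFrame
    n_redrawn: int

    def vprime(self, stage: str) -> float:
        return float(self.summary.set_index("stage").loc[stage, "vprime"])

    def mean_h(self, stage: str) -> float:
        return float(self.summary.set_index("stage").loc[stage, "mean_h"])


def _summarise(tag: str, m: np.ndarray, w: np.ndarray) -> dict:
    tot = m + w
    ok = tot > 0
    h = m[ok] / tot[ok]
    mu = float(h.mean())
    # a homoplasmic sample has no segregation variance by definition
    vprime = normalized_variance(h) if 0.0 < mu < 1.0 else 0.0
    return {"stage": tag, "n": int(ok.sum()), "n_empty": int((~ok).sum()),
            "mean_h": mu, "vprime": vprime,
            "mean_total": float(tot[ok].mean())}


def simulate_meiosis(records_4N: pd.DataFrame, n_iter: int = 10_000,
                     rng: np.random.Generator | None = None,
                     bw_method=None) -> MeiosisPrediction:
    """Predict 2C and 1C heteroplasmy from measured 4N cells.

    Draws ``n_iter`` starting states from the fitted 4N density, applies
    one symmetric binomial partition step for the 2C prediction and two
    for 1C, and summarises mean heteroplasmy and normalized variance per
    class.  Cells partitioned to emptiness are excluded from the
    heteroplasmy summaries (their count is reported).
    """
    if n_iter < 100:
        raise InvalidParameterError("n_iter must be >= 100")
    rng = np.random.default_rng() if rng is None else rng
    kde = fit_density(records_4N, bw_method=bw_method)
    m0, w0, redrawn = kde.sample(n_iter, rng)
    m2, w2 = partition(m0, w0, 1, rng)
    m1, w1 = partition(m2, w2, 1, rng)
    samples = {
        "4N": pd.DataFrame({"m": m0, "w": w0}),
        "2C": pd.DataFrame({"m": m2, "w": w2}),
        "1C": pd.DataFrame({"m": m1, "w": w1}),
    }
    summary = pd.DataFrame([
        _summarise("4N", m0, w0),
        _summarise("2C", m2, w2),
        _summarise("1C", m1, w1),
    ])
    for df in samples.values():
        tot = df["m"] + df["w"]
        df["h"] = np.where(tot > 0, df["m"] / tot.replace(0, 1), np.nan)
    return MeiosisPrediction(samples=samples, summary=summary, n_redrawn=redrawn)
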