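"""ABC rejection inference over the six replication models.

Approximate Bayesian computation compares observed single-oocyte data to
forward simulations through low-dimensional summary statistics.  Each
*particle* is a model indicator ``H`` drawn uniformly from {0..5} plus a
parameter vector from the priors; a cohort is simulated from the
observed primordial states, summarised, and scored by the Euclidean
distance between standardized summary vectors.  Model support at an
acceptance threshold is the per-model share of the particles whose
distance falls below it; tightening the threshold forces stricter
agreement with the data and concentrates support on the models that can
actually reproduce it.

Summary statistics (per developmental stage: primordial, growing,
antral): mean transformed heteroplasmy shift, normalized variance V',
mean and SD of log10 total copy number.  Components are standardized by
their SD across a pilot pool of prior-predictive particles so no single
summary dominates the distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError
from .het_stats import normalized_variance, transformed_shift
from .oocyte_sim import CellState, SimParams, cohort_finals

__all__ = [
    "STAGE_GROUPS",
    "SummaryStats",
    "PriorSpec",
    "ABCResult",
    "summarize",
    "sample_prior",
    "abc_reject",
    "posterior_summary",
]

log = logging.getLogger(__name__)

#: mapping of raw stage labels onto the three summary groups
STAGE_GROUPS = {
    "primordial": "primordial",
    "primary": "growing",
    "secondary": "growing",
    "antral": "antral",
    "ovulated": "antral",
}
GROUP_ORDER = ("primordial", "growing", "antral")
_STAT_NAMES = ("mean_hprime", "vprime", "mean_log10_n", "sd_log10_n")

#: clamp width used when transformed shifts meet fixated cells
_EPS = 1e-4


@dataclass
class SummaryStats:
    """Per-stage-group summary vector with named components."""

    values: np.ndarray
    names: list[str]
    flags: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def summarize(cells: pd.DataFrame) -> SummaryStats:
    """Summaries of an oocyte table for the ABC distance.

    ``cells`` needs columns stage, h, copy_number, mother_h0.  Stages
    are pooled into the three groups (primordial / growing / antral);
    any group with fewer than 2 cells is dropped with a warning, and if
    all groups drop the dataset is unusable.  V' values above 1 (possible
    with sample noise) are flagged, not clamped.
    """
    req = {"stage", "h", "copy_number", "mother_h0"}
    missing = req - set(cells.columns)
    if missing:
        raise InsufficientDataError(f"missing columns: {sorted(missing)}")
    grp = cells["stage"].map(STAGE_GROUPS)
    values, names, flags = [], [], []
    for g in GROUP_ORDER:
        sub = cells[grp == g]
        if len(sub) < 2:
            log.warning("stage group %r has <2 cells; omitted", g)
            continue
        h = sub["h"].to_numpy(float)
        h0 = sub["mother_h0"].to_numpy(float)
        hp = transformed_shift(h, h0, boundary="clamp", eps=_EPS)
        vp = normalized_variance(h)
        if vp > 1.0:
            flags.append(f"{g}: V'={vp:.3f} > 1")
        logn = np.log10(np.maximum(sub["copy_number"].to_numpy(float), 1.0))
        stats = (float(np.mean(hp)), float(vp), float(logn.mean()),
                 float(logn.std()))
        values.extend(stats)
        names.extend(f"{g}_{s}" for s in _STAT_NAMES)
    if not values:
        raise InsufficientDataError("every stage group had <2 cells")
    return SummaryStats(values=np.array(values), names=names, flags=flags)


# ---------------------------------------------------------------------------
# priors

@dataclass(frozen=True)
class PriorSpec:
    """Independent priors for the replication-model parameters.

    lambda rates are uniform; R0 and w_th are log-uniform (they act on
    scale); thresholds are uniform with the H=5 ordering h_th1 < h_th2
    imposed by rejection; T is uniform over the iteration range.
    """

    lambda_lo: float = 0.05
    lambda_hi: float = 1.0
    r0_lo: float = 10.0
    r0_hi: float = 1_000.0
    hth_lo: float = 0.2
    hth_hi: float = 0.99
    wth_lo: float = 100.0
    wth_hi: float = 10_000.0
    t_max: int = 5_000
    #: run controls copied onto every sampled SimParams
    N_final: int = 141_000

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _loguniform(lo, hi, rng):
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def sample_prior(H: int, priors: PriorSpec, rng: np.random.Generator) -> SimParams:
    """One parameter draw respecting the model's structural constraints."""
    if H not in range(6):
        raise InvalidParameterError("H must be in 0..5")
    lam_w = float(rng.uniform(priors.lambda_lo, priors.lambda_hi))
    if H in (1, 4):
        lam_m = lam_w
    else:
        lam_m = float(rng.uniform(priors.lambda_lo, priors.lambda_hi))
    h1, h2 = 0.4, 0.8
    if H == 5:
        while True:  # rejection keeps the pair exchangeably uniform on the wedge
            h1 = float(rng.uniform(priors.hth_lo, priors.hth_hi))
            h2 = float(rng.uniform(priors.hth_lo, priors.hth_hi))
            if h1 < h2:
                break
    return SimParams(
        lambda_m=lam_m,
        lambda_w=lam_w,
        R0=int(round(_loguniform(priors.r0_lo, priors.r0_hi, rng))),
        H=H,
        h_th=float(rng.uniform(priors.hth_lo, priors.hth_hi)),
        T=int(rng.integers(0, priors.t_max + 1)),
        h_th1=h1,
        h_th2=h2,
        w_th=int(round(_loguniform(priors.wth_lo, priors.wth_hi, rng))),
        N_final=priors.N_final,
        t_max=priors.t_max,
    )


def _endpoint_targets(observed: SummaryStats, initials, rng) -> np.ndarray | None:
    """Per-cell stopping copy numbers from the observed antral law.

    Antral copy number varies between cells; the selection models under
    comparison describe heteroplasmy dynamics, not the endpoint size, so
    the stopping rule is conditioned on the observed antral log10
    mean/SD.  Targets are drawn once and shared by every particle
    (common random numbers keep the comparison sharp).  Returns None
    when the antral copy-number summaries are unavailable.
    """
    names = list(observed.names)
    if "antral_mean_log10_n" not in names or "antral_sd_log10_n" not in names:
        return None
    mu = observed.values[names.index("antral_mean_log10_n")]
    sd = observed.values[names.index("antral_sd_log10_n")]
    z = rng.standard_normal(len(initials))
    targets = np.round(10.0 ** (mu + sd * z)).astype(np.int64)
    floor = np.array([s.n for s in initials], dtype=np.int64) + 1
    return np.maximum(targets, floor)


# ---------------------------------------------------------------------------
# rejection sampler

_PARAM_COLS = ["lambda_m", "lambda_w", "R0", "h_th", "T", "h_th1", "h_th2", "w_th"]


@dataclass
class ABCResult:
    """Particles, acceptance thresholds and per-model support."""

    particles: pd.DataFrame
    thresholds: np.ndarray
    threshold_quantiles: np.ndarray
    support: pd.DataFrame
    top_k: pd.DataFrame
    priors: PriorSpec
    seed: int | None = None

    def accepted(self, threshold: float) -> pd.DataFrame:
        return self.particles[self.particles["distance"] <= threshold]

    def support_at(self, threshold: float) -> dict[int, float]:
        acc = self.accepted(threshold)
        if len(acc) == 0:
            return {}
        return (acc["H"].value_counts(normalize=True)
                .reindex(range(6), fill_value=0.0).to_dict())


def _simulate_summaries(params: SimParams, initials, h0s, milestones, rng,
                        targets=None):
    """Summary vector of one simulated cohort, matching `summarize` layout.

    Stage checkpoints map onto the three groups exactly as observed
    stages do; the maternal reference of a simulated cell is its own
    initial heteroplasmy.  ``targets`` (optional) gives each cell its
    own stopping copy number.
    """
    labels, am, aw, _ = cohort_finals(initials, params, rng, milestones,
                                      n_final_per_cell=targets)
    values = []
    tot = am + aw
    h_all = am / tot
    for g in GROUP_ORDER:
        cols = [j for j, lab in enumerate(labels) if STAGE_GROUPS[lab] == g]
        h = h_all[:, cols].ravel()
        n = tot[:, cols].ravel().astype(float)
        hp = transformed_shift(h, np.tile(h0s, len(cols)),
                               boundary="clamp", eps=_EPS)
        mu = h.mean()
        vp = h.var() / (mu * (1 - mu)) if 0 < mu < 1 else 1.0
        logn = np.log10(np.maximum(n, 1.0))
        values.extend((float(np.mean(hp)), float(vp), float(logn.mean()),
                       float(logn.std())))
    return np.array(values)


def abc_reject(observed: SummaryStats, initials: list[CellState],
               n_particles: int, priors: PriorSpec,
               rng: np.random.Generator,
               threshold_quantiles=(0.05, 0.01, 0.005, 0.001),
               milestones: dict[str, int] | None = None,
               n_pilot: int = 1000, top_k: int = 200) -> ABCResult:
    """ABC rejection sampling with model selection over H = 0..5.

    ``initials`` are the primordial starting states (typically built
    from the observed primordial cells); every particle simulates the
    same cohort under its own parameters.  Distances are Euclidean after
    per-component standardization by the SD over the first ``n_pilot``
    particles.  Thresholds are the given quantiles of the pooled
    distance distribution, in decreasing order of looseness.
    """
    if n_particles < 100:
        raise InvalidParameterError("need at least 100 particles")
    q = np.asarray(sorted(threshold_quantiles, reverse=True), dtype=float)
    if np.any(np.diff(q) >= 0):
        raise InvalidParameterError("threshold quantiles must be distinct")
    h0s = np.array([s.h for s in initials])
    obs = observed.values
    targets = _endpoint_targets(observed, initials, rng)
    rows = []
    sims = np.empty((n_particles, obs.size))
    for i in range(n_particles):
        H = int(rng.integers(0, 6))
        params = sample_prior(H, priors, rng)
        sims[i] = _simulate_summaries(params, initials, h0s, milestones, rng,
                                      targets=targets)
        rows.append({"H": H, **{c: getattr(params, c) for c in _PARAM_COLS}})
    pilot_sd = sims[: min(n_pilot, n_particles)].std(axis=0)
    # components that do not vary across particles (e.g. primordial
    # summaries, which are fixed by the starting states) carry no
    # information about the parameters and are excluded from the distance
    active = pilot_sd > 1e-9
    if not active.any():
        raise InsufficientDataError("no summary component varies across particles")
    dist = np.sqrt(
        (((sims[:, active] - obs[active]) / pilot_sd[active]) ** 2).sum(axis=1))
    particles = pd.DataFrame(rows)
    particles["distance"] = dist
    thresholds = np.quantile(dist, q)
    support_rows = []
    for quant, thr in zip(q, thresholds):
        acc = particles[particles["distance"] <= thr]
        if len(acc) == 0:
            for H in range(6):
                support_rows.append({"quantile": quant, "threshold": thr,
                                     "H": H, "support": np.nan, "n_accepted": 0})
            continue
        shares = acc["H"].value_counts(normalize=True)
        for H in range(6):
            support_rows.append({"quantile": quant, "threshold": thr, "H": H,
                                 "support": float(shares.get(H, 0.0)),
                                 "n_accepted": len(acc)})
    support = pd.DataFrame(support_rows)
    top = particles.nsmallest(top_k, "distance").reset_index(drop=True)
    return ABCResult(particles=particles, thresholds=thresholds,
                     threshold_quantiles=q, support=support, top_k=top,
                     priors=priors)


def posterior_summary(result: ABCResult, threshold: float, param: str,
                      H: int | None = None, level: float = 0.90):
    """Posterior moments and equal-tailed credible interval of a parameter.

    Computed over the particles accepted at ``threshold``, optionally
    restricted to one model.  Requires at least 10 acceptances.
    """
    acc = result.accepted(threshold)
    if H is not None:
        acc = acc[acc["H"] == H]
    if len(acc) < 10:
        raise InsufficientDataError(
            f"only {len(acc)} accepted particles at threshold {threshold}")
    v = acc[param].to_numpy(float)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(v, [alpha, 1.0 - alpha])
    return float(v.mean()), float(v.std(ddof=1)), (float(lo), float(hi))
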