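"""Synthetic single-cell heteroplasmy datasets.

Generates the three kinds of tables the analysis pipeline consumes,
with the statistical structure the real study designs assume:

* **oocyte tables** — per-mother primordial heteroplasmy drawn from a
  Kimura distribution around the maternal value (the germline
  bottleneck), primordial copy numbers from a log-normal law
  (natural-scale mean 347, SD 355.8), then forward-simulated through
  oocyte development under a chosen selection model to an antral target
  copy number (mean 1.41e5, SD 4.38e4), with snapshots at the
  intermediate follicle stages;
* **mother->pup transmission tables** — each pup is one cell carried to
  the antral endpoint (defaults 42 mothers, 1167 pups);
* **sperm tables** — 4N spermatocyte copy numbers around a configurable
  mean (default 772 total copies), partitioned binomially to 2N and 1N
  with no selection, so the meiosis model's neutral prediction is exact
  on this data by construction.

Measurement noise is additive Gaussian on the heteroplasmy fraction
(default SD 0.015, truncated to [0, 1]), emulating assay error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .kimura import KimuraParams, kimura_sample
from .meiosis_sim import partition
from .oocyte_sim import CellState, SimParams, cohort_finals

__all__ = ["SynthConfig", "gen_oocyte_dataset", "gen_transmission_table",
           "gen_sperm_dataset", "default_selection_params", "default_neutral_params"]


def default_selection_params(**overrides) -> SimParams:
    """Replication-advantage model with copy-number-dependent tolerance (H=5).

    Mutant birth rate 1.5x wild type; the cell tolerates heteroplasmy
    0.5 below w_th = 500 wild-type copies and 0.8 above.
    """
    kw = dict(lambda_m=0.6, lambda_w=0.4, R0=100, H=5,
              h_th1=0.5, h_th2=0.8, w_th=500)
    kw.update(overrides)
    return SimParams(**kw)


def default_neutral_params(**overrides) -> SimParams:
    """Pure neutral drift (H=4)."""
    kw = dict(lambda_m=0.5, lambda_w=0.5, R0=100, H=4)
    kw.update(overrides)
    return SimParams(**kw)


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of the synthetic generator.

    Copy-number laws are log-normal, parameterised by their
    natural-scale mean and SD (matched by moment transformation).
    """

    n_mothers: int = 42
    #: maternal reference heteroplasmy ~ Uniform(h0_lo, h0_hi)
    h0_lo: float = 0.2
    h0_hi: float = 0.8
    #: Kimura drift parameter of the prenatal bottleneck
    bottleneck_b: float = 0.98
    #: primordial copy-number law (natural-scale mean / SD)
    primordial_mean: float = 347.0
    primordial_sd: float = 355.8
    #: antral target copy-number law
    antral_mean: float = 141_000.0
    antral_sd: float = 43_800.0
    #: generating replication model; None = selection default (H=5)
    sim_params: SimParams | None = None
    #: oocyte table: cells measured per mother per stage
    cells_per_stage: int = 8
    #: transmission table: total pups spread as evenly as possible
    n_pups: int = 1167
    #: measurement noise SD on the heteroplasmy fraction
    noise_sd: float = 0.015
    #: sperm table: cells per ploidy class and 4N copy-number law
    sperm_cells_per_ploidy: int = 200
    sperm_total_mean: float = 772.0
    sperm_total_sd: float = 281.35
    sperm_h: float = 0.6

    def __post_init__(self):
        if self.n_mothers < 1 or self.n_pups < 1:
            raise InvalidParameterError("counts must be positive")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise SD must be >= 0")
        if not (0 < self.h0_lo <= self.h0_hi < 1):
            raise InvalidParameterError("need 0 < h0_lo <= h0_hi < 1")
        if not (0 < self.bottleneck_b <= 1):
            raise InvalidParameterError("bottleneck b must be in (0, 1]")

    @property
    def params(self) -> SimParams:
        return self.sim_params if self.sim_params is not None else default_selection_params()


def _lognormal(mean: float, sd: float, size, rng) -> np.ndarray:
    """Log-normal draws with the given *natural-scale* mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _noisy(h: np.ndarray, sd: float, rng) -> np.ndarray:
    if sd == 0:
        return h
    return np.clip(h + rng.normal(0.0, sd, size=np.shape(h)), 0.0, 1.0)


def _initial_states(h0: float, n: int, cfg: SynthConfig, rng):
    """Primordial cells of one mother: bottlenecked h + log-normal copies."""
    if cfg.bottleneck_b >= 1.0:
        hs = np.full(n, h0)
    else:
        hs = kimura_sample(KimuraParams(h0, cfg.bottleneck_b), n, rng)
    totals = np.maximum(1, np.round(_lognormal(
        cfg.primordial_mean, cfg.primordial_sd, n, rng))).astype(np.int64)
    m = np.round(hs * totals).astype(np.int64)
    return [CellState(int(a), int(t - a)) for a, t in zip(m, totals)]


def _mother_h0s(cfg: SynthConfig, rng) -> np.ndarray:
    if cfg.h0_lo == cfg.h0_hi:
        return np.full(cfg.n_mothers, cfg.h0_lo)
    return rng.uniform(cfg.h0_lo, cfg.h0_hi, cfg.n_mothers)


def gen_oocyte_dataset(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Single-oocyte records across follicle stages for every mother.

    Each mother contributes ``cells_per_stage`` independent cells per
    stage; a cell assigned to a given stage is simulated only up to that
    stage's copy-number milestone.  Columns: mouse_id, stage, h,
    copy_number, mother_h0.
    """
    params = cfg.params
    h0s = _mother_h0s(cfg, rng)
    rows = []
    # per-cell antral target drawn from the antral copy-number law
    for mi, h0 in enumerate(h0s):
        mouse = f"mouse{mi:03d}"
        # primordial cells: no forward simulation
        prim = _initial_states(h0, cfg.cells_per_stage, cfg, rng)
        for s in prim:
            rows.append((mouse, "primordial", s.h, s.n, h0))
        for stage in ("primary", "secondary", "antral"):
            initials = _initial_states(h0, cfg.cells_per_stage, cfg, rng)
            for s in initials:
                target = _stage_target(stage, cfg, params, rng)
                p = replace(params, N_final=target)
                _, am, aw, _ = cohort_finals([s], p, rng)
                m, w = int(am[0, -1]), int(aw[0, -1])
                rows.append((mouse, stage, m / (m + w), m + w, h0))
    df = pd.DataFrame(rows, columns=["mouse_id", "stage", "h", "copy_number",
                                     "mother_h0"])
    df["h"] = _noisy(df["h"].to_numpy(), cfg.noise_sd, rng)
    return df


def _stage_target(stage: str, cfg: SynthConfig, params: SimParams, rng) -> int:
    from .oocyte_sim import DEFAULT_MILESTONES
    if stage == "antral":
        t = _lognormal(cfg.antral_mean, cfg.antral_sd, None, rng)
        return int(max(2, round(float(t))))
    frac = DEFAULT_MILESTONES[stage] / 141_000.0
    return int(max(2, round(frac * min(cfg.antral_mean, params.N_final))))


def gen_transmission_table(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Mother->pup heteroplasmy pair table.

    Each pup is one bottlenecked cell carried through the full oocyte
    simulation to its antral target; maternal ages (months) are drawn
    uniformly on [2, 12].  Columns: mother_id, mother_h0, offspring_h,
    maternal_age.
    """
    params = cfg.params
    h0s = _mother_h0s(cfg, rng)
    base, extra = divmod(cfg.n_pups, cfg.n_mothers)
    rows = []
    for mi, h0 in enumerate(h0s):
        n_pups = base + (1 if mi < extra else 0)
        if n_pups == 0:
            continue
        initials = _initial_states(h0, n_pups, cfg, rng)
        targets = np.round(_lognormal(cfg.antral_mean, cfg.antral_sd, n_pups,
                                      rng)).astype(int)
        age = float(rng.uniform(2.0, 12.0))
        for s, target in zip(initials, targets):
            p = replace(params, N_final=int(max(2, target)))
            _, am, aw, _ = cohort_finals([s], p, rng)
            m, w = int(am[0, -1]), int(aw[0, -1])
            rows.append((f"mother{mi:03d}", h0, m / (m + w), age))
    df = pd.DataFrame(rows, columns=["mother_id", "mother_h0", "offspring_h",
                                     "maternal_age"])
    df["offspring_h"] = _noisy(df["offspring_h"].to_numpy(), cfg.noise_sd, rng)
    return df


def gen_sperm_dataset(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Meiotic male germ-cell records at 4N, 2N and 1N ploidy.

    4N totals are log-normal around the configured mean with binomial
    mutant counts at ``sperm_h``; 2N and 1N cells are produced by one
    and two symmetric partition steps — pure vegetative segregation.
    Columns: mouse_id, ploidy, m, w.
    """
    n = cfg.sperm_cells_per_ploidy
    rows = []
    for ploidy, steps in (("4N", 0), ("2N", 1), ("1N", 2)):
        totals = np.maximum(1, np.round(_lognormal(
            cfg.sperm_total_mean, cfg.sperm_total_sd, n, rng))).astype(np.int64)
        m = rng.binomial(totals, cfg.sperm_h).astype(np.int64)
        w = totals - m
        if steps:
            m, w = partition(m, w, steps, rng)
        for a, b in zip(m, w):
            rows.append(("mouseS", ploidy, int(a), int(b)))
    return pd.DataFrame(rows, columns=["mouse_id", "ploidy", "m", "w"])
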