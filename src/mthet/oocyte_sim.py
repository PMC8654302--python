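"""Stochastic mtDNA replication in non-dividing oocytes.

A cell holds ``m`` mutant and ``w`` wild-type mtDNA molecules.  At every
iteration a fixed-size subset of at most ``R0`` molecules replicates
(limited replication machinery); the number of mutant slots is drawn
binomially with the current heteroplasmy ``h = m/(m+w)`` as the success
probability, and each slot produces one new copy with per-type birth
probability ``lambda_m`` / ``lambda_w``.  Copy number only grows — there
is no degradation — and a cell is simulated until its total reaches
``N_final`` (the measured endpoint of oocyte development) or ``t_max``
iterations have elapsed.

Six selection hypotheses, indexed ``H = 0..5``, modulate the mutant
birth rate:

===  ==================================  ===================================
H    positive selection (lambda_m free)  negative selection (mutant births
                                         stop while the rule holds)
===  ==================================  ===================================
0    throughout                          h > h_th
1    none (lambda_m = lambda_w)          h > h_th
2    only after iteration T              h > h_th
3    only after iteration T              never
4    none (lambda_m = lambda_w)          never (pure neutral drift)
5    throughout                          h > h_th1 if w < w_th else h > h_th2
===  ==================================  ===================================

Model 5 ties tolerance of the mutant load to the absolute wild-type copy
number: with few wild-type molecules the cell shuts down mutant
replication at a low heteroplasmy threshold, with many it tolerates more.

The per-cell inner loop is JIT-compiled (numba); each cell gets an
independent sub-seed derived from the caller's generator, so cohorts are
reproducible and order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import EmptyInputError, ExtinctCellError, InvalidParameterError

__all__ = [
    "CellState",
    "SimParams",
    "Trajectory",
    "step",
    "simulate_cell",
    "simulate_cohort",
    "predict_transmission_curve",
    "DEFAULT_MILESTONES",
]

#: total-copy-number milestones at which stage snapshots are taken;
#: each is capped at the run's N_final (antral is N_final itself)
DEFAULT_MILESTONES = {"primary": 3_000, "secondary": 20_000}

_NEUTRAL_MODELS = (1, 4)  # lambda_m forced equal to lambda_w


@dataclass(frozen=True)
class CellState:
    """Integer mutant/wild-type mtDNA copy numbers of one cell."""

    m: int
    w: int

    def __post_init__(self):
        if self.m < 0 or self.w < 0:
            raise InvalidParameterError("copy numbers must be non-negative")

    @property
    def n(self) -> int:
        return self.m + self.w

    @property
    def h(self) -> float:
        """Heteroplasmy m/(m+w); undefined for an extinct cell."""
        if self.n == 0:
            raise ExtinctCellError("heteroplasmy undefined for m + w = 0")
        return self.m / self.n


@dataclass(frozen=True)
class SimParams:
    """Full parameter vector of the replication model plus run controls.

    lambda_m, lambda_w : per-slot birth probabilities per iteration, in [0, 1]
    R0                 : size of the replicating subset (molecules)
    h_th               : heteroplasmy threshold for negative selection (H in 0..2)
    T                  : iteration at which positive selection switches on (H in 2, 3)
    h_th1, h_th2       : low/high thresholds for H = 5 (h_th1 < h_th2)
    w_th               : wild-type copy number separating the two H = 5 regimes
    H                  : model indicator 0..5
    N_final            : target total copy number at which simulation stops
    t_max              : iteration cap; runs hitting it are flagged incomplete
    """

    lambda_m: float
    lambda_w: float
    R0: int
    H: int
    h_th: float = 0.8
    T: int = 0
    h_th1: float = 0.5
    h_th2: float = 0.8
    w_th: int = 500
    N_final: int = 141_000
    t_max: int = 5_000

    def __post_init__(self):
        if not (0 <= self.lambda_m <= 1 and 0 <= self.lambda_w <= 1):
            raise InvalidParameterError("lambda_m and lambda_w must lie in [0, 1]")
        if self.R0 < 1:
            raise InvalidParameterError("R0 must be a positive integer")
        if self.H not in range(6):
            raise InvalidParameterError("H must be one of 0..5")
        if not (0 < self.h_th <= 1):
            raise InvalidParameterError("h_th must lie in (0, 1]")
        if self.T < 0:
            raise InvalidParameterError("T must be non-negative")
        if not (0 < self.h_th1 < 1 and 0 < self.h_th2 < 1):
            raise InvalidParameterError("h_th1, h_th2 must lie in (0, 1)")
        if self.h_th1 >= self.h_th2:
            raise InvalidParameterError("h_th1 must be < h_th2")
        if self.w_th < 1:
            raise InvalidParameterError("w_th must be a positive integer")
        if self.N_final < 1 or self.t_max < 1:
            raise InvalidParameterError("N_final and t_max must be positive")
        if self.H in _NEUTRAL_MODELS and self.lambda_m != self.lambda_w:
            raise InvalidParameterError(
                f"model H={self.H} has no positive selection: lambda_m must "
                f"equal lambda_w (got {self.lambda_m} vs {self.lambda_w})"
            )

    def as_tuple(self) -> tuple:
        """Numeric parameter tuple in kernel argument order."""
        return (self.lambda_m, self.lambda_w, int(self.R0), self.h_th,
                int(self.T), self.h_th1, self.h_th2, int(self.w_th), int(self.H),
                int(self.N_final), int(self.t_max))


@dataclass
class Trajectory:
    """One simulated cell: per-iteration states and stage snapshots."""

    states: list[CellState] | None
    checkpoints: dict[str, CellState]
    params: SimParams
    seed: int
    t_end: int
    complete: bool

    @property
    def final(self) -> CellState:
        if self.states is not None:
            return self.states[-1]
        return self.checkpoints["antral"]


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _kernel_step(m, w, lam_m, lam_w, R0, h_th, T, h_th1, h_th2, w_th, H, t):
    n = m + w
    h = m / n
    slots = R0 if R0 < n else n
    # stochastic slot allocation with mutant share h, capped and rebalanced
    R_m = np.random.binomial(slots, h)
    if R_m > m:
        R_m = m
    R_w = slots - R_m
    if R_w > w:
        R_m = R_m + (R_w - w)
        if R_m > m:
            R_m = m
        R_w = w
    lam_m_eff = lam_m
    if H == 1 or H == 4:
        lam_m_eff = lam_w
    elif (H == 2 or H == 3) and t < T:
        lam_m_eff = lam_w
    suppress = False
    if H == 0 or H == 1 or H == 2:
        suppress = h > h_th
    elif H == 5:
        thr = h_th1 if w < w_th else h_th2
        suppress = h > thr
    if suppress:
        lam_m_eff = 0.0
    dm = np.random.binomial(R_m, lam_m_eff) if R_m > 0 and lam_m_eff > 0.0 else 0
    dw = np.random.binomial(R_w, lam_w) if R_w > 0 and lam_w > 0.0 else 0
    return m + dm, w + dw


@njit(cache=True)
def _kernel_simulate(m0, w0, lam_m, lam_w, R0, h_th, T, h_th1, h_th2, w_th, H,
                     n_final, t_max, seed, milestones):
    """Run one cell to n_final or t_max; snapshot at copy-number milestones.

    Returns (m, w, t_end, cp_m, cp_w) where cp_* hold the state at the
    first crossing of each milestone (-1 = never crossed).
    """
    np.random.seed(seed)
    m, w = m0, w0
    k = milestones.shape[0]
    cp_m = np.full(k, -1, np.int64)
    cp_w = np.full(k, -1, np.int64)
    for j in range(k):
        if m + w >= milestones[j]:
            cp_m[j] = m
            cp_w[j] = w
    t = 0
    while m + w < n_final and t < t_max:
        m, w = _kernel_step(m, w, lam_m, lam_w, R0, h_th, T, h_th1, h_th2,
                            w_th, H, t)
        t += 1
        for j in range(k):
            if cp_m[j] < 0 and m + w >= milestones[j]:
                cp_m[j] = m
                cp_w[j] = w
    return m, w, t, cp_m, cp_w


@njit(cache=True)
def _kernel_record(m0, w0, lam_m, lam_w, R0, h_th, T, h_th1, h_th2, w_th, H,
                   n_final, t_max, seed):
    """Like _kernel_simulate but records the full (m, w) sequence."""
    np.random.seed(seed)
    ms = np.empty(t_max + 1, np.int64)
    ws = np.empty(t_max + 1, np.int64)
    m, w = m0, w0
    ms[0] = m
    ws[0] = w
    t = 0
    while m + w < n_final and t < t_max:
        m, w = _kernel_step(m, w, lam_m, lam_w, R0, h_th, T, h_th1, h_th2,
                            w_th, H, t)
        t += 1
        ms[t] = m
        ws[t] = w
    return ms[: t + 1], ws[: t + 1], t


@njit(cache=True)
def _kernel_cohort(m0s, w0s, lam_m, lam_w, R0, h_th, T, h_th1, h_th2, w_th, H,
                   n_finals, t_max, seeds, milestones):
    """Whole cohort in one JIT call: finals + milestone snapshots per cell.

    ``n_finals`` holds one stopping copy number per cell, so biological
    variability of the endpoint can be simulated directly.
    """
    n = m0s.shape[0]
    k = milestones.shape[0]
    out_m = np.empty(n, np.int64)
    out_w = np.empty(n, np.int64)
    out_t = np.empty(n, np.int64)
    cp_m = np.empty((n, k), np.int64)
    cp_w = np.empty((n, k), np.int64)
    for c in range(n):
        m, w, t, cm, cw = _kernel_simulate(
            m0s[c], w0s[c], lam_m, lam_w, R0, h_th, T, h_th1, h_th2, w_th, H,
            n_finals[c], t_max, seeds[c], milestones)
        out_m[c] = m
        out_w[c] = w
        out_t[c] = t
        cp_m[c] = cm
        cp_w[c] = cw
    return out_m, out_w, out_t, cp_m, cp_w


# ---------------------------------------------------------------------------
# public API

def _check_alive(state: CellState):
    if state.n == 0:
        raise ExtinctCellError("cannot simulate a cell with m + w = 0")


def step(state: CellState, params: SimParams, t: int,
         rng: np.random.Generator) -> CellState:
    """One replication iteration (pure-numpy reference implementation).

    Mirrors the JIT kernel: allocate replication slots binomially by
    heteroplasmy, apply the model's positive/negative-selection rules to
    the mutant birth rate, then draw binomial birth counts.
    """
    _check_alive(state)
    if t < 0:
        raise InvalidParameterError("iteration index t must be >= 0")
    m, w = state.m, state.w
    n = m + w
    h = m / n
    slots = min(params.R0, n)
    R_m = int(rng.binomial(slots, h))
    if R_m > m:
        R_m = m
    R_w = slots - R_m
    if R_w > w:
        R_m = min(m, R_m + (R_w - w))
        R_w = w
    lam_m_eff = params.lambda_m
    if params.H in _NEUTRAL_MODELS:
        lam_m_eff = params.lambda_w
    elif params.H in (2, 3) and t < params.T:
        lam_m_eff = params.lambda_w
    if params.H in (0, 1, 2):
        suppress = h > params.h_th
    elif params.H == 5:
        suppress = h > (params.h_th1 if w < params.w_th else params.h_th2)
    else:
        suppress = False
    if suppress:
        lam_m_eff = 0.0
    dm = int(rng.binomial(R_m, lam_m_eff)) if R_m > 0 else 0
    dw = int(rng.binomial(R_w, params.lambda_w)) if R_w > 0 else 0
    return CellState(m + dm, w + dw)


def _kernel_args(params: SimParams) -> tuple:
    """Model parameters in kernel order, without the run controls."""
    return (params.lambda_m, params.lambda_w, int(params.R0), params.h_th,
            int(params.T), params.h_th1, params.h_th2, int(params.w_th),
            int(params.H))


def _milestone_arrays(params: SimParams, milestones: dict[str, int] | None):
    ms = dict(DEFAULT_MILESTONES) if milestones is None else dict(milestones)
    ms = {k: min(int(v), params.N_final) for k, v in ms.items()}
    ms["antral"] = params.N_final
    labels = sorted(ms, key=ms.get)
    values = np.array([ms[k] for k in labels], dtype=np.int64)
    return labels, values


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def simulate_cell(initial: CellState, params: SimParams,
                  rng: np.random.Generator,
                  milestones: dict[str, int] | None = None) -> Trajectory:
    """Simulate one cell to ``N_final`` copies, recording every iteration.

    The trajectory is flagged ``complete=False`` when ``t_max`` is hit
    before the target copy number.  Stage checkpoints snapshot the state
    at the first crossing of each copy-number milestone; ``primordial``
    is always the initial state.
    """
    _check_alive(initial)
    if initial.n > params.N_final:
        raise InvalidParameterError("initial copy number exceeds N_final")
    seed = _spawn_seed(rng)
    ms, ws_, t_end = _kernel_record(initial.m, initial.w, *params.as_tuple(), seed)
    states = [CellState(int(a), int(b)) for a, b in zip(ms, ws_)]
    labels, values = _milestone_arrays(params, milestones)
    totals = ms + ws_
    checkpoints = {"primordial": states[0]}
    for lab, v in zip(labels, values):
        idx = np.argmax(totals >= v)
        if totals[idx] >= v:
            checkpoints[lab] = states[int(idx)]
    complete = states[-1].n >= params.N_final
    return Trajectory(states=states, checkpoints=checkpoints, params=params,
                      seed=seed, t_end=int(t_end), complete=complete)


def simulate_cohort(initials: list[CellState], params: SimParams,
                    rng: np.random.Generator,
                    milestones: dict[str, int] | None = None,
                    record: str = "full") -> list[Trajectory]:
    """Independent trajectories for a list of cells.

    Per-cell seeds are drawn once from ``rng``, so results are
    reproducible and do not depend on evaluation order.  With
    ``record="checkpoints"`` the per-iteration history is dropped
    (memory-light path used by the inference machinery).
    """
    if not initials:
        raise EmptyInputError("empty cohort")
    for s in initials:
        _check_alive(s)
    if record == "full":
        return [simulate_cell(s, params, rng, milestones) for s in initials]
    if record != "checkpoints":
        raise ValueError(f"unknown record mode {record!r}")
    labels, values = _milestone_arrays(params, milestones)
    seeds = np.array([_spawn_seed(rng) for _ in initials], dtype=np.int64)
    m0s = np.array([s.m for s in initials], dtype=np.int64)
    w0s = np.array([s.w for s in initials], dtype=np.int64)
    n_finals = np.full(m0s.size, params.N_final, dtype=np.int64)
    fm, fw, ft, cp_m, cp_w = _kernel_cohort(
        m0s, w0s, *_kernel_args(params), n_finals, params.t_max, seeds, values)
    out = []
    for c in range(len(initials)):
        cps = {"primordial": initials[c]}
        for j, lab in enumerate(labels):
            if cp_m[c, j] >= 0:
                cps[lab] = CellState(int(cp_m[c, j]), int(cp_w[c, j]))
        cps.setdefault("antral", CellState(int(fm[c]), int(fw[c])))
        out.append(Trajectory(states=None, checkpoints=cps, params=params,
                              seed=int(seeds[c]), t_end=int(ft[c]),
                              complete=int(fm[c] + fw[c]) >= params.N_final))
    return out


def cohort_finals(initials, params: SimParams, rng: np.random.Generator,
                  milestones: dict[str, int] | None = None,
                  n_final_per_cell=None):
    """Fast path: (labels, cp_m, cp_w, complete) arrays for a cohort.

    ``cp_m``/``cp_w`` have one row per cell and one column per stage
    (primordial first, antral last); used by the ABC machinery where
    building Trajectory objects per particle would dominate runtime.

    ``n_final_per_cell`` makes the stopping copy number cell-specific
    (biological endpoint variability); the antral column is then the
    final state of each cell rather than a shared milestone crossing.
    """
    m0s = np.asarray([s.m for s in initials], dtype=np.int64)
    w0s = np.asarray([s.w for s in initials], dtype=np.int64)
    if m0s.size == 0:
        raise EmptyInputError("empty cohort")
    seeds = rng.integers(1, 2**31 - 1, size=m0s.size).astype(np.int64)
    if n_final_per_cell is None:
        labels, values = _milestone_arrays(params, milestones)
        n_finals = np.full(m0s.size, params.N_final, dtype=np.int64)
        targets = n_finals
    else:
        # intermediate milestones only; antral is each cell's own endpoint
        ms = dict(DEFAULT_MILESTONES) if milestones is None else dict(milestones)
        ms.pop("antral", None)
        labels = sorted(ms, key=ms.get)
        values = np.array([ms[k] for k in labels], dtype=np.int64)
        targets = np.asarray(n_final_per_cell, dtype=np.int64)
        if targets.shape != m0s.shape:
            raise InvalidParameterError("one stopping copy number per cell required")
        n_finals = targets
    fm, fw, ft, cp_m, cp_w = _kernel_cohort(
        m0s, w0s, *_kernel_args(params), n_finals, params.t_max, seeds, values)
    # prepend the initial state as the primordial column; missing (never
    # crossed) milestones fall back to the final state
    for j in range(len(labels)):
        miss = cp_m[:, j] < 0
        cp_m[miss, j] = fm[miss]
        cp_w[miss, j] = fw[miss]
    all_m = np.column_stack([m0s, cp_m])
    all_w = np.column_stack([w0s, cp_w])
    complete = (fm + fw) >= targets
    if n_final_per_cell is None:
        return ["primordial"] + labels, all_m, all_w, complete
    all_m = np.column_stack([all_m, fm])
    all_w = np.column_stack([all_w, fw])
    return ["primordial"] + labels + ["antral"], all_m, all_w, complete


def predict_transmission_curve(params_set: list[SimParams], initial_h_grid,
                               n_cells: int, rng: np.random.Generator,
                               initial_n: int = 347) -> pd.DataFrame:
    """Mean antral heteroplasmy vs initial heteroplasmy.

    For each grid value the cohort mean final heteroplasmy is computed
    under every accepted parametrization; the returned table holds the
    across-parametrization mean and SD per grid point (the SD is the
    model-uncertainty band).  Grid values of exactly 0 or 1 are dropped
    with a warning (fixed points of every model).
    """
    if not params_set:
        raise EmptyInputError("empty parametrization set")
    hs = [float(v) for v in initial_h_grid]
    kept = [v for v in hs if 0.0 < v < 1.0]
    if len(kept) < len(hs):
        warnings.warn("grid values at 0 or 1 excluded (degenerate fixation)")
    if {p.H for p in params_set} != {params_set[0].H}:
        raise InvalidParameterError("all parametrizations must share H")
    rows = []
    for h0 in kept:
        m0 = int(round(h0 * initial_n))
        m0 = min(max(m0, 1), initial_n - 1)
        initials = [CellState(m0, initial_n - m0)] * n_cells
        means = []
        for p in params_set:
            _, am, aw, _ = cohort_finals(initials, p, rng)
            hf = am[:, -1] / (am[:, -1] + aw[:, -1])
            means.append(hf.mean())
        means = np.array(means)
        rows.append({"initial_h": h0, "mean_final_h": float(means.mean()),
                     "sd_final_h": float(means.std(ddof=1)) if len(means) > 1 else 0.0})
    return pd.DataFrame(rows)
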