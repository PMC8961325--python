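"""Joint parameter estimation and absorptive/post-absorptive window scan.

Both interventions are fitted simultaneously.  The intervention coupling
is enforced *by construction*: the optimizer works on log10 of the GLC
rates plus log10 of the WP/GLC ratio for each rate, with the ratio
bounded in [0.1, 10] (symmetric); the protein-hydrolysis rate k_Pro
exists only for WP and is parameterized as k_GLY(WP) times a ratio with
the same bound.  No post-hoc clipping is ever needed.

The cost is the sum over interventions, modelled species and window
time points of squared residuals scaled by the across-subject standard
deviation — a chi-square-style weighted sum, kept exactly in that form
(no root, no mean; the monotone-equivalent of an RMS for ranking fits).

Optimization: differential evolution (best/1/bin, recombination 0.9,
compact population) configured to favor local search, followed by a
derivative-free Powell polish, restarted from independent seeds with the
overall best kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, least_squares

from .model import (
    STATE_SPECIES,
    InputCurves,
    RateParameterSet,
    ScalingSchedule,
    SimulationError,
    simulate,
)

logger = logging.getLogger(__name__)

#: rates shared by both interventions, in theta order
FIT_RATE_NAMES = (
    "k_GLY", "k_LDHf", "k_LDHb", "k_ALTf", "k_ALTb", "k_TCA",
    "d_pyr", "d_lac", "d_ala", "d_cit",
)
N_SHARED = len(FIT_RATE_NAMES)
N_THETA = 2 * N_SHARED + 1  # GLC logs, WP/GLC log-ratios, k_Pro/k_GLY log-ratio

DEFAULT_SPLIT_CANDIDATES = (75.0, 90.0, 105.0, 120.0, 150.0)


@dataclass
class _InterventionData:
    inputs: InputCurves
    times: np.ndarray  # observation times within the window, incl. window start
    y: np.ndarray  # (n_times, 4) measured blood means, STATE_SPECIES order
    sigma: np.ndarray  # matching SDs (floored upstream)
    initial: np.ndarray  # intracellular state at window start
    scale: np.ndarray  # blood/intracellular factor at the observation times


@dataclass
class FitProblem:
    """Window, data and constraints for one joint two-intervention fit."""

    window: tuple[float, float]
    schedule: ScalingSchedule
    log_bounds: tuple[float, float] = (-5.0, 1.0)
    ratio_bounds: tuple[float, float] = (0.1, 10.0)
    initial_policy: str = "zero"  # or "from_data"
    data: dict[str, _InterventionData] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.ratio_bounds
        if not np.isclose(lo * hi, 1.0):
            raise ValueError("ratio bounds must be symmetric (lo * hi = 1)")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede window end")

    @property
    def theta_bounds(self) -> list[tuple[float, float]]:
        lr = np.log10(self.ratio_bounds[1])
        return [self.log_bounds] * N_SHARED + [(-lr, lr)] * (N_SHARED + 1)


def unpack_theta(theta: np.ndarray) -> dict[str, RateParameterSet]:
    """Map an optimizer vector to per-intervention rate sets."""
    theta = np.asarray(theta, dtype=float)
    glc = 10.0 ** theta[:N_SHARED]
    wp = glc * 10.0 ** theta[N_SHARED : 2 * N_SHARED]
    glc_d = dict(zip(FIT_RATE_NAMES, glc), k_Pro=0.0)
    wp_d = dict(zip(FIT_RATE_NAMES, wp))
    wp_d["k_Pro"] = wp_d["k_GLY"] * 10.0 ** theta[2 * N_SHARED]
    return {"GLC": RateParameterSet(**glc_d), "WP": RateParameterSet(**wp_d)}


def pack_theta(params: dict[str, RateParameterSet]) -> np.ndarray:
    """Inverse of :func:`unpack_theta` (k_Pro of GLC is ignored)."""
    glc = np.array([getattr(params["GLC"], n) for n in FIT_RATE_NAMES])
    wp = np.array([getattr(params["WP"], n) for n in FIT_RATE_NAMES])
    theta = np.concatenate(
        [np.log10(glc), np.log10(wp / glc), [np.log10(params["WP"].k_Pro / params["WP"].k_GLY)]]
    )
    return theta


def make_fit_problem(
    model_ds: pd.DataFrame,
    window: tuple[float, float],
    schedule: ScalingSchedule = ScalingSchedule(),
    log_bounds: tuple[float, float] = (-5.0, 1.0),
    ratio_bounds: tuple[float, float] = (0.1, 10.0),
    initial_policy: str = "zero",
) -> FitProblem:
    """Assemble a :class:`FitProblem` from a reduced model dataset.

    ``initial_policy='from_data'`` starts the simulation from the
    measured blood values at the window start divided by s(start) —
    the policy used for late windows, which are fitted separately from
    the early ones.
    """
    problem = FitProblem(
        window=tuple(window), schedule=schedule, log_bounds=tuple(log_bounds),
        ratio_bounds=tuple(ratio_bounds), initial_policy=initial_policy,
    )
    w0, w1 = problem.window
    for iv, sub in model_ds.groupby("intervention", sort=False):
        wide = sub.pivot_table(index="time_min", columns="species", values="mean_uM")
        sds = sub.pivot_table(index="time_min", columns="species", values="sd_uM")
        inputs = InputCurves(
            times=wide.index.to_numpy(),
            glc=wide["glucose_M6"].to_numpy(),
            pro=wide["protein"].to_numpy(),
        )
        mask = (wide.index >= w0) & (wide.index <= w1)
        times = wide.index.to_numpy()[mask]
        if times.size == 0 or times[0] != w0:
            raise ValueError(f"no observation at window start t={w0} for {iv}")
        y = wide.loc[mask, list(STATE_SPECIES)].to_numpy()
        sigma = sds.loc[mask, list(STATE_SPECIES)].to_numpy()
        if initial_policy == "zero":
            initial = np.zeros(4)
        elif initial_policy == "from_data":
            initial = y[0] / schedule.factor(w0)
        else:
            raise ValueError(f"unknown initial policy {initial_policy!r}")
        problem.data[iv] = _InterventionData(
            inputs=inputs, times=times, y=y, sigma=sigma,
            initial=initial, scale=schedule.factor(times),
        )
    if not problem.data:
        raise ValueError("model dataset holds no interventions")
    return problem


def cost(problem: FitProblem, params: dict[str, RateParameterSet]) -> float:
    """Weighted sum of squared residuals over interventions and species."""
    total = 0.0
    for iv, d in problem.data.items():
        try:
            traj = simulate(params[iv], d.inputs, d.initial, d.times, method="expm")
        except (SimulationError, ValueError) as exc:
            logger.warning("simulation failed during cost evaluation: %s", exc)
            return np.inf
        pred = traj.states * d.scale[:, None]
        total += float(np.sum(((d.y - pred) / d.sigma) ** 2))
    return total


def cost_theta(theta: np.ndarray, problem: FitProblem) -> float:
    try:
        params = unpack_theta(theta)
    except ValueError:
        return np.inf
    return cost(problem, params)


def residuals_theta(theta: np.ndarray, problem: FitProblem) -> np.ndarray:
    """Stacked sigma-scaled residual vector (cost = sum of its squares)."""
    params = unpack_theta(theta)
    parts = []
    for iv, d in problem.data.items():
        try:
            traj = simulate(params[iv], d.inputs, d.initial, d.times, method="expm")
        except (SimulationError, ValueError):
            return np.full(sum(v.y.size for v in problem.data.values()), 1e6)
        pred = traj.states * d.scale[:, None]
        parts.append(((d.y - pred) / d.sigma).ravel())
    return np.concatenate(parts)


@dataclass
class FitResult:
    """Best joint fit over all restarts."""

    params: dict[str, RateParameterSet]
    theta: np.ndarray
    cost: float
    restart_costs: list[float]
    window: tuple[float, float]
    seed: int | None
    diagnostics: dict = field(default_factory=dict)


def fit_joint(
    problem: FitProblem,
    n_restarts: int = 50,
    seed: int | None = None,
    maxiter: int = 150,
    pop_size: int = 60,
    tol: float = 1e-8,
    polish: bool = True,
    deep_polish: bool = True,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Differential-evolution fit, best of ``n_restarts`` restarts.

    ``x0`` optionally warm-starts every restart's population with a
    known-good parameter vector (used by the window scan to seed window
    fits with the whole-window optimum).  After the restarts, the best
    point gets one long least-squares refinement (``deep_polish``): the
    cost surface has long, gently sloped valleys along weakly identified
    rate combinations that a capped per-restart polish cannot descend.
    Deterministic for fixed seed.
    """
    bounds = problem.theta_bounds
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    obj = lambda th: cost_theta(th, problem)

    children = np.random.SeedSequence(seed).spawn(n_restarts)
    best_theta, best_cost = None, np.inf
    restart_costs: list[float] = []
    failures: list[str] = []
    for ss in children:
        rng = np.random.default_rng(ss)
        init = rng.uniform(lo, hi, size=(pop_size, len(bounds)))
        if x0 is not None:
            init[0] = np.clip(x0, lo, hi)
        try:
            res = differential_evolution(
                obj, bounds, init=init, strategy="best1bin", maxiter=maxiter,
                tol=tol, mutation=(0.5, 1.0), recombination=0.9,
                seed=rng, polish=False, updating="immediate",
            )
            th, c = res.x, float(res.fun)
            if polish:
                # the cost is a sum of squares, so a bounded trust-region
                # least-squares refinement drills into the local optimum
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pol = least_squares(
                        residuals_theta, np.clip(th, lo, hi), args=(problem,),
                        bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12,
                        max_nfev=400,
                    )
                c_pol = float(2 * pol.cost)  # least_squares cost is 0.5*sum(r^2)
                if np.isfinite(c_pol) and c_pol < c:
                    th, c = pol.x, c_pol
        except Exception as exc:  # noqa: BLE001 - per-restart diagnostics
            failures.append(str(exc))
            restart_costs.append(np.inf)
            continue
        restart_costs.append(c)
        if c < best_cost:
            best_theta, best_cost = th, c
    if best_theta is None:
        raise RuntimeError(f"all {n_restarts} restarts failed: {failures}")
    if deep_polish:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pol = least_squares(
                residuals_theta, np.clip(best_theta, lo, hi), args=(problem,),
                bounds=(lo, hi), method="trf", xtol=1e-15, ftol=1e-15,
                max_nfev=5000,
            )
        if np.isfinite(pol.cost) and 2 * pol.cost < best_cost:
            best_theta, best_cost = pol.x, float(2 * pol.cost)
    return FitResult(
        params=unpack_theta(best_theta), theta=np.asarray(best_theta),
        cost=best_cost, restart_costs=restart_costs, window=problem.window,
        seed=seed, diagnostics={"n_failures": len(failures), "failures": failures},
    )


@dataclass
class SplitReport:
    """Outcome of the absorptive/post-absorptive window scan."""

    candidates: tuple[float, ...]
    whole_cost: float
    early_costs: dict[float, float]
    late_costs: dict[float, float]
    sums: dict[float, float]
    sanity: dict[float, bool]  # two-window sum not worse than whole-window cost
    selected: float
    skipped: dict[float, str]
    whole_fit: FitResult | None = None
    window_fits: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            if c in self.skipped:
                rows.append((c, np.nan, np.nan, np.nan, False, self.skipped[c]))
            else:
                rows.append(
                    (c, self.early_costs[c], self.late_costs[c], self.sums[c],
                     self.sanity[c], "selected" if c == self.selected else "")
                )
        return pd.DataFrame(
            rows, columns=["split_min", "early_cost", "late_cost", "sum_cost",
                           "sanity_ok", "note"],
        )


def scan_splits(
    model_ds: pd.DataFrame,
    schedule: ScalingSchedule = ScalingSchedule(),
    candidates: tuple[float, ...] = DEFAULT_SPLIT_CANDIDATES,
    whole_window: tuple[float, float] = (0.0, 360.0),
    n_restarts: int = 50,
    seed: int | None = None,
    tie_tol: float = 1e-6,
    min_points: int = 4,
    **fit_kwargs,
) -> SplitReport:
    """Scan candidate absorptive/post-absorptive split points.

    The whole window is fitted once; each candidate split is then fitted
    as two independent windows (late window initialized from the data at
    the split) warm-started from the whole-window optimum.  A candidate
    is sane when its two-window cost sum does not exceed the whole-window
    cost; the split with the lowest sum wins, ties (within ``tie_tol``
    relative) resolved toward the earliest candidate.
    """
    # the scan only ranks window costs against each other, so the long
    # final refinement is skipped by default for consistent comparisons
    fit_kwargs.setdefault("deep_polish", False)
    times = np.unique(model_ds["time_min"].to_numpy(dtype=float))
    ss = np.random.SeedSequence(seed).spawn(2 * len(candidates) + 1)
    seeds = iter(int(s.generate_state(1)[0] >> 1) for s in ss)

    whole_problem = make_fit_problem(
        model_ds, whole_window, schedule, initial_policy="zero"
    )
    whole = fit_joint(whole_problem, n_restarts=n_restarts, seed=next(seeds), **fit_kwargs)

    early_costs, late_costs, sums, sanity, skipped = {}, {}, {}, {}, {}
    window_fits = {}
    for c in candidates:
        if not (whole_window[0] < c < whole_window[1]):
            skipped[c] = "outside data range"
            continue
        n_early = int(np.sum((times >= whole_window[0]) & (times <= c)))
        n_late = int(np.sum((times >= c) & (times <= whole_window[1])))
        if n_early < min_points or n_late < min_points:
            skipped[c] = f"too few points (early={n_early}, late={n_late})"
            logger.info("skipping split %s: %s", c, skipped[c])
            continue
        early_p = make_fit_problem(
            model_ds, (whole_window[0], c), schedule, initial_policy="zero"
        )
        late_p = make_fit_problem(
            model_ds, (c, whole_window[1]), schedule, initial_policy="from_data"
        )
        early = fit_joint(early_p, n_restarts=n_restarts, seed=next(seeds),
                          x0=whole.theta, **fit_kwargs)
        late = fit_joint(late_p, n_restarts=n_restarts, seed=next(seeds),
                         x0=whole.theta, **fit_kwargs)
        early_costs[c], late_costs[c] = early.cost, late.cost
        sums[c] = early.cost + late.cost
        sanity[c] = sums[c] <= whole.cost * (1 + 1e-9)
        window_fits[c] = {"early": early, "late": late}
    if not sums:
        raise RuntimeError("no viable split candidate")
    best = min(sums.values())
    viable = [c for c in candidates if c in sums and sums[c] <= best * (1 + tie_tol)]
    if len(viable) > 1:
        logger.info("split tie within tolerance among %s; selecting earliest", viable)
    selected = viable[0]
    return SplitReport(
        candidates=tuple(candidates), whole_cost=whole.cost,
        early_costs=early_costs, late_costs=late_costs, sums=sums,
        sanity=sanity, selected=selected, skipped=skipped,
        whole_fit=whole, window_fits=window_fits,
    )
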