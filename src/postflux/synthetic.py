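"""Synthetic postprandial labeling studies with known ground truth.

Emulates the crossover study design: two interventions (a glucose drink,
GLC, and a wheat porridge, WP, both carrying 2% uniformly 13C-labeled
carbohydrate), 11 subjects, 3 technical replicates, 19 sampling times
from -60 to 360 min.  Ground-truth kinetics switch abruptly between an
absorptive (early) and a post-absorptive (late) parameter set, and the
generator emits the same tidy table the preprocessing stage consumes, so
every downstream stage can be tested against known rates and fluxes.

Exogenous input curves use a scaled gamma-density shape: zero before
ingestion, a single interior peak, then decay — the qualitative shape of
measured postprandial glucose M6 and protein-derived amino acid curves.
The WP intervention additionally carries a protein pool made of four
fully labeled amino acid isotopologues (glutamate M5, glutamine M5,
valine M5, threonine M4) in fixed proportions, so the protein-pool
reconstruction of the preprocessing stage is exercised end to end.

Noise model: per-replicate multiplicative Gaussian (truncated at zero)
with a stated CV, per-subject lognormal multipliers on every rate, and a
small absolute baseline noise for pre-ingestion samples.  The measured
SEM bands of real data motivate the multiplicative form; no specific
noise law is claimed for the real assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    INPUT_SPECIES,
    STATE_SPECIES,
    InputCurves,
    RateParameterSet,
    ScalingSchedule,
    simulate,
    to_blood,
)

INTERVENTIONS = ("GLC", "WP")

DEFAULT_SAMPLING_TIMES = (
    -60.0, -30.0, -5.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0,
    120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 300.0, 330.0, 360.0,
)

#: amino-acid isotopologues composing the protein pool, with the mol%
#: weights used to reconstruct it and the fixed fractions by which the
#: generator splits the pool into its components
PROTEIN_COMPONENTS = ("glutamate_M5", "glutamine_M5", "valine_M5", "threonine_M4")
PROTEIN_COMPONENT_FRACTIONS = (0.50, 0.25, 0.15, 0.10)

CSV_COLUMNS = (
    "subject", "intervention", "replicate", "time_min",
    "metabolite", "isotopologue", "concentration_uM",
)

#: rough physiological total-pool sizes (uM) used only to cap noiseless
#: tracer signal at (tracer fraction) x (pool ceiling)
DEFAULT_POOL_CEILINGS = {
    "glucose_M6": 10_000.0,
    "pyruvate_M3": 250.0,
    "lactate_M3": 3_000.0,
    "alanine_M3": 600.0,
    "citrate_M2": 200.0,
    "protein": 400.0,
}


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout and tracer dose of the intervention study."""

    interventions: tuple[str, ...] = INTERVENTIONS
    n_subjects: int = 11
    n_replicates: int = 3
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    tracer_fraction: float = 0.02
    carbohydrate_g: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.tracer_fraction <= 1):
            raise ValueError("tracer fraction must be in (0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if list(self.sampling_times) != sorted(self.sampling_times):
            raise ValueError("sampling times must be sorted")

    @property
    def post_times(self) -> np.ndarray:
        return np.array([t for t in self.sampling_times if t > 0], dtype=float)


@dataclass(frozen=True)
class CurveShape:
    """Scaled gamma-density input curve: peak ``height`` at ``peak_time``.

    c(t) = height * (t/peak_time)**shape * exp(shape * (1 - t/peak_time))
    for t > 0, zero otherwise.  ``shape`` controls rise/decay width.
    """

    peak_time: float
    height: float
    shape: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.peak_time < 360):
            raise ValueError("peak time must lie in (0, 360) min")
        if self.height < 0:
            raise ValueError("curve height must be >= 0")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = np.clip(t / self.peak_time, 0.0, None)
        with np.errstate(invalid="ignore"):
            v = self.height * x**self.shape * np.exp(self.shape * (1.0 - x))
        return np.where(t <= 0, 0.0, v)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator needs, and recovery tests compare against."""

    rates: dict  # {intervention: {"early": RateParameterSet, "late": ...}}
    glc_curves: dict  # {intervention: CurveShape} for glucose M6
    pro_curves: dict  # {intervention: CurveShape | None} protein pool
    schedule: ScalingSchedule = field(default_factory=ScalingSchedule)
    switch_time: float = 90.0
    replicate_cv: float = 0.10
    subject_sd: float = 0.15  # lognormal sigma of per-subject rate multipliers
    baseline_sd: float = 0.02  # uM, absolute noise of pre-ingestion samples
    pool_ceilings: dict = field(default_factory=lambda: dict(DEFAULT_POOL_CEILINGS))

    def __post_init__(self) -> None:
        if not (0 < self.switch_time < 360):
            raise ValueError("window switch time must lie in (0, 360) min")
        for iv, curve in self.pro_curves.items():
            if iv == "GLC" and curve is not None and curve.height != 0:
                raise ValueError("GLC carries no protein input")
            if iv == "WP" and (curve is None or curve.height <= 0):
                raise ValueError("WP requires a nonzero protein curve")


def default_ground_truth(**overrides) -> GroundTruth:
    """Study-shaped default truth.

    Rate magnitudes are chosen so the implied fluxes (k x substrate
    concentration x 50) land in the low-to-mid uM/min range typical of
    postprandial central carbon metabolism, and so that every WP/GLC rate
    ratio lies inside the [0.1, 10] fitting constraint.
    """
    glc_early = RateParameterSet(
        k_GLY=0.010, k_LDHf=0.50, k_LDHb=0.08, k_ALTf=0.45, k_ALTb=0.15,
        k_TCA=0.07, k_Pro=0.0, d_pyr=0.02, d_lac=0.05, d_ala=0.10, d_cit=0.06,
    )
    wp_early = glc_early.scaled(
        {"k_GLY": 0.75, "k_LDHf": 2.0, "k_LDHb": 2.0, "k_ALTf": 1.5,
         "k_ALTb": 2.5, "k_TCA": 1.8, "d_pyr": 1.5, "d_lac": 1.5,
         "d_ala": 1.2, "d_cit": 1.5}
    )
    wp_early = RateParameterSet(**{**wp_early.as_dict(), "k_Pro": 0.6 * wp_early.k_GLY})
    glc_late = glc_early.scaled(
        {"k_GLY": 0.05, "k_LDHf": 0.6, "k_LDHb": 0.8, "k_ALTf": 0.2,
         "k_ALTb": 0.3, "k_TCA": 0.5, "d_pyr": 2.0, "d_lac": 1.5,
         "d_ala": 0.8, "d_cit": 0.8}
    )
    wp_late = glc_late.scaled(
        {"k_GLY": 8.0, "k_LDHf": 2.0, "k_LDHb": 2.0, "k_ALTf": 1.5,
         "k_ALTb": 1.5, "k_TCA": 1.5, "d_pyr": 3.0, "d_lac": 3.0,
         "d_ala": 1.5, "d_cit": 1.5}
    )
    wp_late = RateParameterSet(**{**wp_late.as_dict(), "k_Pro": 0.5 * wp_late.k_GLY})
    kwargs = dict(
        rates={
            "GLC": {"early": glc_early, "late": glc_late},
            "WP": {"early": wp_early, "late": wp_late},
        },
        glc_curves={
            "GLC": CurveShape(peak_time=60.0, height=80.0, shape=3.0),
            "WP": CurveShape(peak_time=75.0, height=70.0, shape=2.5),
        },
        pro_curves={
            "GLC": None,
            "WP": CurveShape(peak_time=100.0, height=2.0, shape=3.0),
        },
    )
    kwargs.update(overrides)
    return GroundTruth(**kwargs)


def make_input_curves(
    glc_shape: CurveShape, design: StudyDesign, pro_shape: CurveShape | None = None
) -> InputCurves:
    """Evaluate input-curve shapes on the design's (post-ingestion) grid.

    The grid is the sampling schedule restricted to t >= 0 with an
    explicit t=0 anchor, so that linear interpolation of the returned
    curves matches how measured drivers are fed to the model.
    """
    grid = np.concatenate([[0.0], design.post_times])
    glc = glc_shape(grid)
    pro = pro_shape(grid) if pro_shape is not None else np.zeros_like(grid)
    return InputCurves(times=grid, glc=glc, pro=pro)


def _noiseless_blood_curves(
    truth: GroundTruth, design: StudyDesign, intervention: str,
    rate_multipliers: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Noise-free blood-side species curves on the post-ingestion grid."""
    inputs = make_input_curves(
        truth.glc_curves[intervention], design, truth.pro_curves[intervention]
    )
    early = truth.rates[intervention]["early"]
    late = truth.rates[intervention]["late"]
    if rate_multipliers:
        early = early.scaled(rate_multipliers)
        late = late.scaled(rate_multipliers)

    sw = truth.switch_time
    grid = np.concatenate([[0.0], design.post_times])
    pre = grid[grid <= sw]
    if pre[-1] != sw:
        pre = np.append(pre, sw)
    traj_early = simulate(early, inputs, np.zeros(4), pre, method="expm")
    post = grid[grid >= sw]
    if post[0] != sw:
        post = np.insert(post, 0, sw)
    traj_late = simulate(late, inputs, traj_early.states[-1], post, method="expm")

    states = {}
    for i, sp in enumerate(STATE_SPECIES):
        vals = np.interp(grid, traj_early.times, traj_early.states[:, i])
        late_mask = grid >= sw
        vals[late_mask] = np.interp(grid[late_mask], traj_late.times, traj_late.states[:, i])
        states[sp] = vals
    s = truth.schedule.factor(grid)
    rows = {sp: v * s for sp, v in states.items()}
    rows["glucose_M6"] = inputs.glc_at(grid)
    rows["protein"] = inputs.pro_at(grid)
    return pd.DataFrame({"time_min": grid, **rows})


def noiseless_model_curves(truth: GroundTruth, design: StudyDesign) -> pd.DataFrame:
    """Tidy noise-free blood curves for all interventions (for oracles)."""
    frames = []
    for iv in design.interventions:
        df = _noiseless_blood_curves(truth, design, iv)
        long = df.melt("time_min", var_name="species", value_name="concentration_uM")
        long.insert(0, "intervention", iv)
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def simulate_study(truth: GroundTruth, design: StudyDesign, seed: int) -> pd.DataFrame:
    """Generate a full raw replicate-level dataset (tidy CSV dialect).

    Deterministic for a fixed seed.  Pre-ingestion samples are pure
    baseline noise truncated at zero; amino-acid isotopologues are fixed
    fractions of the protein curve so the protein-pool reconstruction is
    exercised; all noise is multiplicative Gaussian truncated at zero.
    """
    rng = np.random.default_rng(seed)
    times = np.array(design.sampling_times, dtype=float)
    post_mask = times > 0
    records = []
    for iv in design.interventions:
        for subj in range(1, design.n_subjects + 1):
            if truth.subject_sd > 0:
                mult = {
                    name: float(np.exp(rng.normal(0.0, truth.subject_sd)))
                    for name in RateParameterSet.__dataclass_fields__
                }
            else:
                mult = None
            curves = _noiseless_blood_curves(truth, design, iv, mult)
            species_truth = {}
            for sp in STATE_SPECIES + INPUT_SPECIES:
                v = np.zeros_like(times)
                v[post_mask] = np.interp(
                    times[post_mask], curves["time_min"], curves[sp]
                )
                species_truth[sp] = v
            # split the protein pool into its amino-acid components so
            # that the mol%-weighted reconstruction returns it exactly
            pro = species_truth.pop("protein")
            denom_scale = (31.9 + 5.4 + 2.8) / 100.0
            for comp, frac in zip(PROTEIN_COMPONENTS, PROTEIN_COMPONENT_FRACTIONS):
                species_truth[comp] = pro * denom_scale * frac
            for sp, v in species_truth.items():
                for rep in range(1, design.n_replicates + 1):
                    noisy = v * (1.0 + truth.replicate_cv * rng.standard_normal(v.size))
                    base = truth.baseline_sd * rng.standard_normal(v.size)
                    noisy = np.where(v > 0, noisy, base)
                    noisy = np.clip(noisy, 0.0, None)
                    met, iso = sp.rsplit("_", 1) if "_" in sp else (sp, "")
                    for t, c in zip(times, noisy):
                        records.append(
                            (f"S{subj:02d}", iv, rep, t, met, iso, c)
                        )
    return pd.DataFrame.from_records(records, columns=CSV_COLUMNS)


def inject_outliers(
    data: pd.DataFrame, fraction: float, magnitude: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multiply a random subset of measurements by ``magnitude``.

    Returns the corrupted copy together with an injection log (row
    index, original and corrupted value) so filter sensitivity can be
    scored exactly.
    """
    if not (0 <= fraction <= 0.2):
        raise ValueError("outlier fraction must lie in [0, 0.2]")
    if magnitude <= 1:
        raise ValueError("outlier magnitude must exceed 1")
    out = data.copy()
    n = int(round(fraction * len(out)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(out), size=n, replace=False) if n else np.array([], dtype=int)
    idx = np.sort(idx)
    log = out.iloc[idx][list(CSV_COLUMNS)].copy()
    log["original_uM"] = log["concentration_uM"]
    log["corrupted_uM"] = log["concentration_uM"] * magnitude
    log["row"] = idx
    out.iloc[idx, out.columns.get_loc("concentration_uM")] *= magnitude
    return out, log.reset_index(drop=True)
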