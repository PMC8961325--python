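"""Reduction of raw replicate-level isotopologue data to the model dataset.

The raw table holds one row per (subject, intervention, replicate, time,
metabolite, isotopologue) with an absolute labeled-isotopologue
concentration in uM.  Preprocessing (i) removes outliers beyond 1.5xIQR
within each (intervention, time, metabolite, isotopologue) group,
(ii) collapses technical replicates to their median per subject,
(iii) reconstructs the dietary protein pool from four fully labeled
amino-acid isotopologues weighted by their mol% abundance in wheat
gluten, (iv) subtracts the pre-ingestion baseline, and (v) averages
across subjects into mean +/- SD curves per intervention and species —
the quantities the fitting cost consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import INPUT_SPECIES, STATE_SPECIES

GROUP_COLS = ("intervention", "time_min", "metabolite", "isotopologue")

MODEL_SPECIES = STATE_SPECIES + INPUT_SPECIES  # fitted + driver species

#: amino-acid isotopologues feeding the protein-pool reconstruction
PROTEIN_COMPONENTS = ("glutamate_M5", "glutamine_M5", "valine_M5", "threonine_M4")


@dataclass(frozen=True)
class ProteinComposition:
    """Mol% abundances normalising the protein-pool sum.

    The printed denominator has three terms for four isotopologues; it
    is kept exactly as printed and is configurable.
    """

    mol_percent: tuple[float, ...] = (31.9, 5.4, 2.8)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.mol_percent):
            raise ValueError("mol% abundances must be > 0")

    @property
    def denominator(self) -> float:
        return float(sum(self.mol_percent))


def isotopologue_concentration(enrichment: float, total_uM: float) -> float:
    """Absolute labeled concentration = enrichment fraction x total pool."""
    if not (0 <= enrichment <= 1):
        raise ValueError("enrichment fraction must lie in [0, 1]")
    if total_uM < 0:
        raise ValueError("total concentration must be >= 0")
    return enrichment * total_uM


def protein_pool(glu_M5, gln_M5, val_M5, thr_M4, comp: ProteinComposition = ProteinComposition()):
    """Protein pool (uM) = (Glu M5 + Gln M5 + Val M5 + Thr M4) * 100 / mol%."""
    parts = [np.asarray(v, dtype=float) for v in (glu_M5, gln_M5, val_M5, thr_M4)]
    if any(np.any(p < 0) for p in parts):
        raise ValueError("amino-acid isotopologue concentrations must be >= 0")
    return (parts[0] + parts[1] + parts[2] + parts[3]) * 100.0 / comp.denominator


def contribution_percent(c_iso: float, c_met: float, tracer_fraction: float = 0.02) -> float:
    """Percent of a plasma pool derived from the labeled food.

    c_iso / c_met, rescaled by the inverse tracer fraction (x50 for 2%
    labeling) and expressed in percent.
    """
    if c_met <= 0:
        raise ValueError("total metabolite concentration must be > 0")
    if c_iso < 0:
        raise ValueError("isotopologue concentration must be >= 0")
    return c_iso / c_met * (1.0 / tracer_fraction) * 100.0


def remove_outliers_iqr(
    data: pd.DataFrame,
    group_cols: tuple[str, ...] = GROUP_COLS,
    factor: float = 1.5,
    min_group_size: int = 4,
    value_col: str = "concentration_uM",
    max_passes: int | None = None,
    quartile_method: str = "linear",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] within groups.

    Quartiles use the linear-interpolation convention by default
    (``quartile_method`` accepts any numpy percentile method and is
    recorded in the log).  Fences are
    recomputed and the filter reapplied until no value is removed (or
    ``max_passes`` is reached), so the operation is a projection:
    applying it to its own output changes nothing.  Groups smaller than
    ``min_group_size`` pass through unfiltered (logged).  Returns the
    filtered table and a log of removals / skipped groups per pass.
    """
    out = data
    log_rows: list[tuple] = []
    n_pass = 0
    while max_passes is None or n_pass < max_passes:
        n_pass += 1
        keep = np.ones(len(out), dtype=bool)
        removed_any = False
        for key, idx in out.groupby(list(group_cols), sort=False).groups.items():
            vals = out.loc[idx, value_col].to_numpy(dtype=float)
            if len(vals) < min_group_size:
                if n_pass == 1:
                    log_rows.append(
                        (*key, np.nan, np.nan, np.nan, "group_too_small",
                         len(vals), n_pass)
                    )
                continue
            q1, q3 = np.percentile(vals, [25, 75], method=quartile_method)
            lo, hi = q1 - factor * (q3 - q1), q3 + factor * (q3 - q1)
            bad = (vals < lo) | (vals > hi)
            if bad.any():
                removed_any = True
                keep[out.index.get_indexer(idx)[bad]] = False
                for v in vals[bad]:
                    log_rows.append((*key, lo, hi, v, "removed", len(vals), n_pass))
        out = out.loc[keep]
        if not removed_any:
            break
    log = pd.DataFrame(
        log_rows,
        columns=[*group_cols, "fence_low", "fence_high", "value_uM", "action",
                 "group_size", "pass_idx"],
    )
    log["quartile_method"] = quartile_method
    return out.reset_index(drop=True), log


def _species_column(data: pd.DataFrame) -> pd.Series:
    iso = data["isotopologue"].astype(str)
    return np.where(
        iso.str.len() > 0, data["metabolite"].astype(str) + "_" + iso,
        data["metabolite"].astype(str),
    )


def reduce_to_model_dataset(
    data: pd.DataFrame,
    comp: ProteinComposition = ProteinComposition(),
    sigma_floor_abs: float = 1e-6,
    sigma_floor_rel: float = 0.0,
    subject_agg: str = "mean",
) -> pd.DataFrame:
    """Collapse a (filtered) raw table to per-intervention model curves.

    Per subject, technical replicates are reduced to their median; the
    protein pool is reconstructed from its amino-acid components;
    the pre-ingestion baseline (mean over t < 0) is subtracted per
    subject and species (clipped at zero) and a t = 0 anchor of zero is
    inserted; finally values are averaged across subjects
    (``subject_agg``: mean, or median) with the across-subject SD as
    sigma.  The SD floor max(sigma_floor_abs, sigma_floor_rel x peak
    mean) is purely numerical (it keeps the weighted cost defined for
    noise-free data); real across-subject scatter always exceeds it.

    Returns a tidy frame (intervention, time_min, species, mean_uM,
    sd_uM) restricted to the modelled and driver species.
    """
    if subject_agg not in ("mean", "median"):
        raise ValueError("subject_agg must be 'mean' or 'median'")
    df = data.copy()
    df["species"] = _species_column(df)

    present = set(df["species"].unique())
    needed = set(MODEL_SPECIES) - {"protein"} | set(PROTEIN_COMPONENTS)
    missing = sorted(needed - present)
    if missing:
        raise ValueError(f"dataset is missing required species: {', '.join(missing)}")

    # replicate medians per subject
    med = (
        df.groupby(["intervention", "subject", "time_min", "species"], sort=False)
        ["concentration_uM"].median().reset_index()
    )

    # protein pool per subject/time from the four components
    wide = med.pivot_table(
        index=["intervention", "subject", "time_min"],
        columns="species", values="concentration_uM",
    )
    wide["protein"] = protein_pool(
        wide["glutamate_M5"], wide["glutamine_M5"],
        wide["valine_M5"], wide["threonine_M4"], comp,
    )
    long = (
        wide[[s for s in MODEL_SPECIES if s in wide.columns]]
        .reset_index()
        .melt(["intervention", "subject", "time_min"],
              var_name="species", value_name="concentration_uM")
        .dropna(subset=["concentration_uM"])
    )

    # baseline subtraction per subject/species, then t = 0 anchor
    keys = ["intervention", "subject", "species"]
    baseline = (
        long.loc[long["time_min"] < 0]
        .groupby(keys, sort=False)["concentration_uM"].mean()
        .rename("baseline_uM").reset_index()
    )
    post = long.loc[long["time_min"] > 0].merge(baseline, on=keys, how="left")
    post["baseline_uM"] = post["baseline_uM"].fillna(0.0)
    post["concentration_uM"] = np.clip(
        post["concentration_uM"] - post["baseline_uM"], 0.0, None
    )
    anchors = post[keys].drop_duplicates().copy()
    anchors["time_min"] = 0.0
    anchors["concentration_uM"] = 0.0
    long = pd.concat(
        [anchors, post[keys + ["time_min", "concentration_uM"]]], ignore_index=True
    )

    agg = (
        long.groupby(["intervention", "time_min", "species"], sort=False)
        ["concentration_uM"]
        .agg(mean_uM=subject_agg, sd_uM=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0)
        .reset_index()
    )

    # sigma floor: absolute, or relative to each species' peak mean
    peak = agg.groupby(["intervention", "species"])["mean_uM"].transform("max")
    floor = np.maximum(sigma_floor_abs, sigma_floor_rel * peak)
    agg["sd_uM"] = np.maximum(agg["sd_uM"].fillna(0.0), floor)
    agg = agg.sort_values(["intervention", "species", "time_min"]).reset_index(drop=True)
    return agg
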