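"""Trial-level agronomic quantities for a two-treatment maize trial.

A trial compares the same genotype panel under low managed nitrogen (LOW)
and optimal fertilization (OP), three replicates each. The quantities:

* grain yield  GY = X·10 / area  (Mg/ha), X the plot grain weight in kg at
  standardized moisture, area the harvested plot area (default 5.25 m² =
  0.75 m row spacing × 2 rows × 3.5 m harvested row length);
* grain yield loss index  GYLI = (GY_OP − GY_LOW)/GY_OP × 100 (percent);
* visual senescence  SEN = (YC + DC)/(YC + DC + GC), from green, yellow
  and dry canopy-cover classes;
* anthesis–silking interval  ASI = SD − AD (days; negative retained);
* rank-based yield quartiles HY/MHY/MLY/LY per treatment, and the
  percentage of genotypes shared by the same quartile across treatments.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "HARVEST_AREA_M2",
    "harvest_area",
    "grain_yield",
    "gyli",
    "senescence",
    "asi",
    "ground_sample_distance",
    "quartile_groups",
    "group_overlap",
    "yield_summary",
    "QUARTILE_LABELS",
]

#: Default harvested plot area (m²).
HARVEST_AREA_M2 = 5.25

#: Quartile labels in descending yield order.
QUARTILE_LABELS = ["HY", "MHY", "MLY", "LY"]


def harvest_area(row_spacing_m: float = 0.75, n_rows: int = 2,
                 row_length_m: float = 3.5) -> float:
    """Harvested plot area from row geometry (default 0.75 × 2 × 3.5 = 5.25 m²)."""
    area = row_spacing_m * n_rows * row_length_m
    if area <= 0:
        raise ValueError("harvest area must be positive")
    return area


def grain_yield(grain_weight_kg: float, area_m2: float = HARVEST_AREA_M2) -> float:
    """GY (Mg/ha) = grain weight (kg/plot) × 10 / area (m²)."""
    if area_m2 <= 0:
        raise ValueError("area must be positive")
    if grain_weight_kg < 0:
        raise ValueError("grain weight must be non-negative")
    return grain_weight_kg * 10.0 / area_m2


def gyli(gy_op: float, gy_low: float) -> float:
    """Grain yield loss index (%): (GY_OP − GY_LOW)/GY_OP × 100.

    NaN (with a warning) when the optimal-condition yield is not positive;
    negative values mean LOW outyielded OP.
    """
    if gy_op <= 0:
        warnings.warn("GYLI undefined: GY at OP is not positive", stacklevel=2)
        return math.nan
    return (gy_op - gy_low) / gy_op * 100.0


def senescence(gc: float, yc: float, dc: float) -> float:
    """SEN = (YC + DC)/(YC + DC + GC) in [0, 1]; NaN when all classes zero."""
    if min(gc, yc, dc) < 0:
        raise ValueError("canopy-cover classes must be non-negative")
    total = gc + yc + dc
    if total == 0:
        return math.nan
    return (yc + dc) / total


def asi(sd_days: float, ad_days: float) -> float:
    """Anthesis–silking interval, SD − AD (days); may be negative."""
    return sd_days - ad_days


def ground_sample_distance(sensor_width_mm: float, image_width_px: int,
                           focal_length_mm: float, altitude_m: float) -> float:
    """Ground sample distance (cm/pixel) of a nadir frame.

    GSD = sensor width × altitude / (focal length × image width); e.g. a
    4/3″ sensor (17.3 mm) at 4592 px, 20 mm lens, 50 m altitude gives
    0.9419 cm/pixel.
    """
    if min(sensor_width_mm, image_width_px, focal_length_mm, altitude_m) <= 0:
        raise ValueError("all camera/flight parameters must be positive")
    return sensor_width_mm * altitude_m * 100.0 / (focal_length_mm * image_width_px)


def quartile_groups(genotype_gy: pd.Series) -> pd.Series:
    """Rank genotypes into HY/MHY/MLY/LY quartiles by descending yield.

    Input is one treatment's genotype-level mean GY indexed by genotype.
    Group sizes are n/4 (±1 under non-divisible n); ties are broken by
    genotype name so the labelling is deterministic under row reordering.
    """
    s = pd.Series(genotype_gy).astype(float)
    if s.index.has_duplicates:
        raise ValueError("duplicate genotypes in input")
    n = len(s)
    if n < 4:
        raise ValueError("need at least 4 genotypes to form quartiles")
    order = sorted(s.index, key=lambda g: (-s[g], str(g)))
    labels = pd.Series(index=s.index, dtype=object)
    for lab, chunk in zip(QUARTILE_LABELS, np.array_split(np.array(order, dtype=object), 4)):
        labels[list(chunk)] = lab
    return labels


def group_overlap(labels_op: pd.Series, labels_low: pd.Series) -> dict[str, int]:
    """Per-quartile percentage of genotypes keeping their group across treatments.

    For each group g: 100 × |{genotypes labelled g under both}| / |g under
    OP|, rounded to the nearest integer percent (e.g. 7 of 16 shared HY
    genotypes → 44%).
    """
    a, b = pd.Series(labels_op), pd.Series(labels_low)
    if set(a.index) != set(b.index):
        raise ValueError(
            "genotype sets differ: "
            f"only-op={sorted(set(a.index) - set(b.index))}, "
            f"only-low={sorted(set(b.index) - set(a.index))}"
        )
    b = b.reindex(a.index)
    out: dict[str, int] = {}
    for g in QUARTILE_LABELS:
        members = a.index[a == g]
        if len(members) == 0:
            continue
        shared = int((b.loc[members] == g).sum())
        out[g] = round(100.0 * shared / len(members))
    return out


def yield_summary(trial: pd.DataFrame, area_m2: float = HARVEST_AREA_M2) -> pd.DataFrame:
    """Genotype-level yield summary across both treatments.

    Expects columns genotype, treatment (LOW/OP), and either grain_weight
    (kg/plot, converted via :func:`grain_yield`) or a precomputed ``gy``
    column. Genotype GY is the mean over replicates within treatment.
    Returns one row per genotype with gy_low, gy_op, gyli and the quartile
    label under each treatment.
    """
    df = trial.copy()
    if "gy" not in df.columns:
        if "grain_weight" not in df.columns:
            raise ValueError("trial table needs a grain_weight or gy column")
        df["gy"] = df["grain_weight"].astype(float).map(lambda x: grain_yield(x, area_m2))
    means = df.groupby(["genotype", "treatment"])["gy"].mean().unstack("treatment")
    for t in ("LOW", "OP"):
        if t not in means.columns:
            raise ValueError(f"treatment {t!r} absent from trial table")
    summary = pd.DataFrame({
        "gy_low": means["LOW"],
        "gy_op": means["OP"],
    })
    summary["gyli"] = [gyli(o, l) for o, l in zip(summary["gy_op"], summary["gy_low"])]
    summary["group_op"] = quartile_groups(summary["gy_op"])
    summary["group_low"] = quartile_groups(summary["gy_low"])
    return summary
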