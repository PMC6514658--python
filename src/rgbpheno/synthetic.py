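"""Synthetic canopy scenes and trial tables with known ground truth.

No public field-trial imagery accompanies the analysis this toolkit
implements, so every module is exercised against synthetic data whose
truth is known by construction:

* :func:`render_scene` paints a soil background with seeded elliptical
  vegetation blobs, an optional share of which is rendered yellow-green
  (chlorotic, hue 60–80°), and returns the image together with its true
  vegetation/chlorotic masks and the applied vignetting field. Class
  pixel counts hit the requested fractions exactly (the last blob is
  trimmed), so GA/GGA recovery can be checked against mask counts.

* :func:`simulate_trial` draws a two-treatment (LOW/OP nitrogen) maize
  trial: genotype yield effects from a correlated bivariate model, with
  default level and spread chosen to span roughly 1.5–4.4 Mg/ha under
  LOW and 6.7–12.3 Mg/ha under OP — the magnitudes typical of managed
  low-N maize trials — and agronomic covariates (AD, ASI, PH, SEN) and
  field-sensor columns generated with programmed correlations to yield
  (negative ASI/AD under LOW). The generative parameters are returned
  for recovery tests.

Per-pixel texture uses multiplicative brightness jitter in DN space,
which preserves hue exactly, so every mask-true pixel's hue is guaranteed
to lie in its class's programmed hue band before vignetting. Vignetting
is applied multiplicatively in linear RGB before re-encoding, as lens
falloff acts on sensor irradiance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .agronomy import HARVEST_AREA_M2
from .color import RgbImage, linear_to_srgb, srgb_to_linear

__all__ = ["SceneSpec", "TrialSpec", "render_scene", "simulate_trial"]


@dataclass
class SceneSpec:
    """Parameters of one synthetic canopy scene.

    Class colors sit well inside their hue bands: soil ≈ 36° (outside the
    vegetation window, and with chroma away from the NDLuv singular line
    (1 − u*) + v* = 0 so the normalized-difference indices are
    well-defined on soil), green ≈ 113° (inside [80°, 180°)) and
    chlorotic ≈ 65° (inside [60°, 80°)). ``jitter_sigma`` is the relative SD of the
    hue-preserving brightness jitter; ``vignetting_strength`` in [0, 1]
    scales a cos⁴ radial falloff.
    """

    width: int = 160
    height: int = 120
    veg_fraction: float = 0.4
    chlorotic_share: float = 0.0
    soil_color: tuple[int, int, int] = (140, 110, 65)
    green_color: tuple[int, int, int] = (60, 140, 50)
    chlorotic_color: tuple[int, int, int] = (150, 160, 40)
    jitter_sigma: float = 0.08
    vignetting_strength: float = 0.0
    blob_scale: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must have positive area")
        for name in ("veg_fraction", "chlorotic_share", "vignetting_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def _blob_mask(rng: np.random.Generator, h: int, w: int, target: int,
               blob_scale: float) -> np.ndarray:
    """Seeded elliptical blobs trimmed to exactly ``target`` pixels."""
    mask = np.zeros((h, w), bool)
    if target <= 0:
        return mask
    if target >= h * w:
        mask[:] = True
        return mask
    yy, xx = np.mgrid[0:h, 0:w]
    scale = blob_scale * min(h, w)
    count = 0
    for _ in range(10_000):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        a = rng.uniform(0.6, 1.6) * scale
        b = rng.uniform(0.6, 1.6) * scale
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        new = blob & ~mask
        n_new = int(new.sum())
        if n_new == 0:
            continue
        need = target - count
        if n_new > need:
            idx = np.flatnonzero(new.ravel())
            keep = rng.choice(idx, size=need, replace=False)
            sel = np.zeros(h * w, bool)
            sel[keep] = True
            new = sel.reshape(h, w)
            n_new = need
        mask |= new
        count += n_new
        if count >= target:
            break
    else:  # pragma: no cover - defensive
        raise RuntimeError("blob placement did not converge")
    return mask


def _vignetting_field(h: int, w: int, strength: float) -> np.ndarray:
    """Radial cos⁴ falloff multiplier, 1 at center, 1 − 0.75·strength at corners."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    rmax = np.hypot(cy, cx) or 1.0
    falloff = np.cos(np.pi / 4 * r / rmax) ** 4
    return 1.0 - strength * (1.0 - falloff)


def render_scene(spec: SceneSpec) -> tuple[RgbImage, dict[str, np.ndarray]]:
    """Render one scene; returns (image, ground-truth masks).

    The masks dict holds boolean ``vegetation`` and ``chlorotic`` masks
    (chlorotic ⊆ vegetation) and the float ``vignetting`` multiplier
    field. Same seed → byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    total = h * w
    target_veg = int(round(spec.veg_fraction * total))
    veg = _blob_mask(rng, h, w, target_veg, spec.blob_scale)

    n_veg = int(veg.sum())
    k_chl = int(round(spec.chlorotic_share * n_veg))
    chlorotic = np.zeros((h, w), bool)
    if k_chl > 0:
        smooth = ndimage.gaussian_filter(
            rng.standard_normal((h, w)), sigma=max(2.0, min(h, w) / 10.0)
        )
        veg_idx = np.flatnonzero(veg.ravel())
        order = veg_idx[np.argsort(-smooth.ravel()[veg_idx], kind="stable")]
        sel = np.zeros(total, bool)
        sel[order[:k_chl]] = True
        chlorotic = sel.reshape(h, w)

    img = np.empty((h, w, 3), float)
    img[:] = np.asarray(spec.soil_color, float)
    img[veg] = np.asarray(spec.green_color, float)
    img[chlorotic] = np.asarray(spec.chlorotic_color, float)

    # hue-preserving brightness texture: common per-pixel gain, no clipping
    gain = np.clip(1.0 + spec.jitter_sigma * rng.standard_normal((h, w)), 0.55, 1.40)
    img *= gain[..., None]

    vig = _vignetting_field(h, w, spec.vignetting_strength)
    if spec.vignetting_strength > 0:
        lin = srgb_to_linear(img / 255.0) * vig[..., None]
        img = linear_to_srgb(lin) * 255.0

    rgb = RgbImage(np.clip(np.round(img), 0, 255),
                   source_id=f"scene-{spec.seed}")
    return rgb, {"vegetation": veg, "chlorotic": chlorotic, "vignetting": vig}


@dataclass
class TrialSpec:
    """Parameters of one synthetic two-treatment trial.

    Yield means/SDs are genotype-level; replicate noise is added on top.
    ``genotype_corr`` couples a genotype's OP and LOW effects (1 → same
    ranking in both treatments, 0 → independent rankings).
    ``cov_targets`` maps covariate → (mean, sd, r_low, r_op), the marginal
    scale and the programmed genotype-level correlation with yield under
    each treatment.
    """

    n_genotypes: int = 64
    n_reps: int = 3
    gy_low_mean: float = 2.93
    gy_low_sd: float = 0.55
    gy_op_mean: float = 9.62
    gy_op_sd: float = 1.10
    genotype_corr: float = 0.5
    rep_noise_low: float = 0.25
    rep_noise_op: float = 0.45
    cov_targets: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "ad": (70.0, 3.0, -0.46, 0.27),
            "asi": (2.0, 1.5, -0.53, 0.16),
            "ph": (180.0, 15.0, 0.19, 0.13),
            "sen": (0.30, 0.10, -0.21, 0.0),
            "ndvi": (0.68, 0.06, 0.38, 0.1),
            "spad_v": (45.0, 6.0, 0.54, 0.1),
            "spad_r": (40.0, 7.0, 0.51, 0.1),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.genotype_corr <= 1.0:
            raise ValueError("genotype_corr must lie in [-1, 1]")
        for v in (self.gy_low_sd, self.gy_op_sd):
            if v <= 0:
                raise ValueError("yield SDs must be positive")


def simulate_trial(spec: TrialSpec) -> tuple["pd.DataFrame", dict]:
    """Simulate one genotype × replicate × treatment trial table.

    Returns ``(table, truth)`` where the table has one row per plot
    (columns genotype, replicate, treatment, grain_weight, gy, ad, sd,
    ph, gc/yc/dc canopy classes, ndvi, spad_v, spad_r) and ``truth``
    carries the generative genotype effects and target correlations.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    n = spec.n_genotypes
    rho = spec.genotype_corr

    e1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    z_op = e1
    z_low = rho * e1 + np.sqrt(max(0.0, 1 - rho**2)) * e2

    gy_geno = {
        "OP": np.clip(spec.gy_op_mean + spec.gy_op_sd * z_op, 0.1, None),
        "LOW": np.clip(spec.gy_low_mean + spec.gy_low_sd * z_low, 0.1, None),
    }
    z_t = {"OP": z_op, "LOW": z_low}
    rep_noise = {"OP": spec.rep_noise_op, "LOW": spec.rep_noise_low}

    genos = [f"G{i + 1:03d}" for i in range(n)]
    rows = []
    for treatment in ("LOW", "OP"):
        z = z_t[treatment]
        cov_geno = {}
        for name, (mean, sd, r_low, r_op) in spec.cov_targets.items():
            r = r_low if treatment == "LOW" else r_op
            e = rng.standard_normal(n)
            cov_geno[name] = mean + sd * (r * z + np.sqrt(max(0.0, 1 - r**2)) * e)
        for rep in range(1, spec.n_reps + 1):
            gy = np.clip(
                gy_geno[treatment] + rep_noise[treatment] * rng.standard_normal(n),
                0.05, None,
            )
            sen = np.clip(
                cov_geno["sen"] + 0.02 * rng.standard_normal(n), 0.0, 1.0
            )
            cover = np.clip(0.9 + 0.04 * rng.standard_normal(n), 0.5, 1.0)
            yellow_share = rng.uniform(0.3, 0.7, n)
            ad_rep = cov_geno["ad"] + 0.8 * rng.standard_normal(n)
            asi_rep = cov_geno["asi"] + 0.3 * rng.standard_normal(n)
            for i, g in enumerate(genos):
                rows.append(dict(
                    genotype=g,
                    replicate=rep,
                    treatment=treatment,
                    gy=gy[i],
                    grain_weight=gy[i] * HARVEST_AREA_M2 / 10.0,
                    ad=ad_rep[i],
                    sd=ad_rep[i] + asi_rep[i],
                    ph=cov_geno["ph"][i] + 3.0 * rng.standard_normal(),
                    gc=(1 - sen[i]) * cover[i],
                    yc=sen[i] * cover[i] * yellow_share[i],
                    dc=sen[i] * cover[i] * (1 - yellow_share[i]),
                    ndvi=float(np.clip(cov_geno["ndvi"][i]
                                       + 0.02 * rng.standard_normal(), 0, 1)),
                    spad_v=cov_geno["spad_v"][i] + 1.5 * rng.standard_normal(),
                    spad_r=cov_geno["spad_r"][i] + 1.5 * rng.standard_normal(),
                ))
    table = pd.DataFrame(rows)
    truth = dict(
        spec=spec,
        genotypes=genos,
        z_op=z_op,
        z_low=z_low,
        gy_geno_op=gy_geno["OP"],
        gy_geno_low=gy_geno["LOW"],
        cov_targets=dict(spec.cov_targets),
    )
    return table, truth
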