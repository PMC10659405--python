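"""Synthetic nested datasets, label masks and FP traces with known ground truth.

The generator emulates the statistical structure of a layered SEM
morphometry study: two genotypes (CTL, cKO) x animals x hippocampal
sections x three dendritic layers (SO, SR, SLM) x 100 um^2 tiles, with
per-tile mitochondrial counts drawn from a negative binomial
(overdispersed Poisson) and per-object areas from a log-normal truncated
to the analysis size filter.  Animal- and section-level multiplicative
log-normal random effects induce the within-cluster correlation the
hierarchical bootstrap exists to handle.

Default per-layer tile-count means reproduce the reported layer medians
(CTL SO/SR/SLM = 10/10/19; cKO = 13/13/23 per 100 um^2), and default
effect directions follow the reported phenotype: more numerous but
smaller mitochondria in the knockout, with no aspect-ratio change.
Absolute areas are not reported (plots are normalised), so the CTL SR
median defaults to 0.20 um^2 — an arbitrary but configurable anchor
inside the size-filter bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .hierboot import HierarchicalDataset
from .morphometry import SizeFilter
from .plasticity import FPTrace, PHASE_PRE, PHASE_POST

__all__ = [
    "LayerParams",
    "GeneratorParams",
    "generate_hierarchy",
    "generate_mask",
    "generate_fp_experiment",
]

GENOTYPES = ("CTL", "cKO")
LAYERS = ("SO", "SR", "SLM")


@dataclass(frozen=True)
class LayerParams:
    """Generative distributions for one genotype x layer cell.

    count_mean / count_dispersion
        Negative-binomial mean and shape for mitochondria per 100 um^2
        tile (variance = mean + mean^2 / dispersion).
    area_median / area_log_sd
        Log-normal median (um^2) and log-scale SD of individual areas,
        truncated to the size filter.
    aspect_alpha / aspect_beta
        Beta parameters of the aspect ratio on (0, 1].
    """

    count_mean: float
    area_median: float
    count_dispersion: float = 10.0
    area_log_sd: float = 0.6
    aspect_alpha: float = 4.0
    aspect_beta: float = 3.0

    def __post_init__(self) -> None:
        if self.count_mean <= 0 or self.area_median <= 0:
            raise ValueError("means must be positive")
        if self.count_dispersion <= 0 or self.area_log_sd <= 0:
            raise ValueError("dispersion parameters must be positive")


def _default_layer_params() -> dict[tuple[str, str], LayerParams]:
    # Count means from the reported per-layer medians; areas anchored at
    # 0.20 um^2 in CTL SR with SLM 30% larger (larger distal mitochondria)
    # and a uniform 10% genotype decrease (smaller mitochondria in cKO).
    # SO mitochondria are rounder (Beta mean closer to 1).
    base_area = {"SO": 0.20, "SR": 0.20, "SLM": 0.26}
    counts = {
        ("CTL", "SO"): 10.0,
        ("CTL", "SR"): 10.0,
        ("CTL", "SLM"): 19.0,
        ("cKO", "SO"): 13.0,
        ("cKO", "SR"): 13.0,
        ("cKO", "SLM"): 23.0,
    }
    aspect = {"SO": (6.0, 2.5), "SR": (4.0, 3.0), "SLM": (4.0, 3.0)}
    params = {}
    for genotype in GENOTYPES:
        area_scale = 1.0 if genotype == "CTL" else 0.90
        for layer in LAYERS:
            a, b = aspect[layer]
            params[(genotype, layer)] = LayerParams(
                count_mean=counts[(genotype, layer)],
                area_median=base_area[layer] * area_scale,
                aspect_alpha=a,
                aspect_beta=b,
            )
    return params


@dataclass(frozen=True)
class GeneratorParams:
    """Full study-design parameters for the nested generator.

    ``animal_cv`` and ``section_cv`` are coefficients of variation of the
    multiplicative log-normal random effects applied to the count mean and
    area median at the animal and section level.
    """

    layer_params: Mapping[tuple[str, str], LayerParams] = field(
        default_factory=_default_layer_params
    )
    animal_cv: float = 0.15
    section_cv: float = 0.10
    n_animals: int = 3
    n_sections: int = 3
    n_tiles: int = 30
    tile_side_um: float = 10.0
    size_filter: SizeFilter = field(default_factory=SizeFilter)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.animal_cv < 0 or self.section_cv < 0:
            raise ValueError("random-effect CVs must be >= 0")
        for name in ("n_animals", "n_sections", "n_tiles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "GeneratorParams":
        """Both genotypes share the CTL generative parameters (no effect)."""
        base = _default_layer_params()
        null_params = {
            (g, layer): base[("CTL", layer)] for g in GENOTYPES for layer in LAYERS
        }
        return cls(layer_params=null_params, seed=seed, **kwargs)


def _lognormal_effect(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def _truncated_lognormal(
    rng: np.random.Generator,
    median: float,
    log_sd: float,
    bounds: SizeFilter,
    size: int,
) -> np.ndarray:
    """Inverse-CDF sampling of a log-normal restricted to the size filter."""
    if not (bounds.min_area <= median <= bounds.max_area):
        raise ValueError(
            f"area median {median:.3g} um^2 lies outside the size filter "
            f"[{bounds.min_area}, {bounds.max_area}]; truncation impossible"
        )
    dist = stats.lognorm(s=log_sd, scale=median)
    lo, hi = dist.cdf([bounds.min_area, bounds.max_area])
    u = rng.random(size)
    return dist.ppf(lo + u * (hi - lo))


def generate_hierarchy(
    params: GeneratorParams, with_objects: bool = True
) -> HierarchicalDataset:
    """Generate a full nested dataset, deterministic from ``params.seed``.

    With ``with_objects=False`` only the per-tile table (counts and total
    areas implied zero) is produced, which is much faster when only the
    tile-count metric is needed.
    """
    rng = np.random.default_rng(params.seed)
    tile_rows = []
    obj_rows = []
    tile_k = 0
    for genotype in GENOTYPES:
        for a in range(params.n_animals):
            animal_id = f"{genotype}_a{a}"
            ac = _lognormal_effect(rng, params.animal_cv)
            aa = _lognormal_effect(rng, params.animal_cv)
            for s in range(params.n_sections):
                section_id = f"{animal_id}_s{s}"
                sc = _lognormal_effect(rng, params.section_cv)
                sa = _lognormal_effect(rng, params.section_cv)
                for layer in LAYERS:
                    lp = params.layer_params[(genotype, layer)]
                    mean_count = lp.count_mean * ac * sc
                    k = lp.count_dispersion
                    counts = rng.negative_binomial(
                        n=k, p=k / (k + mean_count), size=params.n_tiles
                    )
                    for t, count in enumerate(counts):
                        tile_id = f"{section_id}_{layer}_t{t}"
                        total_area = 0.0
                        if with_objects and count > 0:
                            areas = _truncated_lognormal(
                                rng,
                                lp.area_median * aa * sa,
                                lp.area_log_sd,
                                params.size_filter,
                                int(count),
                            )
                            aspects = np.clip(
                                rng.beta(lp.aspect_alpha, lp.aspect_beta, int(count)),
                                1e-3,
                                1.0,
                            )
                            # full ellipse axes from area and aspect ratio
                            long_ax = np.sqrt(4.0 * areas / (np.pi * aspects))
                            short_ax = aspects * long_ax
                            cx = rng.uniform(0, params.tile_side_um, int(count))
                            cy = rng.uniform(0, params.tile_side_um, int(count))
                            total_area = float(areas.sum())
                            for j in range(int(count)):
                                obj_rows.append(
                                    {
                                        "object_id": f"{tile_id}_o{j}",
                                        "tile_id": tile_id,
                                        "centroid_x_um": cx[j],
                                        "centroid_y_um": cy[j],
                                        "area_um2": areas[j],
                                        "short_axis_um": short_ax[j],
                                        "long_axis_um": long_ax[j],
                                        "aspect_ratio": aspects[j],
                                    }
                                )
                        tile_rows.append(
                            {
                                "tile_id": tile_id,
                                "section_id": section_id,
                                "animal_id": animal_id,
                                "genotype": genotype,
                                "layer": layer,
                                "mito_count": int(count),
                                "total_mito_area": total_area,
                            }
                        )
                        tile_k += 1
    tiles = pd.DataFrame(tile_rows)
    objects = pd.DataFrame(obj_rows) if with_objects else None
    return HierarchicalDataset(tiles, objects)


def generate_mask(
    objects: pd.DataFrame,
    pixel_size: float = 0.02,
    image_size_um: float = 10.0,
    seed: int = 0,
    max_attempts: int = 100,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render objects as disjoint filled rotated ellipses in a label mask.

    Parameters
    ----------
    objects
        Table with ``area_um2`` and ``aspect_ratio`` columns (one row per
        object); positions and orientations are drawn at random.
    pixel_size
        Microns per pixel (default 0.02 -> a 10 um tile is 500 px).

    Returns
    -------
    (mask, truth)
        ``mask`` is an int32 raster with labels 1..n; ``truth`` records
        each object's requested area/aspect and rendered centroid/angle.
        Overlaps are resolved by re-drawing the position up to
        ``max_attempts`` times, then an error names the offending object.
    """
    rng = np.random.default_rng(seed)
    n_px = int(round(image_size_um / pixel_size))
    mask = np.zeros((n_px, n_px), dtype=np.int32)
    truth_rows = []
    for label, row in enumerate(objects.itertuples(index=False), start=1):
        area = float(row.area_um2)
        aspect = float(row.aspect_ratio)
        long_ax = np.sqrt(4.0 * area / (np.pi * aspect))  # full axes, um
        short_ax = aspect * long_ax
        a_px = long_ax / 2.0 / pixel_size  # semi-axes, px
        b_px = short_ax / 2.0 / pixel_size
        if 2 * a_px >= n_px:
            raise ValueError(
                f"object {label} (area {area:.3g} um^2) does not fit in the tile"
            )
        placed = False
        for _ in range(max_attempts):
            theta = rng.uniform(0, np.pi)
            # keep the bounding circle inside the image
            margin = a_px + 1.0
            c_row = rng.uniform(margin, n_px - margin)
            c_col = rng.uniform(margin, n_px - margin)
            r0 = max(int(c_row - margin), 0)
            r1 = min(int(np.ceil(c_row + margin)) + 1, n_px)
            c0 = max(int(c_col - margin), 0)
            c1 = min(int(np.ceil(c_col + margin)) + 1, n_px)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            dr, dc = rr - c_row, cc - c_col
            ct, st = np.cos(theta), np.sin(theta)
            u = dr * ct + dc * st
            v = -dr * st + dc * ct
            inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
            if not inside.any():
                continue
            window = mask[r0:r1, c0:c1]
            if (window[inside] != 0).any():
                continue
            window[inside] = label
            truth_rows.append(
                {
                    "label": label,
                    "area_um2": area,
                    "aspect_ratio": aspect,
                    "centroid_row_px": c_row,
                    "centroid_col_px": c_col,
                    "angle_rad": theta,
                    "n_pixels": int(inside.sum()),
                }
            )
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place object {label} without overlap "
                f"after {max_attempts} attempts"
            )
    return mask, pd.DataFrame(truth_rows)


def generate_fp_experiment(
    effect: float,
    noise_cv: float = 0.10,
    seed: int = 0,
    baseline_uv: float = 100.0,
    pre_min: float = 10.0,
    conditioning_min: float = 20.0,
    post_min: float = 60.0,
    rate_hz: float = 0.1,
    slice_id: str = "synthetic",
    genotype: str = "",
    pathway: str = "",
) -> FPTrace:
    """Simulate one FP recording: 10 min pre, conditioning gap, 60 min post.

    Pre-phase amplitudes are i.i.d. Normal(baseline, noise_cv * baseline)
    and post-phase amplitudes Normal(baseline * (1 + effect), same SD),
    clipped at zero.  ``effect`` is the fractional change (0.54 mimics a
    robust LTP; values within +/-0.10 score as no change downstream).
    """
    if effect <= -1:
        raise ValueError("effect must be > -1 (amplitudes are non-negative)")
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz
    n_pre = int(round(pre_min * 60 * rate_hz))
    n_post = int(round(post_min * 60 * rate_hz))
    t_pre = np.arange(n_pre) * dt
    t_post = pre_min * 60 + conditioning_min * 60 + np.arange(n_post) * dt
    sd = noise_cv * baseline_uv
    amp_pre = baseline_uv + sd * rng.standard_normal(n_pre)
    amp_post = baseline_uv * (1 + effect) + sd * rng.standard_normal(n_post)
    return FPTrace(
        time_s=np.concatenate([t_pre, t_post]),
        amplitude_uv=np.clip(np.concatenate([amp_pre, amp_post]), 0.0, None),
        phase=np.array([PHASE_PRE] * n_pre + [PHASE_POST] * n_post, dtype=object),
        slice_id=slice_id,
        genotype=genotype,
        pathway=pathway,
    )
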