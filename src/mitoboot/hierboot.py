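"""Hierarchical bootstrap over a nested animal -> section -> tile -> object design.

Treating thousands of segmented mitochondria as independent observations
overstates significance because objects within a tile, tiles within a
section, and sections within an animal are correlated.  The hierarchical
bootstrap propagates every level of that nesting into the uncertainty of a
summary statistic: each repetition resamples, with replacement, animals
within a genotype, sections within each drawn animal, tiles (of the group's
layer) within each drawn section, and — for per-object metrics — individual
objects within each drawn tile.  The median of the pooled values is one
bootstrap repetition; repeating gives a population of resampled medians per
group whose pairwise comparison is summarised as ``P_boot``: the proportion
of paired repetitions in which one group's median exceeds the other's.

Groups are genotype x layer cells.  Repetition ``r`` uses the same random
substream for every group, so repetition-wise comparisons between groups are
paired (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "JointDistribution",
    "HierarchicalDataset",
    "resample_once",
    "run_bootstrap",
    "p_boot",
    "joint_distribution",
    "sampling_size_test",
]

METRIC_MEDIAN_AREA = "median_area"
METRIC_COUNT = "count_per_tile"
_METRICS = (METRIC_MEDIAN_AREA, METRIC_COUNT)


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling depths for one bootstrap run.

    Defaults follow the study design: 3 animals x 3 sections x 50 tiles
    (so 450 tiles pooled per repetition) and, for the per-object area
    metric, 100 objects per tile (45,000 objects per repetition);
    10,000 repetitions for final runs, 1,000 for calibration runs.
    """

    metric: str
    n_reps: int = 10_000
    n_animals: int = 3
    n_sections: int = 3
    n_tiles: int = 50
    n_mitos: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        for name in ("n_reps", "n_animals", "n_sections", "n_tiles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.metric == METRIC_MEDIAN_AREA:
            if self.n_mitos is None:
                object.__setattr__(self, "n_mitos", 100)
            elif self.n_mitos < 1:
                raise ValueError("n_mitos must be >= 1")


@dataclass
class BootstrapResult:
    """Population of resampled medians for one group."""

    group: tuple[str, str]
    medians: np.ndarray
    config: BootstrapConfig

    def __post_init__(self) -> None:
        self.medians = np.asarray(self.medians, dtype=float)
        if len(self.medians) != self.config.n_reps:
            raise ValueError("medians length must equal n_reps")
        if not np.all(np.isfinite(self.medians)):
            raise ValueError("medians must be finite")


@dataclass
class JointDistribution:
    """Paired 2D histogram of two groups' resampled medians, plus P_boot."""

    hist: np.ndarray
    edges_a: np.ndarray
    edges_b: np.ndarray
    p_boot: float

    def __post_init__(self) -> None:
        total = self.hist.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError("joint histogram mass must sum to 1")
        if not (0.0 <= self.p_boot <= 1.0):
            raise ValueError("p_boot must lie in [0, 1]")


@dataclass
class _GroupArrays:
    """Flattened, index-based view of one genotype x layer cell."""

    animal_ids: list
    # per animal: indices into `sections`
    animal_sections: list[np.ndarray]
    # per section: positions into the tile-level arrays below
    section_tiles: list[np.ndarray]
    # per section: positions of tiles that contain at least one object
    section_tiles_nonempty: list[np.ndarray]
    tile_counts: np.ndarray
    obj_offsets: np.ndarray
    obj_lengths: np.ndarray
    areas_flat: np.ndarray | None


_TILE_COLS = ["tile_id", "section_id", "animal_id", "genotype", "layer", "mito_count"]


class HierarchicalDataset:
    """Nested tile/object collection consumed by the bootstrap.

    Parameters
    ----------
    tiles
        One row per tile with columns ``tile_id, section_id, animal_id,
        genotype, layer, mito_count`` (``total_mito_area`` optional).
        Every tile appears exactly once; each tile belongs to one layer.
    objects
        Optional per-object table with at least ``tile_id`` and ``area_um2``;
        required for the per-object area metric.  Objects must reference
        tiles present in ``tiles``.
    """

    def __init__(self, tiles: pd.DataFrame, objects: pd.DataFrame | None = None):
        missing = [c for c in _TILE_COLS if c not in tiles.columns]
        if missing:
            raise ValueError(f"tiles table missing columns: {missing}")
        if tiles["tile_id"].duplicated().any():
            dupes = tiles.loc[tiles["tile_id"].duplicated(), "tile_id"].tolist()
            raise ValueError(f"duplicate tile ids: {dupes[:5]}")
        self.tiles = tiles.reset_index(drop=True)
        if objects is not None:
            if "tile_id" not in objects.columns or "area_um2" not in objects.columns:
                raise ValueError("objects table needs tile_id and area_um2 columns")
            known = set(self.tiles["tile_id"])
            orphan = ~objects["tile_id"].isin(known)
            if orphan.any():
                raise ValueError(
                    f"objects reference unknown tiles: "
                    f"{objects.loc[orphan, 'tile_id'].unique()[:5].tolist()}"
                )
        self.objects = objects.reset_index(drop=True) if objects is not None else None
        self._group_cache: dict[tuple[str, str], _GroupArrays] = {}

    @classmethod
    def from_csv(cls, tiles_path, objects_path=None) -> "HierarchicalDataset":
        tiles = pd.read_csv(tiles_path)
        objects = pd.read_csv(objects_path) if objects_path is not None else None
        return cls(tiles, objects)

    def groups(self) -> list[tuple[str, str]]:
        """All (genotype, layer) cells present, sorted."""
        pairs = self.tiles[["genotype", "layer"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def group_arrays(self, genotype: str, layer: str) -> _GroupArrays:
        key = (genotype, layer)
        if key not in self._group_cache:
            self._group_cache[key] = self._build_group(genotype, layer)
        return self._group_cache[key]

    def _build_group(self, genotype: str, layer: str) -> _GroupArrays:
        sel = self.tiles[
            (self.tiles["genotype"] == genotype) & (self.tiles["layer"] == layer)
        ].reset_index(drop=True)
        if len(sel) == 0:
            raise ValueError(f"no tiles for group ({genotype!r}, {layer!r})")

        areas_by_tile: dict | None = None
        if self.objects is not None:
            tile_set = set(sel["tile_id"])
            obj = self.objects[self.objects["tile_id"].isin(tile_set)]
            areas_by_tile = {
                tid: grp["area_um2"].to_numpy(dtype=float)
                for tid, grp in obj.groupby("tile_id", sort=False)
            }

        tile_counts = sel["mito_count"].to_numpy(dtype=float)
        obj_lengths = np.zeros(len(sel), dtype=np.int64)
        area_chunks: list[np.ndarray] = []
        if areas_by_tile is not None:
            for i, tid in enumerate(sel["tile_id"]):
                chunk = areas_by_tile.get(tid)
                if chunk is not None and len(chunk):
                    obj_lengths[i] = len(chunk)
                    area_chunks.append(chunk)
        obj_offsets = np.concatenate([[0], np.cumsum(obj_lengths)[:-1]])
        areas_flat = (
            np.concatenate(area_chunks) if area_chunks else None
        )

        animal_ids: list = []
        animal_sections: list[np.ndarray] = []
        section_tiles: list[np.ndarray] = []
        section_tiles_nonempty: list[np.ndarray] = []
        for animal_id, animal_grp in sel.groupby("animal_id", sort=True):
            sec_idx = []
            for _, sec_grp in animal_grp.groupby("section_id", sort=True):
                positions = sec_grp.index.to_numpy()
                sec_idx.append(len(section_tiles))
                section_tiles.append(positions)
                section_tiles_nonempty.append(
                    positions[obj_lengths[positions] > 0]
                )
            animal_ids.append(animal_id)
            animal_sections.append(np.asarray(sec_idx))
        return _GroupArrays(
            animal_ids=animal_ids,
            animal_sections=animal_sections,
            section_tiles=section_tiles,
            section_tiles_nonempty=section_tiles_nonempty,
            tile_counts=tile_counts,
            obj_offsets=obj_offsets,
            obj_lengths=obj_lengths,
            areas_flat=areas_flat,
        )


def _check_area_support(ga: _GroupArrays, group: tuple[str, str]) -> None:
    if ga.areas_flat is None:
        raise ValueError(
            f"group {group}: per-object areas required for the {METRIC_MEDIAN_AREA} "
            "metric but no objects table was provided"
        )
    for i, tiles in enumerate(ga.section_tiles_nonempty):
        if len(tiles) == 0:
            raise ValueError(
                f"group {group}: section #{i} has no tiles with objects"
            )


def _resample(
    ga: _GroupArrays,
    config: BootstrapConfig,
    rng: np.random.Generator,
    return_values: bool = False,
):
    """One bootstrap repetition on pre-flattened group arrays."""
    per_object = config.metric == METRIC_MEDIAN_AREA
    section_pool = ga.section_tiles_nonempty if per_object else ga.section_tiles

    animal_draw = rng.integers(0, len(ga.animal_ids), config.n_animals)
    drawn_sections: list[int] = []
    for a in animal_draw:
        secs = ga.animal_sections[a]
        drawn_sections.extend(secs[rng.integers(0, len(secs), config.n_sections)])

    tile_draw = np.concatenate(
        [
            section_pool[s][rng.integers(0, len(section_pool[s]), config.n_tiles)]
            for s in drawn_sections
        ]
    )
    if per_object:
        lengths = ga.obj_lengths[tile_draw]
        offsets = ga.obj_offsets[tile_draw]
        u = rng.random((len(tile_draw), config.n_mitos))
        idx = offsets[:, None] + (u * lengths[:, None]).astype(np.int64)
        values = ga.areas_flat[idx.ravel()]
    else:
        values = ga.tile_counts[tile_draw]
    median = float(np.median(values))
    if return_values:
        return median, values
    return median


def resample_once(
    dataset: HierarchicalDataset,
    group: tuple[str, str],
    config: BootstrapConfig,
    rng: np.random.Generator,
    return_values: bool = False,
):
    """Draw one bootstrap repetition for ``group`` and return its median.

    With ``return_values=True`` also returns the pooled metric values of the
    repetition (450 tile counts, or 45,000 object areas, at defaults).
    """
    ga = dataset.group_arrays(*group)
    if config.metric == METRIC_MEDIAN_AREA:
        _check_area_support(ga, group)
    return _resample(ga, config, rng, return_values=return_values)


def _rep_streams(seed: int, n_reps: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n_reps)


def run_bootstrap(
    dataset: HierarchicalDataset,
    config: BootstrapConfig,
    groups: Sequence[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], BootstrapResult]:
    """Run the full bootstrap, returning resampled-median populations per group.

    Repetition ``r`` re-seeds an identical substream for every group, so the
    per-repetition medians of two groups form a paired sample.
    """
    if groups is None:
        groups = dataset.groups()
    arrays = {}
    for group in groups:
        ga = dataset.group_arrays(*group)
        if config.metric == METRIC_MEDIAN_AREA:
            _check_area_support(ga, group)
        arrays[group] = ga
    streams = _rep_streams(config.seed, config.n_reps)
    results = {}
    for group in groups:
        ga = arrays[group]
        medians = np.empty(config.n_reps)
        for r, stream in enumerate(streams):
            rng = np.random.Generator(np.random.PCG64(stream))
            medians[r] = _resample(ga, config, rng)
        results[group] = BootstrapResult(group=group, medians=medians, config=config)
    return results


def p_boot(medians_a: np.ndarray, medians_b: np.ndarray) -> float:
    """Proportion of paired repetitions with median_a > median_b; ties 0.5.

    The tie rule makes the statistic antisymmetric:
    ``p_boot(a, b) + p_boot(b, a) == 1`` exactly.
    """
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("median arrays must have equal length (paired repetitions)")
    return float(np.mean((a > b) + 0.5 * (a == b)))


def joint_distribution(
    medians_a: np.ndarray, medians_b: np.ndarray, metric: str
) -> JointDistribution:
    """Equal-width 2D histogram of paired medians, normalised to mass 1.

    10 bins per axis for the tile-count metric, 100 for the area metric,
    over the pooled range of both arrays.  If all values are identical the
    histogram degenerates to a single bin on the diagonal.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    a = np.asarray(medians_a, dtype=float)
    b = np.asarray(medians_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("median arrays must have equal length (paired repetitions)")
    n_bins = 10 if metric == METRIC_COUNT else 100
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return JointDistribution(
            hist=np.ones((1, 1)),
            edges_a=np.array([lo, hi]),
            edges_b=np.array([lo, hi]),
            p_boot=p_boot(a, b),
        )
    hist, edges_a, edges_b = np.histogram2d(a, b, bins=n_bins, range=[[lo, hi]] * 2)
    return JointDistribution(
        hist=hist / hist.sum(),
        edges_a=edges_a,
        edges_b=edges_b,
        p_boot=p_boot(a, b),
    )


def sampling_size_test(
    dataset: HierarchicalDataset,
    level: str,
    candidate_sizes: Sequence[int] | None = None,
    n_reps: int = 1_000,
    n_runs: int = 10,
    seed: int = 0,
    groups: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Calibrate how many tiles (or objects) to draw per repetition.

    For each candidate sampling size the full bootstrap is repeated
    ``n_runs`` times with distinct sub-seeds.  Two variability measures are
    reported per group: ``rep_median_sd`` — the spread of the resampled
    medians within a run, averaged over runs (the width of the bootstrap
    distribution itself) — and ``grand_median_sd`` — the across-run
    standard deviation of each run's grand median.  Default candidates are
    {20, 32, 50} tiles and {5, 10, 20, 50, 100} objects.  Oversampling
    with replacement is expected to reduce the bootstrap variability; for
    the discrete tile-count metric the grand medians snap to a half-integer
    grid, so ``rep_median_sd`` is the more sensitive measure.
    """
    if level not in ("tiles", "mitochondria"):
        raise ValueError("level must be 'tiles' or 'mitochondria'")
    if candidate_sizes is None:
        candidate_sizes = (20, 32, 50) if level == "tiles" else (5, 10, 20, 50, 100)
    if len(candidate_sizes) == 0:
        raise ValueError("candidate_sizes must be non-empty")
    if groups is None:
        groups = dataset.groups()
    metric = METRIC_COUNT if level == "tiles" else METRIC_MEDIAN_AREA

    sub_seeds = np.random.SeedSequence(seed).generate_state(
        len(candidate_sizes) * n_runs
    ) & 0x7FFFFFFF
    rows = []
    k = 0
    for size in candidate_sizes:
        grand = {g: [] for g in groups}
        spread = {g: [] for g in groups}
        for _ in range(n_runs):
            if level == "tiles":
                cfg = BootstrapConfig(
                    metric=metric, n_reps=n_reps, n_tiles=int(size),
                    seed=int(sub_seeds[k]),
                )
            else:
                cfg = BootstrapConfig(
                    metric=metric, n_reps=n_reps, n_mitos=int(size),
                    seed=int(sub_seeds[k]),
                )
            k += 1
            results = run_bootstrap(dataset, cfg, groups)
            for g, res in results.items():
                grand[g].append(np.median(res.medians))
                spread[g].append(res.medians.std(ddof=1))
        for g in groups:
            vals = np.asarray(grand[g])
            rows.append(
                {
                    "level": level,
                    "size": int(size),
                    "genotype": g[0],
                    "layer": g[1],
                    "grand_median_mean": vals.mean(),
                    "grand_median_sd": vals.std(ddof=1),
                    "rep_median_sd": float(np.mean(spread[g])),
                    "n_runs": n_runs,
                    "n_reps": n_reps,
                }
            )
    return pd.DataFrame(rows)
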