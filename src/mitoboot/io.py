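"""CSV / TIFF input and output for the analysis pipeline.

Canonical formats:

* object table — ``object_id,tile_id,centroid_x_um,centroid_y_um,area_um2,
  short_axis_um,long_axis_um[,feret_um,aspect_ratio,nn_dist_um]``
* tile metadata — ``tile_id,section_id,animal_id,genotype,layer``
* per-tile aggregates — metadata plus ``mito_count,total_mito_area_um2``
* FP trace — ``time_s,amplitude_uV,phase``
* I/O curve — ``intensity_uA,amplitude_uV``
* label masks — 8/16/32-bit integer TIFF or PNG, 0 = background
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import MitoObject, objects_to_frame, frame_to_objects
from .plasticity import FPTrace, IOCurve

TILE_META_COLUMNS = ["tile_id", "section_id", "animal_id", "genotype", "layer"]


def read_label_mask(path) -> np.ndarray:
    """Read an integer label mask from TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        mask = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        mask = iio.imread(path)
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError(f"{path}: label mask must be an integer raster")
    return mask


def write_label_mask(path, mask: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(mask))


def read_objects_csv(path) -> list[MitoObject]:
    return frame_to_objects(pd.read_csv(path))


def write_objects_csv(path, objects) -> None:
    objects_to_frame(objects).to_csv(path, index=False)


def read_tile_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    missing = [c for c in TILE_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"tile metadata missing columns: {missing}")
    return meta


def read_fp_trace(path, **metadata) -> FPTrace:
    frame = pd.read_csv(path)
    return FPTrace(
        time_s=frame["time_s"].to_numpy(),
        amplitude_uv=frame["amplitude_uV"].to_numpy(),
        phase=frame["phase"].to_numpy(),
        **metadata,
    )


def write_fp_trace(path, trace: FPTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time_s, "amplitude_uV": trace.amplitude_uv, "phase": trace.phase}
    ).to_csv(path, index=False)


def read_io_curve(path) -> IOCurve:
    frame = pd.read_csv(path)
    return IOCurve(
        intensity_ua=frame["intensity_uA"].to_numpy(),
        amplitude_uv=frame["amplitude_uV"].to_numpy(),
    )
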