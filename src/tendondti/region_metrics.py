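"""Region-wise scalar statistics in long (tidy) format.

Each row of the measurement table is one (participant, limb, region,
metric, rater, session) combination holding the voxel-weighted mean of a
scalar map over the region's valid voxels.  Diffusivities are reported in
10⁻³ mm²/s, FA is dimensionless, and mask volumes — computed on the
high-resolution anatomical grid before downsampling — are reported in cm³.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .roi_geometry import RegionSet
from .tensor_model import ScalarMaps

__all__ = ["DTI_METRICS", "ALL_METRICS", "extract_region_stats"]

DTI_METRICS = ("lambda1", "lambda2", "lambda3", "md", "fa")
ALL_METRICS = DTI_METRICS + ("volume",)

# diffusivity maps are stored in mm²/s; tables use the conventional 1e-3 unit
_SCALE = {"lambda1": 1e3, "lambda2": 1e3, "lambda3": 1e3, "md": 1e3, "fa": 1.0}

TABLE_COLUMNS = [
    "participant_id", "limb", "limb_type", "region", "metric",
    "rater", "session", "value", "sd_within_region", "n_voxels", "missing",
]


def extract_region_stats(maps: ScalarMaps, regions: RegionSet, *,
                         participant_id: str, limb: str, limb_type: str,
                         rater: str, session: str,
                         volumes_mm3: dict[str, float] | None = None,
                         region_names=None) -> pd.DataFrame:
    """Per-region means of the scalar maps, plus optional volume rows.

    Region masks must already live on the scalar-map (DTI) grid, eroded
    upstream.  A region with zero valid voxels produces a row flagged
    ``missing`` rather than failing; reliability fits drop such rows.
    ``volumes_mm3`` maps region names to anatomical-grid volumes and is
    emitted as ``metric == "volume"`` rows in cm³.
    """
    rows: list[dict] = []
    names = tuple(region_names) if region_names is not None else regions.names()
    key = dict(participant_id=participant_id, limb=limb, limb_type=limb_type,
               rater=rater, session=session)
    for region in names:
        sel = regions[region] & maps.valid
        for metric in DTI_METRICS:
            arr = maps.as_dict()[metric]
            vals = arr[sel]
            vals = vals[np.isfinite(vals)]
            n = vals.size
            if n == 0:
                rows.append(dict(key, region=region, metric=metric,
                                 value=np.nan, sd_within_region=np.nan,
                                 n_voxels=0, missing=True))
                continue
            scale = _SCALE[metric]
            rows.append(dict(
                key, region=region, metric=metric,
                value=float(vals.mean() * scale),
                sd_within_region=float(vals.std(ddof=1) * scale) if n > 1 else 0.0,
                n_voxels=int(n), missing=False,
            ))
    if volumes_mm3 is not None:
        for region, vol in volumes_mm3.items():
            rows.append(dict(
                key, region=region, metric="volume",
                value=float(vol) / 1000.0,      # cm³
                sd_within_region=0.0, n_voxels=0, missing=False,
            ))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
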