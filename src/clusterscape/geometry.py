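"""Coordinate utilities shared by both rendering pathways."""

from __future__ import annotations

import numpy as np

from .io import PointCloud

__all__ = ["lift_to_3d", "scale_coordinates"]


def lift_to_3d(cloud: PointCloud) -> PointCloud:
    """Add a z = 0 plane to a 2-D cloud; x, y and point order are untouched.

    3-D input is rejected rather than silently overwritten.
    """
    if cloud.dims == 3:
        raise ValueError("cloud is already 3D; refusing to overwrite z")
    z = np.zeros((cloud.n_points, 1))
    return PointCloud(ids=cloud.ids.copy(), coords=np.hstack([cloud.coords, z]))


def scale_coordinates(cloud: PointCloud, factor: float) -> PointCloud:
    """Multiply every coordinate by ``factor`` (> 0), spreading points apart.

    A factor of 3 is the conventional spread for opening up space between
    rendered spheres while keeping all pairwise distance ratios intact.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return PointCloud(ids=cloud.ids.copy(), coords=cloud.coords * factor)
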