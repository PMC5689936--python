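"""Construction of the gamma analysis mask.

The analysis region is the patient's external contour expanded by a margin
(default 10 mm) and limited in the superior/inferior (z) direction to the
slice range spanned by the high-dose CTV — the region of most clinical
concern.  Restricting the comparison to this region keeps the failed-pixel
statistics from being polluted by reconstruction artifacts outside the
patient.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import Mask3D


def dilate_mask(mask: Mask3D, margin_mm: float) -> Mask3D:
    """Expand the true set by Euclidean distance ≤ ``margin_mm`` in physical space.

    Anisotropic spacing aware: a voxel joins the dilated set when its center
    lies within the margin of some originally-true voxel center (distance
    transform thresholding).  Expansion is clipped at the array bounds.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be >= 0, got {margin_mm}")
    if margin_mm == 0 or not mask.values.any():
        return mask.with_values(mask.values.copy())
    dist = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing)
    prov = dict(mask.provenance)
    prov["dilated_mm"] = prov.get("dilated_mm", 0.0) + float(margin_mm)
    return mask.with_values(dist <= margin_mm, prov)


def ctv_z_range(ctv: Mask3D) -> tuple[int, int]:
    """Inclusive (zmin, zmax) slice indices containing any true CTV voxel."""
    zs = np.nonzero(ctv.values.any(axis=(0, 1)))[0]
    if zs.size == 0:
        raise ValueError("CTV mask is empty; axial limits are undefined")
    return int(zs[0]), int(zs[-1])


def build_analysis_mask(external: Mask3D, ctv: Mask3D, margin_mm: float = 10.0) -> Mask3D:
    """External contour + margin, limited axially by the CTV extent.

    ``result = dilate(external, margin) AND z ∈ [zmin(CTV), zmax(CTV)]``.
    """
    if not external.grid_compatible(ctv):
        raise ValueError("external and CTV masks are not grid-compatible")
    zmin, zmax = ctv_z_range(ctv)
    dilated = dilate_mask(external, margin_mm)
    out = dilated.values.copy()
    out[:, :, :zmin] = False
    out[:, :, zmax + 1:] = False
    if not out.any():
        raise ValueError("analysis mask is empty")
    return Mask3D(
        out,
        external.spacing,
        external.origin,
        provenance={
            "external": external.provenance,
            "margin_mm": float(margin_mm),
            "ctv_z_slices": [zmin, zmax],
        },
    )
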