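"""3D gamma-index comparison of CT-number volumes.

The gamma index, borrowed from dose-distribution QA and applied here to
anatomy, scores each reference voxel ``r`` against every evaluated voxel
``r'`` within a search radius:

    gamma(r) = min over r' of sqrt( (|r - r'| / DTA)^2
                                  + ((HU_eval(r') - HU_ref(r)) / dHU)^2 )

where DTA is the distance-to-agreement criterion (mm) and dHU the CT-number
difference criterion.  gamma <= 1 means the voxel finds an acceptable match
in its neighbourhood; gamma > 1 is a *failure* and marks local anatomy
mismatch.  Values are capped at ``cap`` (default 5): since the distance term
alone exceeds ``cap`` outside radius ``cap * DTA``, restricting the search to
that radius is exact for every gamma below the cap.

Candidates are evaluated-volume voxel centers (no sub-voxel interpolation)
over the full evaluated volume, visited in order of increasing physical
distance with per-voxel early exit once the distance term alone rules out
improvement.  :func:`gamma_bruteforce` is the unpruned reference
implementation used as an oracle in tests.

Note the comparison is NOT symmetric in (reference, evaluated).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import Mask3D, Volume3D
from . import io as _io

#: sentinel written outside the mask in exported gamma maps
GAMMA_SENTINEL = -1.0


@dataclass(frozen=True)
class GammaCriteria:
    """Distance-to-agreement (mm) and CT-number difference (HU) criteria."""

    dta: float
    dhu: float

    def __post_init__(self) -> None:
        if self.dta <= 0 or self.dhu <= 0:
            raise ValueError(f"gamma criteria must be strictly positive, got {self}")


@dataclass
class GammaMap:
    """Per-voxel gamma values on a mask; NaN where the mask is false."""

    gamma: np.ndarray
    mask: Mask3D
    criteria: GammaCriteria
    cap: float

    def masked_values(self) -> np.ndarray:
        """Gamma values at masked voxels (1D, defined everywhere)."""
        return self.gamma[self.mask.values]

    def failed_count(self) -> int:
        return int(np.count_nonzero(self.masked_values() > 1.0))


def _sorted_offsets(spacing, radius_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer voxel offsets with physical norm <= radius, ascending by norm."""
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) for h in half]
    ii, jj, kk = np.meshgrid(*ax, indexing="ij")
    offs = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    d = np.sqrt(((offs * np.asarray(spacing, dtype=float)) ** 2).sum(axis=1))
    keep = d <= radius_mm + 1e-9
    offs, d = offs[keep], d[keep]
    # stable deterministic order: by distance, then lexicographic offset
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0], d))
    return offs[order], d[order]


def _validate(ref: Volume3D, ev: Volume3D, mask: Mask3D, criteria: GammaCriteria, cap: float):
    if not ref.grid_compatible(ev):
        raise ValueError("reference and evaluated volumes are not grid-compatible")
    if not ref.grid_compatible(mask):
        raise ValueError("mask is not on the reference grid")
    if not mask.values.any():
        raise ValueError("analysis mask is empty")
    if cap <= 0:
        raise ValueError("cap must be positive")


def gamma_map(
    ref: Volume3D,
    ev: Volume3D,
    criteria: GammaCriteria,
    mask: Mask3D,
    cap: float = 5.0,
) -> GammaMap:
    """Exact capped gamma map with distance-sorted search and early exit.

    Exactness: a voxel's final value below ``cap`` cannot be improved by any
    candidate whose distance term alone reaches the current best, so visiting
    offsets in increasing distance and retiring voxels whose best value is
    ≤ distance/DTA yields the same minimum as the exhaustive search.
    """
    _validate(ref, ev, mask, criteria, cap)
    offs, dists = _sorted_offsets(ref.spacing, cap * criteria.dta)
    coords = np.argwhere(mask.values)
    n = coords.shape[0]
    evv = np.ascontiguousarray(ev.values, dtype=np.float64)
    refv = ref.values[mask.values].astype(np.float64)
    best = np.full(n, float(cap))
    active = np.arange(n)
    shape = np.asarray(ref.shape)
    dta, dhu = criteria.dta, criteria.dhu

    for off, d in zip(offs, dists):
        dn = d / dta
        if dn >= cap:
            break
        keep = best[active] > dn
        if not keep.all():
            active = active[keep]
            if active.size == 0:
                break
        c = coords[active] + off
        inb = np.all((c >= 0) & (c < shape), axis=1)
        if not inb.all():
            sub = active[inb]
            c = c[inb]
        else:
            sub = active
        if sub.size == 0:
            continue
        diff = (evv[c[:, 0], c[:, 1], c[:, 2]] - refv[sub]) / dhu
        cand = np.sqrt(dn * dn + diff * diff)
        np.minimum(best[sub], cand, out=cand)
        best[sub] = cand

    out = np.full(ref.shape, np.nan)
    out[mask.values] = np.minimum(best, cap)
    return GammaMap(out, mask, criteria, float(cap))


_BRUTEFORCE_MAX_VOXELS = 40_000


def gamma_bruteforce(
    ref: Volume3D,
    ev: Volume3D,
    criteria: GammaCriteria,
    mask: Mask3D,
    cap: float = 5.0,
) -> GammaMap:
    """Unpruned exhaustive gamma over all voxels within ``cap * DTA``.

    Test oracle only; refuses volumes much beyond 32^3 voxels.
    """
    _validate(ref, ev, mask, criteria, cap)
    if int(np.prod(ref.shape)) > _BRUTEFORCE_MAX_VOXELS:
        raise ValueError(
            f"volume {ref.shape} too large for brute-force gamma "
            f"(limit {_BRUTEFORCE_MAX_VOXELS} voxels)"
        )
    offs, dists = _sorted_offsets(ref.spacing, cap * criteria.dta)
    coords = np.argwhere(mask.values)
    evv = np.ascontiguousarray(ev.values, dtype=np.float64)
    refv = ref.values[mask.values].astype(np.float64)
    best = np.full(coords.shape[0], np.inf)
    shape = np.asarray(ref.shape)
    for off, d in zip(offs, dists):
        dn = d / criteria.dta
        c = coords + off
        inb = np.all((c >= 0) & (c < shape), axis=1)
        c = c[inb]
        if c.shape[0] == 0:
            continue
        diff = (evv[c[:, 0], c[:, 1], c[:, 2]] - refv[inb]) / criteria.dhu
        cand = np.sqrt(dn * dn + diff * diff)
        best[inb] = np.minimum(best[inb], cand)
    out = np.full(ref.shape, np.nan)
    out[mask.values] = np.minimum(best, cap)
    return GammaMap(out, mask, criteria, float(cap))


def write_gamma_map(gmap: GammaMap, path: str | Path, sidecar: str | Path | None = None) -> Path:
    """Write a gamma map as float32 NIfTI (sentinel −1 outside the mask) plus
    a JSON sidecar with criteria, cap, and failed-voxel count."""
    path = Path(path)
    values = np.where(np.isnan(gmap.gamma), GAMMA_SENTINEL, gmap.gamma).astype(np.float32)
    _io.write_volume(
        Volume3D(values, gmap.mask.spacing, gmap.mask.origin), path
    )
    if sidecar is None:
        name = path.name
        for suf in (".nii.gz", ".nii"):
            if name.endswith(suf):
                name = name[: -len(suf)]
                break
        sidecar = path.with_name(name + ".json")
    meta = {
        "dta_mm": gmap.criteria.dta,
        "dhu_hu": gmap.criteria.dhu,
        "cap": gmap.cap,
        "sentinel": GAMMA_SENTINEL,
        "n_masked": gmap.mask.count(),
        "n_failed": gmap.failed_count(),
    }
    Path(sidecar).write_text(json.dumps(meta, indent=2))
    return path
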