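"""Reading and writing volumes, structure masks, and course manifests.

Volumes travel as NIfTI (``.nii``/``.nii.gz``) or as a directory of DICOM CT
slices; structure masks as NIfTI label volumes or a DICOM RT Structure Set
rasterized onto a reference grid.  A treatment course is described by a JSON
*manifest* listing, in order, the per-fraction CBCT volumes grouped into plan
segments (a replan starts a new segment and resets the MQP reference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import nibabel as nib
import numpy as np
import pydicom

from .grids import Mask3D, Volume3D

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as float32 NIfTI with a diagonal affine.

    The affine encodes spacing on the diagonal and origin in the translation
    column, so write→read round-trips values, spacing, and origin exactly
    (values at float32 precision).
    """
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path, format: str | None = None) -> Volume3D:
    """Read a CT-number volume from NIfTI or a DICOM CT series directory.

    ``format`` may force ``"nifti"`` or ``"dicom"``; by default it is inferred
    from the path (directory ⇒ DICOM series).  DICOM stored values are mapped
    to HU via RescaleSlope/RescaleIntercept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    if format is None:
        format = "dicom" if path.is_dir() else "nifti"
    if format == "nifti":
        return _read_nifti_volume(path)
    if format == "dicom":
        return _read_dicom_series(path)
    raise ValueError(f"unknown volume format {format!r}")


def _read_nifti_volume(path: Path) -> Volume3D:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj).astype(np.float32)
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    if any(s == 0 for s in spacing):
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(affine[i, 3]) for i in range(3))
    return Volume3D(values, spacing, origin)


def _read_dicom_series(path: Path) -> Volume3D:
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() != ".json")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {path}")
    modality = getattr(slices[0], "Modality", "CT")
    if modality not in ("CT", "CBCT"):
        raise ValueError(f"non-HU modality {modality!r}; expected a CT/CBCT series")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) < 2:
        raise ValueError("DICOM series must contain at least 2 slices")
    dz = np.diff(zs)
    if np.ptp(dz) > 1e-3:
        raise ValueError(
            f"inconsistent slice spacing in DICOM series: gaps range "
            f"{dz.min():.4f}–{dz.max():.4f} mm"
        )
    first = slices[0]
    dy, dx = (float(v) for v in first.PixelSpacing)  # PixelSpacing = (row, col)
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    # DICOM slice arrays are (row=y, col=x); stack to (x, y, z)
    values = np.stack(planes, axis=-1).transpose(1, 0, 2).astype(np.float32)
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(zs[0]),
    )
    return Volume3D(values, (dx, dy, float(dz.mean())), origin)


# ---------------------------------------------------------------------------
# structure masks
# ---------------------------------------------------------------------------

def read_structure_mask(
    path: str | Path,
    structure: str | int = 1,
    reference: Volume3D | Mask3D | None = None,
) -> Mask3D:
    """Read a structure as a boolean mask.

    For a NIfTI label volume, ``structure`` is the integer label (default 1).
    For a DICOM RT Structure Set, ``structure`` is the ROI name and
    ``reference`` (the grid to rasterize onto) is required; contours are
    assigned to the nearest slice by z and filled with the even-odd rule.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        values = np.asarray(img.dataobj)
        label = int(structure) if not isinstance(structure, str) else 1
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in range(3))
        origin = tuple(float(affine[i, 3]) for i in range(3))
        return Mask3D(values == label, spacing, origin,
                      provenance={"source": str(path), "label": label})
    if reference is None:
        raise ValueError("rasterizing an RT Structure Set requires a reference grid")
    return _rasterize_rtstruct(path, str(structure), reference)


def _rasterize_rtstruct(path: Path, name: str, ref: Volume3D | Mask3D) -> Mask3D:
    from matplotlib.path import Path as MplPath

    ds = pydicom.dcmread(str(path))
    rois = {str(r.ROIName): int(r.ROINumber) for r in ds.StructureSetROISequence}
    if name not in rois:
        raise KeyError(
            f"structure {name!r} not found in {path.name}; available: {sorted(rois)}"
        )
    number = rois[name]
    contour_seq = None
    for rc in ds.ROIContourSequence:
        if int(rc.ReferencedROINumber) == number:
            contour_seq = getattr(rc, "ContourSequence", [])
            break
    if contour_seq is None:
        raise KeyError(f"structure {name!r} has no contours in {path.name}")

    nx, ny, nz = ref.shape
    sx, sy, sz = ref.spacing
    ox, oy, oz = ref.origin
    out = np.zeros(ref.shape, dtype=bool)
    # voxel-center coordinates of one axial plane
    xs = ox + np.arange(nx) * sx
    ys = oy + np.arange(ny) * sy
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    for contour in contour_seq:
        pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
        z = float(np.mean(pts[:, 2]))
        k = int(round((z - oz) / sz))
        if k < 0 or k >= nz:
            raise ValueError(
                f"contour at z={z:.2f} mm falls outside the reference grid"
            )
        inside = MplPath(pts[:, :2]).contains_points(centers).reshape(nx, ny)
        out[:, :, k] ^= inside  # XOR across contours on a slice = even-odd fill
    return Mask3D(out, ref.spacing, ref.origin,
                  provenance={"source": str(path), "structure": name})


def write_mask(mask: Mask3D, path: str | Path) -> Path:
    """Write a mask as a {0,1} uint8 NIfTI label volume."""
    path = Path(path)
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# course manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CourseEntry:
    fraction: int
    volume: str
    segment: int


@dataclass
class CourseManifest:
    """Ordered description of a treatment course's CBCT acquisitions.

    ``entries`` are (fraction, volume path, plan segment); fraction numbers
    strictly increase, segment ids are non-decreasing (a replan bumps the
    segment).  ``rect_orders`` maps segment id → fraction on which a re-CT
    was actually ordered for that segment (absent if none was).
    """

    patient_id: str
    entries: list[CourseEntry]
    external_mask: str | None = None
    ctv_mask: str | None = None
    rect_orders: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("manifest has no entries")
        fracs = [e.fraction for e in self.entries]
        if any(f <= 0 for f in fracs):
            raise ValueError("fraction numbers must be positive")
        if any(b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("fraction numbers must be strictly increasing")
        segs = [e.segment for e in self.entries]
        if any(b < a for a, b in zip(segs, segs[1:])):
            raise ValueError("segment ids must be non-decreasing")
        self.rect_orders = {int(k): int(v) for k, v in self.rect_orders.items()}

    @property
    def segments(self) -> list[int]:
        seen: list[int] = []
        for e in self.entries:
            if not seen or e.segment != seen[-1]:
                seen.append(e.segment)
        return seen

    def segment_entries(self, segment: int) -> list[CourseEntry]:
        return [e for e in self.entries if e.segment == segment]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "entries": [
                {"fraction": e.fraction, "volume": e.volume, "segment": e.segment}
                for e in self.entries
            ],
            "masks": {"external": self.external_mask, "ctv": self.ctv_mask},
            "rect_orders": {str(k): v for k, v in self.rect_orders.items()},
        }


def write_manifest(manifest: CourseManifest, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest.to_dict(), indent=2))
    return path


def read_manifest(path: str | Path) -> CourseManifest:
    path = Path(path)
    data = json.loads(path.read_text())
    masks = data.get("masks", {})
    return CourseManifest(
        patient_id=data["patient_id"],
        entries=[
            CourseEntry(int(e["fraction"]), e["volume"], int(e.get("segment", 0)))
            for e in data["entries"]
        ],
        external_mask=masks.get("external"),
        ctv_mask=masks.get("ctv"),
        rect_orders={int(k): int(v) for k, v in data.get("rect_orders", {}).items()},
    )


class Course:
    """A manifest plus access to its volumes and structure masks.

    Volumes may be held in memory (synthetic courses) or loaded lazily from
    paths relative to ``root`` (file-backed courses).
    """

    def __init__(
        self,
        manifest: CourseManifest,
        external: Mask3D | None = None,
        ctv: Mask3D | None = None,
        volumes: dict[int, Volume3D] | None = None,
        root: str | Path | None = None,
    ) -> None:
        self.manifest = manifest
        self.external = external
        self.ctv = ctv
        self._volumes = dict(volumes or {})
        self.root = Path(root) if root is not None else None

    def volume(self, fraction: int) -> Volume3D:
        if fraction in self._volumes:
            return self._volumes[fraction]
        entry = next((e for e in self.manifest.entries if e.fraction == fraction), None)
        if entry is None:
            raise KeyError(f"no CBCT at fraction {fraction}")
        path = Path(entry.volume)
        if self.root is not None and not path.is_absolute():
            path = self.root / path
        return read_volume(path)

    def fractions(self) -> list[int]:
        return [e.fraction for e in self.manifest.entries]


def load_course(manifest_path: str | Path) -> Course:
    """Load a file-backed course; mask paths resolve relative to the manifest."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    root = manifest_path.parent

    def _mask(rel: str | None) -> Mask3D | None:
        if rel is None:
            return None
        p = Path(rel)
        if not p.is_absolute():
            p = root / p
        return read_structure_mask(p)

    return Course(
        manifest,
        external=_mask(manifest.external_mask),
        ctv=_mask(manifest.ctv_mask),
        root=root,
    )
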