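"""Synthetic head-and-neck CBCT course generator.

Produces CT-number volume courses with programmable anatomy change so the
gamma/MQP/decision pipeline is testable end to end without clinical data.
The phantom is an elliptical soft-tissue neck cylinder containing a bony
spine with a low-density canal and an air-filled airway; a mid-neck cylinder
stands in for the high-dose CTV that axially limits the analysis mask.

Weight loss is modelled as bilateral lateral erosion of the soft-tissue
surface: at cumulative erosion depth d, each lateral side recedes by d/2, so
the external contour's total lateral width shrinks by d millimetres.  Ground
truth mirrors the clinical review trigger — a simulated re-CT order is
placed at the first CBCT fraction where d reaches 10 mm (the "external
contour differences of 1 cm or more" guideline).

Per-fraction image degradation adds Gaussian HU noise, a small random rigid
setup shift, and optional phenomenological artifacts.  Ring artifacts are
scanner-frame patterns fixed in position across fractions (detector-gain
rings recur at the same image location) with only their amplitude jittering
fraction to fraction; streaks are radial spokes with per-fraction random
orientation.  No projection/reconstruction physics is simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import AIR_HU, Mask3D, Volume3D
from .io import Course, CourseEntry, CourseManifest, write_manifest, write_mask, write_volume

HU_MIN, HU_MAX = -1024.0, 3071.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue HU of the static neck phantom."""

    shape: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    neck_semi_axes: tuple[float, float] = (65.0, 80.0)  # (x, y) mm
    soft_tissue_hu: float = 40.0
    spine_radius: float = 12.0
    spine_center_y: float = 35.0
    bone_hu: float = 800.0
    canal_radius: float = 4.0
    canal_hu: float = 0.0
    airway_radius: float = 8.0
    airway_center_y: float = -30.0
    background_hu: float = AIR_HU
    edge_blur_mm: float = 8.0
    ctv_radius: float = 20.0
    ctv_center: tuple[float, float] = (20.0, 0.0)  # (x, y) mm
    ctv_z_slices: tuple[int, int] = (16, 31)  # inclusive

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        sx, sy, sz = self.spacing
        a, b = self.neck_semi_axes
        if 2 * a >= nx * sx or 2 * b >= ny * sy:
            raise ValueError("neck ellipse does not fit inside the grid")
        z0, z1 = self.ctv_z_slices
        if not (0 <= z0 <= z1 < nz):
            raise ValueError("CTV z-slice range outside the grid")
        for hu in (self.soft_tissue_hu, self.bone_hu, self.canal_hu, self.background_hu):
            if not HU_MIN <= hu <= HU_MAX:
                raise ValueError(f"HU value {hu} outside [{HU_MIN}, {HU_MAX}]")

    def origin(self) -> tuple[float, float, float]:
        # grid centered on the phantom axis
        return tuple(-(n - 1) / 2.0 * s for n, s in zip(self.shape, self.spacing))


@dataclass(frozen=True)
class ArtifactSpec:
    """Phenomenological CBCT artifact settings.

    ``ring_amplitude`` is bounded at 100 HU, the magnitude of CT-number
    perturbation that CBCT artifacts are reported to reach.
    """

    ring_amplitude: float = 0.0
    ring_period_mm: float = 30.0
    ring_amplitude_jitter: float = 0.05  # fractional per-fraction gain drift
    streaks: bool = False
    streak_amplitude: float = 50.0
    n_streaks: int = 12

    def __post_init__(self) -> None:
        if not 0 <= self.ring_amplitude <= 100.0:
            raise ValueError("ring amplitude must lie in [0, 100] HU")
        if self.streak_amplitude < 0:
            raise ValueError("streak amplitude must be >= 0")


@dataclass(frozen=True)
class CourseSpec:
    """Parameters of one synthetic treatment course.

    ``cbct_fractions`` of None means a CBCT every fraction (the daily-IGRT
    arm of the guideline); pass an explicit list for sparser schedules.
    ``change_onset`` of None generates a stable (non-changing) course.
    """

    n_fractions: int = 30
    cbct_fractions: tuple[int, ...] | None = None
    change_onset: int | None = None
    erosion_rate: float = 2.0  # mm of total width loss per fraction after onset
    noise_sigma: float = 20.0  # HU
    jitter_sigma: float = 0.5  # mm per axis
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.erosion_rate < 0 or self.noise_sigma < 0 or self.jitter_sigma < 0:
            raise ValueError("rates and sigmas must be >= 0")
        fracs = self.schedule()
        if self.change_onset is not None and not (
            fracs[0] <= self.change_onset <= fracs[-1]
        ):
            raise ValueError("change onset must fall within the CBCT-covered range")

    def schedule(self) -> tuple[int, ...]:
        if self.cbct_fractions is not None:
            fr = tuple(int(f) for f in self.cbct_fractions)
            if any(b <= a for a, b in zip(fr, fr[1:])) or fr[0] < 1 or fr[-1] > self.n_fractions:
                raise ValueError("cbct_fractions must be strictly increasing within the course")
            return fr
        return tuple(range(1, self.n_fractions + 1))


@dataclass
class GroundTruth:
    """Programmed change and the simulated re-CT order it implies."""

    onset_fraction: int | None
    erosion_depth_mm: dict[int, float]  # per CBCT fraction, cumulative
    order_fraction: int | None  # first CBCT fraction with depth >= 10 mm

    def to_dict(self) -> dict:
        return {
            "onset_fraction": self.onset_fraction,
            "erosion_depth_mm": {str(k): v for k, v in self.erosion_depth_mm.items()},
            "order_fraction": self.order_fraction,
        }


ORDER_DEPTH_MM = 10.0


def _grid_coords(spec: PhantomSpec):
    ox, oy, oz = spec.origin()
    xs = ox + np.arange(spec.shape[0]) * spec.spacing[0]
    ys = oy + np.arange(spec.shape[1]) * spec.spacing[1]
    return np.meshgrid(xs, ys, indexing="ij")


def _soft_tissue_ellipse(spec: PhantomSpec, erosion_depth: float) -> np.ndarray:
    a = spec.neck_semi_axes[0] - erosion_depth / 2.0
    b = spec.neck_semi_axes[1]
    gx, gy = _grid_coords(spec)
    return (gx / a) ** 2 + (gy / b) ** 2 <= 1.0


def _check_erosion_valid(spec: PhantomSpec, erosion_depth: float) -> None:
    a = spec.neck_semi_axes[0] - erosion_depth / 2.0
    b = spec.neck_semi_axes[1]
    # spine and airway circles must stay strictly inside the eroded ellipse
    for cy, r, label in (
        (spec.spine_center_y, spec.spine_radius, "spine"),
        (spec.airway_center_y, spec.airway_radius, "airway"),
    ):
        if a <= r or (r / a) ** 2 + ((abs(cy) + r) / b) ** 2 >= 1.0:
            raise ValueError(
                f"erosion depth {erosion_depth:.1f} mm reaches the {label}; "
                "phantom spec invalid at this depth"
            )


def generate_anatomy(spec: PhantomSpec, erosion_depth: float = 0.0):
    """Noise-free phantom volume plus external and CTV masks.

    Returns ``(volume, external_mask, ctv_mask)``.  ``erosion_depth`` > 0
    shrinks the lateral soft-tissue boundary (see module docstring).
    """
    _check_erosion_valid(spec, erosion_depth)
    gx, gy = _grid_coords(spec)
    soft2d = _soft_tissue_ellipse(spec, erosion_depth)
    spine2d = gx**2 + (gy - spec.spine_center_y) ** 2 <= spec.spine_radius**2
    canal2d = gx**2 + (gy - spec.spine_center_y) ** 2 <= spec.canal_radius**2
    airway2d = gx**2 + (gy - spec.airway_center_y) ** 2 <= spec.airway_radius**2

    plane = np.full(spec.shape[:2], spec.background_hu)
    plane[soft2d] = spec.soft_tissue_hu
    plane[spine2d] = spec.bone_hu
    plane[canal2d] = spec.canal_hu
    plane[airway2d] = AIR_HU

    if spec.edge_blur_mm > 0:
        # tissue-interface smoothing: real necks ramp from air through skin and
        # fat over ~1 cm and the scanner PSF blurs further; without it, binary
        # HU steps make every sub-voxel setup shift a spurious gamma failure
        # under the voxel-center DTA search
        plane = ndimage.gaussian_filter(
            plane, [spec.edge_blur_mm / s for s in spec.spacing[:2]]
        )
    values = np.repeat(plane[:, :, None], spec.shape[2], axis=2)
    origin = spec.origin()
    vol = Volume3D(values.astype(np.float32), spec.spacing, origin)

    external = np.repeat(soft2d[:, :, None], spec.shape[2], axis=2)
    cx, cy = spec.ctv_center
    ctv2d = (gx - cx) ** 2 + (gy - cy) ** 2 <= spec.ctv_radius**2
    ctv = np.zeros(spec.shape, dtype=bool)
    z0, z1 = spec.ctv_z_slices
    ctv[:, :, z0 : z1 + 1] = ctv2d[:, :, None]
    return (
        vol,
        Mask3D(external, spec.spacing, origin, provenance={"structure": "External"}),
        Mask3D(ctv, spec.spacing, origin, provenance={"structure": "CTV"}),
    )


def erosion_depth_at(fraction: int, onset: int | None, rate: float) -> float:
    """Cumulative erosion depth (mm) at a fraction; 0 before onset."""
    if onset is None or fraction < onset:
        return 0.0
    return rate * (fraction - onset)


def apply_weight_loss(
    spec: PhantomSpec, fraction: int, onset: int | None, rate: float
) -> Volume3D:
    """Phantom volume at a fraction under the programmed erosion schedule."""
    if fraction < 1:
        raise ValueError("fraction must be >= 1")
    vol, _, _ = generate_anatomy(spec, erosion_depth_at(fraction, onset, rate))
    return vol


def _ring_pattern(spec: PhantomSpec, art: ArtifactSpec) -> np.ndarray:
    gx, gy = _grid_coords(spec)
    r = np.hypot(gx, gy)
    return np.sin(2.0 * np.pi * r / art.ring_period_mm)


def degrade(
    vol: Volume3D,
    noise_sigma: float,
    jitter_sigma: float,
    artifacts: ArtifactSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    spec: PhantomSpec | None = None,
) -> Volume3D:
    """Apply setup jitter, artifacts, and HU noise; reproducible from seed.

    Order mimics acquisition: the patient shifts (rigid translation,
    trilinear resample, air fill), the scanner stamps its artifacts in the
    image frame, and stochastic HU noise is added last.
    """
    if noise_sigma < 0 or jitter_sigma < 0:
        raise ValueError("sigmas must be >= 0")
    # independent substreams so that toggling one degradation (e.g. artifacts
    # on/off) leaves the realizations of the others bit-identical
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    jitter_rng, artifact_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    out = vol.values.astype(np.float64)

    shift_mm = jitter_rng.normal(0.0, jitter_sigma, 3) if jitter_sigma > 0 else np.zeros(3)
    if np.any(shift_mm != 0.0):
        idx = np.indices(vol.shape, dtype=float)
        coords = [idx[a] - shift_mm[a] / vol.spacing[a] for a in range(3)]
        out = ndimage.map_coordinates(out, coords, order=1, mode="constant", cval=AIR_HU)

    if artifacts is not None and artifacts.ring_amplitude > 0:
        if spec is None:
            raise ValueError("ring artifacts require the phantom spec (scanner frame)")
        amp = artifacts.ring_amplitude * (
            1.0 + artifacts.ring_amplitude_jitter * artifact_rng.standard_normal()
        )
        amp = float(np.clip(amp, 0.0, 100.0))
        out = out + amp * _ring_pattern(spec, artifacts)[:, :, None]

    if artifacts is not None and artifacts.streaks:
        if spec is None:
            raise ValueError("streak artifacts require the phantom spec")
        gx, gy = _grid_coords(spec)
        theta = np.arctan2(gy, gx)
        phase = artifact_rng.uniform(0, 2 * np.pi)
        out = out + artifacts.streak_amplitude * np.cos(
            artifacts.n_streaks * theta + phase
        )[:, :, None]

    if noise_sigma > 0:
        out = out + noise_rng.normal(0.0, noise_sigma, vol.shape)

    return Volume3D(out.astype(np.float32), vol.spacing, vol.origin)


def generate_course(
    spec: PhantomSpec,
    course: CourseSpec,
    out_dir: str | Path | None = None,
    patient_id: str = "phantom",
) -> tuple[Course, GroundTruth]:
    """One full synthetic course: volumes, masks, manifest, ground truth.

    With ``out_dir`` the volumes/masks are written as NIfTI and the manifest
    and ground truth as JSON (a fully file-backed course); otherwise volumes
    stay in memory.  All randomness derives from ``course.seed``.
    """
    schedule = course.schedule()
    _, external, ctv = generate_anatomy(spec)

    depths = {
        f: erosion_depth_at(f, course.change_onset, course.erosion_rate)
        for f in schedule
    }
    order = next((f for f in schedule if depths[f] >= ORDER_DEPTH_MM), None)
    gt = GroundTruth(course.change_onset, depths, order)

    ss = np.random.SeedSequence(entropy=course.seed)
    child_seeds = ss.spawn(len(schedule))

    volumes: dict[int, Volume3D] = {}
    for f, child in zip(schedule, child_seeds):
        anat = apply_weight_loss(spec, f, course.change_onset, course.erosion_rate)
        volumes[f] = degrade(
            anat,
            course.noise_sigma,
            course.jitter_sigma,
            course.artifacts,
            seed=child,
            spec=spec,
        )

    entries = [CourseEntry(f, f"cbct_f{f:02d}.nii.gz", 0) for f in schedule]
    rect_orders = {0: order} if order is not None else {}
    manifest = CourseManifest(
        patient_id=patient_id,
        entries=entries,
        external_mask="external.nii.gz",
        ctv_mask="ctv.nii.gz",
        rect_orders=rect_orders,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for f, vol in volumes.items():
            write_volume(vol, out_dir / f"cbct_f{f:02d}.nii.gz")
        write_mask(external, out_dir / "external.nii.gz")
        write_mask(ctv, out_dir / "ctv.nii.gz")
        write_manifest(manifest, out_dir / "manifest.json")
        payload = gt.to_dict()
        payload["seed"] = course.seed
        payload["course_spec"] = _course_spec_dict(course)
        (out_dir / "ground_truth.json").write_text(json.dumps(payload, indent=2))
        return Course(manifest, external, ctv, volumes, root=out_dir), gt

    return Course(manifest, external, ctv, volumes), gt


def _course_spec_dict(course: CourseSpec) -> dict:
    d = asdict(course)
    d["cbct_fractions"] = list(course.schedule())
    return d


@dataclass(frozen=True)
class CohortRanges:
    """Per-patient parameter ranges for cohort generation."""

    onset_range: tuple[int, int] = (10, 20)
    erosion_rate: float = 2.0
    noise_sigma: float = 20.0
    jitter_sigma: float = 0.5
    n_fractions: int = 30
    artifacts: ArtifactSpec = field(default_factory=ArtifactSpec)


def generate_cohort(
    n_changers: int,
    n_stable: int,
    ranges: CohortRanges | None = None,
    master_seed: int = 0,
    spec: PhantomSpec | None = None,
) -> list[tuple[Course, GroundTruth]]:
    """Reproducible cohort of changing and stable synthetic patients.

    Changers draw a change onset uniformly from ``ranges.onset_range``
    (inclusive); stable patients share the noise model but never change.
    The entire cohort is a pure function of ``master_seed``.
    """
    if n_changers < 0 or n_stable < 0:
        raise ValueError("cohort counts must be >= 0")
    ranges = ranges or CohortRanges()
    spec = spec or PhantomSpec()
    master = np.random.SeedSequence(entropy=master_seed)
    out: list[tuple[Course, GroundTruth]] = []
    lo, hi = ranges.onset_range
    for i, child in enumerate(master.spawn(n_changers + n_stable)):
        rng = np.random.default_rng(child)
        seed = int(rng.integers(0, 2**31 - 1))
        changer = i < n_changers
        cs = CourseSpec(
            n_fractions=ranges.n_fractions,
            change_onset=int(rng.integers(lo, hi + 1)) if changer else None,
            erosion_rate=ranges.erosion_rate,
            noise_sigma=ranges.noise_sigma,
            jitter_sigma=ranges.jitter_sigma,
            artifacts=ranges.artifacts,
            seed=seed,
        )
        kind = "changer" if changer else "stable"
        out.append(generate_course(spec, cs, patient_id=f"{kind}-{i:02d}"))
    return out
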