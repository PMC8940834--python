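"""Synthetic cardiac phantoms and parallel-beam projection of SPECT-MPI data.

The phantom is a 3D activity map containing a half-ellipsoidal left-ventricular
(LV) myocardial shell with optional perfusion defects and an optional hot
liver blob.  It stands in for clinical acquisitions: projections are formed
with a parallel-beam line-integral model (no attenuation, scatter or
depth-dependent resolution) over a 180-degree RAO-to-LPO arc, and Poisson
counting noise is added at a configurable standard-dose count level.

Conventions
-----------
* Volumes are indexed ``(x, y, z)`` with ``z`` the scanner axis.  Detector
  rows map to ``z``, detector columns to the rotated in-plane coordinate.
* The projector is voxel-driven: each voxel splats onto at most two adjacent
  detector columns with linear-interpolation weights, and contributes its
  activity times the voxel edge length (mm) to the line integral.  The
  backprojector used in reconstruction is the exact transpose.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

__all__ = [
    "Defect",
    "LVParams",
    "LiverSpec",
    "Phantom",
    "AcquisitionGeometry",
    "ProjectionSet",
    "ParallelProjector",
    "make_phantom",
    "project",
    "sample_counts",
    "derive_seed",
]

DOSE_PRESETS = (1.0, 0.5, 0.25, 0.125)


def derive_seed(master_seed: int, stream: str) -> int:
    """Deterministically derive a per-stage seed (< 2**31) from a master seed.

    Named substreams (``"phantom"``, ``"poisson"``, ``"thinning"``, ...) keep
    every random stage independently re-runnable from one master seed.
    """
    h = zlib.crc32(stream.encode("utf-8"))
    return (int(master_seed) * 1_000_003 + h) % (2**31 - 1)


@dataclass(frozen=True)
class Defect:
    """Angular/axial perfusion defect carved into the LV shell.

    ``theta_center_deg``/``theta_width_deg`` select a circumferential sector in
    the short-axis plane (angle measured by atan2 in the plane perpendicular
    to the LV long axis); ``axial_span`` is a (lo, hi) fraction of the
    apex-to-base extent; ``severity`` in [0, 1] multiplies shell activity by
    ``1 - severity`` inside the span.
    """

    theta_center_deg: float = 0.0
    theta_width_deg: float = 60.0
    axial_span: tuple[float, float] = (0.3, 0.7)
    severity: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"defect severity must be in [0, 1], got {self.severity}")
        lo, hi = self.axial_span
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError(f"axial_span must satisfy 0 <= lo < hi <= 1, got {self.axial_span}")


@dataclass(frozen=True)
class LVParams:
    """Geometry of the half-ellipsoidal LV shell (all lengths in mm)."""

    center_voxel: tuple[float, float, float] = (31.5, 31.5, 31.5)
    long_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    outer_semi_axes_mm: tuple[float, float, float] = (35.0, 35.0, 50.0)
    wall_thickness_mm: float = 12.0


@dataclass(frozen=True)
class LiverSpec:
    """Optional ellipsoidal hot blob mimicking hepatic uptake."""

    center_voxel: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float] = (25.0, 25.0, 20.0)
    activity: float = 1.5


@dataclass
class Phantom:
    """3D activity map with known LV-shell and defect ground truth.

    ``activity`` is relative activity (arbitrary units, nonnegative).
    ``shell_mask`` marks the myocardial shell; ``defect_masks`` are the exact
    boolean masks used to carve each defect, so ground truth round-trips.
    """

    activity: np.ndarray
    voxel_mm: float
    lv_params: LVParams
    defects: list[Defect]
    seed: int
    shell_mask: np.ndarray = field(repr=False, default=None)
    defect_masks: list[np.ndarray] = field(repr=False, default_factory=list)
    liver_mask: np.ndarray | None = field(repr=False, default=None)

    @property
    def grid_size(self) -> tuple[int, int, int]:
        return self.activity.shape


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Dual-head cardiac SPECT orbit: evenly spaced views over a 180-deg arc."""

    n_views: int = 32
    arc_deg: float = 180.0
    start_deg: float = -45.0  # RAO start, rotating to LPO
    detector_rows: int = 64
    detector_cols: int = 64
    pixel_mm: float = 6.4

    def __post_init__(self) -> None:
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")

    @property
    def view_angles_deg(self) -> np.ndarray:
        return self.start_deg + self.arc_deg * np.arange(self.n_views) / self.n_views

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_views, self.detector_rows, self.detector_cols)


@dataclass
class ProjectionSet:
    """Counts (and/or noiseless expectations) on a views x rows x cols grid."""

    geometry: AcquisitionGeometry
    counts: np.ndarray | None = None
    expected: np.ndarray | None = None
    dose_fraction: float = 1.0
    gate: int | None = None
    n_gates: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for arr, name in ((self.counts, "counts"), (self.expected, "expected")):
            if arr is None:
                continue
            if arr.shape != self.geometry.shape:
                raise ValueError(
                    f"{name} shape {arr.shape} does not match geometry {self.geometry.shape}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.counts is not None and not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be an integer array")
        if not 0.0 < self.dose_fraction <= 1.0:
            raise ValueError("dose_fraction must be in (0, 1]")

    @property
    def total_counts(self) -> int:
        if self.counts is None:
            raise ValueError("counts not set")
        return int(self.counts.sum())

    def with_counts(self, counts: np.ndarray, **changes) -> "ProjectionSet":
        out = replace(self, counts=counts)
        for k, v in changes.items():
            setattr(out, k, v)
        return out


def _lv_frame(long_axis: tuple[float, float, float]) -> np.ndarray:
    """Orthonormal frame with the third row along the LV long axis."""
    w = np.asarray(long_axis, dtype=float)
    n = np.linalg.norm(w)
    if n == 0:
        raise ValueError("long_axis must be a nonzero vector")
    w = w / n
    helper = np.array([1.0, 0.0, 0.0]) if abs(w[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(helper, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.stack([u, v, w])


def make_phantom(
    lv_params: LVParams | None = None,
    defects: list[Defect] | None = None,
    grid_size: int | tuple[int, int, int] = 64,
    voxel_mm: float = 6.4,
    seed: int = 0,
    shell_activity: float = 1.0,
    background_activity: float = 0.0,
    liver: LiverSpec | None = None,
) -> Phantom:
    """Build an LV-shell phantom with optional defects and liver blob.

    The shell is the region between two confocal half-ellipsoids (outer
    semi-axes minus wall thickness gives the inner ones), truncated at the
    base plane (apex side kept).  A defect with severity ``s`` multiplies
    shell activity by ``1 - s`` inside its angular/axial span only.
    Deterministic for fixed inputs; ``seed`` is recorded for provenance of
    downstream noise stages.
    """
    lv_params = lv_params if lv_params is not None else LVParams()
    defects = list(defects) if defects else []
    if isinstance(grid_size, int):
        grid_size = (grid_size,) * 3
    if min(grid_size) < 16:
        raise ValueError("grid_size must be >= 16 per axis")
    a, b, c = lv_params.outer_semi_axes_mm
    t = lv_params.wall_thickness_mm
    if t >= min(a, b, c):
        raise ValueError(
            f"wall thickness {t} mm must be smaller than every outer semi-axis {lv_params.outer_semi_axes_mm}"
        )

    nx, ny, nz = grid_size
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = lv_params.center_voxel
    # mm coordinates relative to the LV center
    rel = np.stack(
        [(ix - cx) * voxel_mm, (iy - cy) * voxel_mm, (iz - cz) * voxel_mm]
    )
    frame = _lv_frame(lv_params.long_axis)
    local = np.tensordot(frame, rel, axes=(1, 0))  # (u, v, w) coords, mm
    u, v, w = local

    def ellipsoid_q(sa: float, sb: float, sc: float) -> np.ndarray:
        return (u / sa) ** 2 + (v / sb) ** 2 + (w / sc) ** 2

    outer = ellipsoid_q(a, b, c) <= 1.0
    inner = ellipsoid_q(a - t, b - t, c - t) < 1.0
    apex_side = w <= 0.0  # truncation at the base plane
    shell = outer & ~inner & apex_side

    activity = np.full(grid_size, float(background_activity))
    activity[shell] = shell_activity

    # defect spans: theta in the short-axis (u, v) plane, axial fraction of
    # the apex (w = -c) to base (w = 0) extent
    theta = np.degrees(np.arctan2(v, u))
    axial_frac = 1.0 + w / c  # 0 at apex tip, 1 at base plane
    defect_masks: list[np.ndarray] = []
    for d in defects:
        dtheta = (theta - d.theta_center_deg + 180.0) % 360.0 - 180.0
        in_theta = np.abs(dtheta) <= d.theta_width_deg / 2.0
        lo, hi = d.axial_span
        in_axial = (axial_frac >= lo) & (axial_frac <= hi)
        mask = shell & in_theta & in_axial
        activity[mask] *= 1.0 - d.severity
        defect_masks.append(mask)

    liver_mask = None
    if liver is not None:
        lx, ly, lz = liver.center_voxel
        la, lb, lc = liver.semi_axes_mm
        q = (
            ((ix - lx) * voxel_mm / la) ** 2
            + ((iy - ly) * voxel_mm / lb) ** 2
            + ((iz - lz) * voxel_mm / lc) ** 2
        )
        liver_mask = q <= 1.0
        activity[liver_mask] = np.maximum(activity[liver_mask], liver.activity)

    return Phantom(
        activity=activity,
        voxel_mm=voxel_mm,
        lv_params=lv_params,
        defects=defects,
        seed=seed,
        shell_mask=shell,
        defect_masks=defect_masks,
        liver_mask=liver_mask,
    )


class ParallelProjector:
    """Parallel-beam projector/backprojector pair for one acquisition geometry.

    For each view angle phi the in-plane coordinate of voxel (x, y) on the
    detector is ``u = (x - cx) cos phi + (y - cy) sin phi + (cols - 1)/2``;
    the voxel's activity is splatted onto columns ``floor(u)`` and
    ``floor(u) + 1`` with linear weights and scaled by the voxel edge length.
    Rows copy the z index directly (detector_rows must equal nz).  The
    per-view operation is stored as a sparse matrix so the backprojector is
    the exact matrix transpose — the adjoint property iterative
    reconstruction relies on.
    """

    def __init__(self, grid_size: tuple[int, int, int], geometry: AcquisitionGeometry, voxel_mm: float):
        nx, ny, nz = grid_size
        if geometry.detector_rows != nz:
            raise ValueError(
                f"detector_rows ({geometry.detector_rows}) must equal grid z size ({nz})"
            )
        if abs(voxel_mm - geometry.pixel_mm) > 1e-9:
            raise ValueError("phantom voxel size and detector pixel size must match")
        self.grid_size = grid_size
        self.geometry = geometry
        self.voxel_mm = voxel_mm
        self._mats: list[sparse.csr_matrix] = []
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        ccol = (geometry.detector_cols - 1) / 2.0
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        xs = xs.ravel().astype(float)
        ys = ys.ravel().astype(float)
        n_xy = nx * ny
        for phi_deg in geometry.view_angles_deg:
            phi = np.radians(phi_deg)
            ucoord = (xs - cx) * np.cos(phi) + (ys - cy) * np.sin(phi) + ccol
            i0 = np.floor(ucoord).astype(int)
            w1 = ucoord - i0
            rows_idx = np.concatenate([i0, i0 + 1])
            cols_idx = np.concatenate([np.arange(n_xy)] * 2)
            weights = np.concatenate([1.0 - w1, w1]) * voxel_mm
            ok = (rows_idx >= 0) & (rows_idx < geometry.detector_cols)
            mat = sparse.csr_matrix(
                (weights[ok], (rows_idx[ok], cols_idx[ok])),
                shape=(geometry.detector_cols, n_xy),
            )
            self._mats.append(mat)

    def forward(self, volume: np.ndarray, view_indices: np.ndarray | None = None) -> np.ndarray:
        """Line integrals: volume (nx, ny, nz) -> projections (n_views, rows, cols)."""
        nx, ny, nz = self.grid_size
        flat = volume.reshape(nx * ny, nz)
        idx = list(range(len(self._mats))) if view_indices is None else list(view_indices)
        out = np.empty((len(idx), self.geometry.detector_rows, self.geometry.detector_cols))
        for k, v in enumerate(idx):
            # (cols, nz) -> transpose to (rows=z, cols)
            out[k] = (self._mats[v] @ flat).T
        return out

    def back(self, projections: np.ndarray, view_indices: np.ndarray | None = None) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        nx, ny, nz = self.grid_size
        acc = np.zeros((nx * ny, nz))
        idx = range(len(self._mats)) if view_indices is None else view_indices
        for k, v in enumerate(idx):
            acc += self._mats[v].T @ projections[k].T
        return acc.reshape(nx, ny, nz)


def project(phantom: Phantom, geometry: AcquisitionGeometry | None = None) -> ProjectionSet:
    """Noiseless line-integral projections of a phantom (counts unset).

    The result is linear in the phantom activity; ``expected`` holds the
    per-pixel means in activity-mm units.
    """
    geometry = geometry if geometry is not None else AcquisitionGeometry(
        detector_rows=phantom.grid_size[2],
        detector_cols=phantom.grid_size[1],
        pixel_mm=phantom.voxel_mm,
    )
    projector = ParallelProjector(phantom.grid_size, geometry, phantom.voxel_mm)
    expected = projector.forward(phantom.activity)
    return ProjectionSet(
        geometry=geometry,
        expected=expected,
        dose_fraction=1.0,
        provenance={"seed": phantom.seed, "stage": "project"},
    )


def sample_counts(proj: ProjectionSet, total_counts: float, seed: int) -> ProjectionSet:
    """Draw Poisson counts after rescaling the expected grid to a total count level.

    The expected grid is rescaled so its sum equals ``total_counts`` (the
    standard-dose count level of the whole projection set), then each bin is
    drawn independently from a Poisson law with that mean.  Reproducible for
    a fixed seed.
    """
    if proj.expected is None:
        raise ValueError("projection set has no expected means to sample from")
    if total_counts <= 0:
        raise ValueError("total_counts must be > 0")
    s = proj.expected.sum()
    if s <= 0:
        raise ValueError("expected projections are all zero; nothing to sample")
    lam = proj.expected * (total_counts / s)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(np.int64)
    return ProjectionSet(
        geometry=proj.geometry,
        counts=counts,
        expected=lam,
        dose_fraction=1.0,
        provenance={**proj.provenance, "seed": seed, "stage": "sample_counts"},
    )
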