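"""Synthetic 3D capillary/fibre phantoms with exactly known ground truth.

The generator emulates confocal fields of view of transversely sectioned
skeletal muscle: a 387.5 × 387.5 × 100 µm box imaged at 0.76 µm pixels and
1 µm optical steps, containing a capillary network dominated by fibre-axis
(z) aligned "trunks" with transverse side branches, plus prism-like fibre
territories. Every generated network is delivered both as an exact vector
graph (the ground truth all metrics are computed from, via the same
``capmetrics`` code path the pipeline uses) and as a rasterised image stack.

Prescribable setpoints:

- ``target_LVm``: capillary length per tissue volume — hit within 2% by
  construction (a final branch-free filler trunk is trimmed to the residual).
- ``target_NV``: branch points per volume — hit exactly; every side branch
  creates exactly one degree-3 node.
- ``tortuosity_amplitude``: sinusoidal perturbation amplitude; the exact
  exterior-angle tortuosity is strictly monotone in it and can be calibrated
  to a setpoint by root finding (:func:`calibrate_tortuosity_amplitude`).
- ``orientation_kappa``: concentration of trunk directions about the fibre
  axis (Watson-type distribution); anisotropy is monotone in it.

Tubes are placed with a minimum clearance of one diameter plus a margin so
capillaries only meet at branch points — networks that touch elsewhere would
fuse at rasterisation and corrupt the prescribed branch count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.spatial import cKDTree
from skimage import measure

from .capmetrics import FibreModel, FibreSection, compute_morphometry
from .errors import InfeasibleSpecError, ThinStructureWarning
from .fibremorph import CHANNELS, FIBRE_TYPES, SectionSet
from .graph import CapillaryGraph, polyline_length
from .reconstruct import VoxelVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_capillary_network",
    "rasterise_network",
    "generate_fibre_phantom",
    "generate_serial_sections",
    "calibrate_tortuosity_amplitude",
    "nv_for_meancap",
]

_SAMPLE_STEP = 2.0     # µm between polyline vertices at generation
_WAVELENGTH = 40.0     # µm, perturbation wavelength (≫ the 5 µm vectorisation step)
_BRANCH_LEN = (15.0, 35.0)  # µm, side-branch length range


@dataclass
class PhantomSpec:
    """Parameters of one synthetic field of view.

    Defaults reproduce the standard study conditions: field geometry and voxel
    size of the confocal protocol, and capillary density setpoints at the
    control-group diaphragm values of the reference morphometry table.
    The capillary radius (2.5 µm, a typical muscle capillary calibre) and the
    noise level are free parameters the imaging protocol does not pin down.
    """

    field_size: tuple[float, float, float] = (387.5, 387.5, 100.0)
    voxel_size: tuple[float, float, float] = (0.76, 0.76, 1.0)
    target_LVm: float = 598.75e-6   # µm⁻²
    target_NV: float = 1.37e-6      # µm⁻³
    tortuosity_amplitude: float = 1.5  # µm
    orientation_kappa: float = 3.0
    capillary_radius: float = 2.5   # µm
    z_shrinkage: float = 1.0
    noise_sd: float = 0.0           # additive Gaussian on 8-bit intensities
    fibre_diameter_mean: float = 55.0  # µm
    fibre_diameter_sd: float = 8.0
    n_fibres: int = 25
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.field_size) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("field and voxel sizes must be strictly positive")
        if self.target_LVm <= 0 or self.target_NV < 0:
            raise ValueError("length density must be positive, branch density non-negative")
        if not (0 < self.z_shrinkage <= 1):
            raise ValueError(f"z_shrinkage must be in (0, 1], got {self.z_shrinkage}")
        if self.capillary_radius <= 0 or self.tortuosity_amplitude < 0 or self.orientation_kappa < 0:
            raise ValueError("radius must be positive; amplitude and kappa non-negative")
        if self.fibre_diameter_mean <= 0 or self.fibre_diameter_sd < 0 or self.n_fibres < 1:
            raise ValueError("invalid fibre parameters")

    @property
    def volume(self) -> float:
        fx, fy, fz = self.field_size
        return fx * fy * fz


@dataclass
class GroundTruth:
    """Exact vector-level truth of one phantom field.

    The ``true_*`` metrics are the ``capmetrics`` outputs on ``graph``
    (standard 5-µm vectorisation) — the oracle the pipeline is judged against.
    """

    graph: CapillaryGraph
    true_LVm: float
    true_NV: float
    true_tortuosity: float
    true_anisotropy: float
    true_MeanCap: float
    fibre_contours: FibreModel | None = None
    fibre_types: dict[int, str] | None = None
    imcl_true: dict[int, float] | None = None

    def as_dict(self) -> dict:
        return {
            "true_LVm": self.true_LVm,
            "true_NV": self.true_NV,
            "true_tortuosity": self.true_tortuosity,
            "true_anisotropy": self.true_anisotropy,
            "true_MeanCap": self.true_MeanCap,
        }


# --------------------------------------------------------------- direction sampling
def _watson_axis_direction(rng: np.random.Generator, kappa: float) -> np.ndarray:
    """Unit vector from an axially symmetric Watson-type density ∝ exp(κ·uz²)."""
    while True:
        t = rng.uniform(0.0, 1.0)  # |cos θ|; orientations are sign-symmetric
        if rng.uniform() < np.exp(kappa * (t * t - 1.0)):
            break
    phi = rng.uniform(0.0, 2 * np.pi)
    s = np.sqrt(max(0.0, 1.0 - t * t))
    return np.array([s * np.cos(phi), s * np.sin(phi), t])


def _isotropic_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _perturb(points: np.ndarray, u: np.ndarray, amplitude: float,
             rng: np.random.Generator, pin_start: bool = False) -> np.ndarray:
    """Sinusoidal random-phase transverse displacement of a straight polyline."""
    if amplitude == 0 or len(points) < 3:
        return points
    e1, e2 = _orthonormal_frame(u)
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(points, axis=0), axis=1))])
    ph1, ph2 = (0.0, 0.0) if pin_start else rng.uniform(0, 2 * np.pi, 2)
    w = 2 * np.pi / _WAVELENGTH
    off = amplitude * (
        np.sin(w * s + ph1)[:, None] * e1 + np.sin(w * s + ph2)[:, None] * e2
    )
    return points + off


def _clip_box(points: np.ndarray, field_size, margin: float = 0.2) -> np.ndarray:
    lo = np.full(3, margin)
    hi = np.asarray(field_size, float) - margin
    return np.clip(points, lo, hi)


def _chord_through_box(p0, u, lo, hi):
    """Parameter interval [t0, t1] of the line p0 + t·u inside the box, or None."""
    t0, t1 = -np.inf, np.inf
    for k in range(3):
        if abs(u[k]) < 1e-9:
            if not (lo[k] <= p0[k] <= hi[k]):
                return None
        else:
            a, b = (lo[k] - p0[k]) / u[k], (hi[k] - p0[k]) / u[k]
            t0, t1 = max(t0, min(a, b)), min(t1, max(a, b))
    return (t0, t1) if t1 > t0 else None


class _Clearance:
    """KD-tree of accepted centreline points for minimum-clearance checks."""

    def __init__(self, clearance: float):
        self.clearance = clearance
        self.points: list[np.ndarray] = []
        self._tree = None

    def add(self, pts: np.ndarray):
        self.points.append(np.asarray(pts, float))
        self._tree = None

    def ok(self, pts: np.ndarray, exclude_center=None, exclude_radius: float = 0.0) -> bool:
        if not self.points:
            return True
        if self._tree is None:
            self._tree = cKDTree(np.vstack(self.points))
        d, idx = self._tree.query(pts, k=1)
        bad = d < self.clearance
        if not bad.any():
            return True
        if exclude_center is None:
            return False
        offending = self._tree.data[idx[bad]]
        return bool(
            (np.linalg.norm(offending - exclude_center, axis=1) < exclude_radius).all()
        )


def generate_capillary_network(spec: PhantomSpec) -> tuple[CapillaryGraph, GroundTruth]:
    """Grow a capillary network with prescribed length and branch densities.

    Axial trunks (Watson-distributed directions, concentration
    ``orientation_kappa``) are laid down with minimum clearance, side branches
    are attached (one degree-3 node each, ``ceil(target_NV·V)`` in total), the
    polylines are perturbed sinusoidally (``tortuosity_amplitude``), and a
    final branch-free filler trunk is trimmed so the total vector length hits
    ``target_LVm·V`` within 2%. Deterministic for a fixed seed.

    Raises
    ------
    InfeasibleSpecError
        If branching is requested below one branch per field, if the branch
        length budget exceeds the total length budget, or if the clearance
        constraint cannot be satisfied at the requested density.
    """
    rng = np.random.default_rng([int(spec.seed), 11])
    fx, fy, fz = spec.field_size
    V = spec.volume
    L_target = spec.target_LVm * V
    n_branches = max(1, int(round(spec.target_NV * V))) if spec.target_NV > 0 else 0
    if spec.target_NV > 0 and spec.target_NV * V < 1.0:
        raise InfeasibleSpecError(
            f"target_NV × volume = {spec.target_NV * V:.3f} < 1: "
            "branching requested but the field cannot hold one branch point"
        )
    branch_lengths = rng.uniform(*_BRANCH_LEN, size=n_branches)
    margin_trunk = 150.0  # reserve roughly one trunk for the filler stage
    cap = L_target - 1.1 * branch_lengths.sum() - margin_trunk
    if cap <= 0:
        raise InfeasibleSpecError(
            "branch length budget exceeds the total length budget: "
            "target_NV too high for target_LVm in this field"
        )

    clear = _Clearance(2 * spec.capillary_radius + 3.0)
    xy_margin = spec.capillary_radius + spec.tortuosity_amplitude + 1.0
    lo = np.array([xy_margin, xy_margin, 0.0])
    hi = np.array([fx - xy_margin, fy - xy_margin, fz])

    trunks: list[np.ndarray] = []        # perturbed polylines carrying branches
    trunk_dirs: list[np.ndarray] = []

    def _make_trunk(max_length=None):
        for _ in range(200):
            u = _watson_axis_direction(rng, spec.orientation_kappa)
            p0 = np.array([
                rng.uniform(lo[0], hi[0]), rng.uniform(lo[1], hi[1]), rng.uniform(0, fz),
            ])
            span = _chord_through_box(p0, u, lo, hi)
            if span is None:
                continue
            t0, t1 = span
            if max_length is not None and (t1 - t0) > max_length:
                t1 = t0 + max_length
            if t1 - t0 < 30.0:
                continue
            n_pts = max(3, int(np.ceil((t1 - t0) / _SAMPLE_STEP)) + 1)
            ts = np.linspace(t0, t1, n_pts)
            pts = p0[None, :] + ts[:, None] * u[None, :]
            if spec.tortuosity_amplitude > 0:
                pts = _clip_box(
                    _perturb(pts, u, spec.tortuosity_amplitude, rng), spec.field_size
                )
            if clear.ok(pts):
                return pts, u
        raise InfeasibleSpecError(
            "could not place a trunk with the required clearance; "
            "density/clearance combination is infeasible"
        )

    total = 0.0
    while total < cap:
        pts, u = _make_trunk(max_length=max(40.0, cap - total + 40.0))
        clear.add(pts)
        trunks.append(pts)
        trunk_dirs.append(u)
        total += polyline_length(pts)

    # ---- side branches: each one creates exactly one degree-3 node
    attachments: list[list[int]] = [[] for _ in trunks]
    branches: list[tuple[int, int, np.ndarray]] = []  # (trunk idx, vertex idx, polyline)
    trunk_weights = np.array([polyline_length(t) for t in trunks])
    trunk_weights = trunk_weights / trunk_weights.sum()
    min_sep_idx = max(2, int(np.ceil(10.0 / _SAMPLE_STEP)))  # ≥10 µm between attachments
    for ℓ in branch_lengths:
        placed = False
        for _ in range(300):
            ti = rng.choice(len(trunks), p=trunk_weights)
            pts = trunks[ti]
            if len(pts) < 2 * min_sep_idx + 3:
                continue
            vi = int(rng.integers(min_sep_idx, len(pts) - min_sep_idx))
            if any(abs(vi - a) < min_sep_idx for a in attachments[ti]):
                continue
            p = pts[vi]
            w = _isotropic_direction(rng)
            if abs(np.dot(w, trunk_dirs[ti])) > 0.9:
                continue
            span = _chord_through_box(p, w, np.full(3, 0.5), np.asarray(spec.field_size) - 0.5)
            if span is None:
                continue
            ℓ_eff = min(ℓ, span[1])
            if ℓ_eff < 8.0:
                continue
            n_pts = max(3, int(np.ceil(ℓ_eff / _SAMPLE_STEP)) + 1)
            ts = np.linspace(0.0, ℓ_eff, n_pts)
            bpts = p[None, :] + ts[:, None] * w[None, :]
            if spec.tortuosity_amplitude > 0:
                bpts = _clip_box(
                    _perturb(bpts, w, spec.tortuosity_amplitude, rng, pin_start=True),
                    spec.field_size,
                )
            bpts[0] = p
            if not clear.ok(bpts[1:], exclude_center=p,
                            exclude_radius=clear.clearance + 3.0):
                continue
            clear.add(bpts[len(bpts) // 3:])  # keep the stem near p out of the tree
            attachments[ti].append(vi)
            branches.append((ti, vi, bpts))
            placed = True
            break
        if not placed:
            raise InfeasibleSpecError("could not attach a side branch with clearance")

    # ---- filler trunks trimmed to the exact residual length
    current = sum(polyline_length(t) for t in trunks) + sum(
        polyline_length(b) for _, _, b in branches
    )
    fillers: list[np.ndarray] = []
    residual = L_target - current
    while residual > 2.0:
        pts, _ = _make_trunk(max_length=max(40.0, residual + 20.0))
        ln = polyline_length(pts)
        if ln > residual:
            pts = _trim_polyline(pts, residual)
            ln = polyline_length(pts)
        clear.add(pts)
        fillers.append(pts)
        residual -= ln

    # ---- assemble the graph
    graph = CapillaryGraph()
    attach_map: dict[tuple[int, int], int] = {}
    for ti, pts in enumerate(trunks):
        cut_idx = sorted(set(attachments[ti]))
        bounds = [0] + cut_idx + [len(pts) - 1]
        node_ids = [graph.add_node(pts[i]) for i in bounds]
        for a, b, na, nb in zip(bounds[:-1], bounds[1:], node_ids[:-1], node_ids[1:]):
            seg = pts[a : b + 1].copy()
            seg[0] = graph.nodes[na]
            seg[-1] = graph.nodes[nb]
            graph.add_edge(na, nb, seg)
        for i, nid in zip(bounds, node_ids):
            attach_map[(ti, i)] = nid
    for ti, vi, bpts in branches:
        start = attach_map[(ti, vi)]
        seg = bpts.copy()
        seg[0] = graph.nodes[start]
        end = graph.add_node(seg[-1])
        graph.add_edge(start, end, seg)
    for pts in fillers:
        na, nb = graph.add_node(pts[0]), graph.add_node(pts[-1])
        graph.add_edge(na, nb, pts)

    mm = compute_morphometry(graph, V, resample_step=5.0)
    gt = GroundTruth(
        graph=graph,
        true_LVm=mm.LVm,
        true_NV=mm.Br_dens,
        true_tortuosity=mm.tortuosity,
        true_anisotropy=mm.anisotropy,
        true_MeanCap=mm.MeanCap,
    )
    return graph, gt


def _trim_polyline(points: np.ndarray, target_length: float) -> np.ndarray:
    """Cut a polyline at the given arc length (linear interpolation)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if target_length >= s[-1]:
        return points
    k = int(np.searchsorted(s, target_length))
    frac = (target_length - s[k - 1]) / (s[k] - s[k - 1])
    last = points[k - 1] + frac * (points[k] - points[k - 1])
    return np.vstack([points[:k], last])


def calibrate_tortuosity_amplitude(
    spec: PhantomSpec, target_tortuosity: float, bracket=(1e-3, 6.0)
) -> float:
    """Amplitude whose exact exterior-angle tortuosity equals the setpoint.

    Root-finds on the generated network's ground-truth tortuosity (5-µm
    vectorisation), which is monotone in the amplitude. Returns the amplitude
    in µm; plug it back into the spec to generate the calibrated field.
    """

    def f(a):
        _, gt = generate_capillary_network(replace(spec, tortuosity_amplitude=float(a)))
        return gt.true_tortuosity - target_tortuosity

    return float(optimize.brentq(f, *bracket, xtol=1e-3, rtol=1e-4))


def nv_for_meancap(target_LVm: float, target_MeanCap: float) -> float:
    """Branch density consistent with a MeanCap setpoint: N_V = (2/3)·L_V/MeanCap."""
    if target_MeanCap <= 0:
        raise ValueError("MeanCap setpoint must be positive")
    return (2.0 / 3.0) * target_LVm / target_MeanCap


# ------------------------------------------------------------------ rasterise
def _dense_points(points: np.ndarray, step: float) -> np.ndarray:
    out = [points[:1]]
    for a, b in zip(points[:-1], points[1:]):
        d = np.linalg.norm(b - a)
        n = max(1, int(np.ceil(d / step)))
        ts = np.linspace(0.0, 1.0, n + 1)[1:]
        out.append(a[None, :] + ts[:, None] * (b - a)[None, :])
    return np.vstack(out)


def rasterise_network(graph: CapillaryGraph, spec: PhantomSpec) -> VoxelVolume:
    """Render a capillary graph into a confocal-style 8-bit image stack.

    Voxels whose centre lies within ``capillary_radius`` of any polyline
    become foreground (intensity 200 on a background of 20); optional
    Gaussian noise of SD ``noise_sd`` is added. If ``z_shrinkage`` < 1 the z
    world-coordinates are compressed by that factor before rasterisation,
    emulating axial shrinkage of the thick section; the stack then has
    correspondingly fewer optical slices.
    """
    dx, dy, dz = spec.voxel_size
    if spec.capillary_radius < max(spec.voxel_size):
        warnings.warn(
            "capillary radius below the voxel size: thin structures may lose "
            "connectivity on the grid",
            ThinStructureWarning,
            stacklevel=2,
        )
    fx, fy, fz = spec.field_size
    nx, ny = int(round(fx / dx)), int(round(fy / dy))
    nz = max(1, int(round(fz * spec.z_shrinkage / dz)))
    centre = np.zeros((nz, ny, nx), bool)
    g = graph.scale_z(spec.z_shrinkage) if spec.z_shrinkage != 1.0 else graph
    for e in g.edges:
        pts = _dense_points(np.asarray(e.points, float), 0.25 * min(spec.voxel_size))
        ix = np.clip((pts[:, 0] / dx).astype(int), 0, nx - 1)
        iy = np.clip((pts[:, 1] / dy).astype(int), 0, ny - 1)
        iz = np.clip((pts[:, 2] / dz).astype(int), 0, nz - 1)
        centre[iz, iy, ix] = True
    if centre.any():
        dist = ndimage.distance_transform_edt(~centre, sampling=(dz, dy, dx))
        fg = dist <= spec.capillary_radius
    else:
        fg = centre
    data = np.where(fg, 200, 20).astype(np.float64)
    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([int(spec.seed), 13])
        data += noise_rng.normal(0.0, spec.noise_sd, size=data.shape)
    return VoxelVolume(np.clip(data, 0, 255).astype(np.uint8), spec.voxel_size)


# ------------------------------------------------------------- fibre phantoms
def _draw_fibre_layout(spec: PhantomSpec, rng: np.random.Generator):
    """Seed positions and radii of the fibre territories (power diagram ∩ disc)."""
    fx, fy, _ = spec.field_size
    m, s = spec.fibre_diameter_mean, spec.fibre_diameter_sd
    if s > 0:
        sigma2 = np.log(1.0 + (s / m) ** 2)
        mu = np.log(m) - sigma2 / 2.0
        diams = rng.lognormal(mu, np.sqrt(sigma2), size=spec.n_fibres)
    else:
        diams = np.full(spec.n_fibres, float(m))
    radii = diams / 2.0
    if np.sum(np.pi * radii**2) > 0.95 * fx * fy:
        raise InfeasibleSpecError(
            f"{spec.n_fibres} fibres of mean diameter {m} µm do not fit a "
            f"{fx:g}×{fy:g} µm field"
        )
    seeds = np.empty((spec.n_fibres, 2))
    for i in range(spec.n_fibres):
        margin = min(radii[i], 0.45 * min(fx, fy))
        for attempt in range(400):
            c = np.array([rng.uniform(margin, fx - margin), rng.uniform(margin, fy - margin)])
            if all(
                np.linalg.norm(c - seeds[j]) >= 0.6 * (radii[i] + radii[j])
                for j in range(i)
            ):
                seeds[i] = c
                break
        else:
            raise InfeasibleSpecError("could not place fibre seeds at the requested density")
    return seeds, radii


def _fibre_label_2d(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Power-diagram fibre label image (0 = extracellular background)."""
    dx, dy = spec.voxel_size[0], spec.voxel_size[1]
    fx, fy, _ = spec.field_size
    nx, ny = int(round(fx / dx)), int(round(fy / dy))
    seeds, radii = _draw_fibre_layout(spec, rng)
    X = (np.arange(nx) + 0.5) * dx
    Y = (np.arange(ny) + 0.5) * dy
    XX, YY = np.meshgrid(X, Y)  # shape (ny, nx)
    best_val = np.full((ny, nx), np.inf, dtype=np.float32)
    best_lab = np.zeros((ny, nx), dtype=np.uint16)
    inside = np.zeros((ny, nx), bool)
    for i, (c, r) in enumerate(zip(seeds, radii), start=1):
        d2 = (XX - c[0]) ** 2 + (YY - c[1]) ** 2
        power = (d2 - r * r).astype(np.float32)
        take = power < best_val
        best_val[take] = power[take]
        best_lab[take] = i
        inside[take] = d2[take] <= r * r
    best_lab[~inside] = 0
    return best_lab


def _contour_of_label(lab2d: np.ndarray, fibre_id: int, dx: float, dy: float) -> np.ndarray:
    contours = measure.find_contours(lab2d == fibre_id, 0.5)
    if not contours:
        raise InfeasibleSpecError(f"fibre {fibre_id} vanished from the label map")
    c = max(contours, key=len)  # (row, col) subpixel positions, closed loop
    closed = np.allclose(c[0], c[-1])
    if closed and len(c) > 9:
        # circular moving average removes the marching-squares staircase,
        # whose zigzag inflates the perimeter of smooth outlines by ~5%
        ring = c[:-1]
        kernel = np.ones(5) / 5.0
        sm = np.column_stack(
            [np.convolve(np.r_[ring[-2:, k], ring[:, k], ring[:2, k]], kernel, "valid")
             for k in range(2)]
        )
        c = np.vstack([sm, sm[:1]])
    out = np.empty((len(c), 2))
    out[:, 0] = (c[:, 1] + 0.5) * dx
    out[:, 1] = (c[:, 0] + 0.5) * dy
    return out


def generate_fibre_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, FibreModel]:
    """Prism-like fibre territories along z with known contours.

    Fibre cross-sections are the intersection of a power-diagram cell with the
    fibre's own disc (lognormal-ish diameters at the stated mean/SD), extruded
    along z; contours are provided on four planes (identical by construction,
    matching contour tracing on four planes of the stack).
    """
    rng = np.random.default_rng([int(spec.seed), 17])
    dx, dy, dz = spec.voxel_size
    fz = spec.field_size[2]
    lab2d = _fibre_label_2d(spec, rng)
    nz = max(1, int(round(fz / dz)))
    labels = np.broadcast_to(lab2d, (nz, *lab2d.shape)).copy()
    vol = VoxelVolume(labels, spec.voxel_size)
    plane_z = np.linspace(0.0, fz, 4)
    fibres = []
    for i in range(1, spec.n_fibres + 1):
        if not (lab2d == i).any():
            continue
        contour = _contour_of_label(lab2d, i, dx, dy)
        fibres.append(FibreSection(i, plane_z.copy(), [contour.copy() for _ in plane_z]))
    model = FibreModel(fibres=fibres, z_bounds=(0.0, fz))
    return vol, model


# --------------------------------------------------------- serial sections
#: (BA-D5, SC-71, 6H1) positivity per fibre type
TYPE_POSITIVITY = {
    "1": (True, False, False),
    "1/2a": (True, True, False),
    "2a": (False, True, False),
    "2a/2x": (False, True, True),
    "2x": (False, False, True),
}


def _place_jittered(img: np.ndarray, shift: tuple[int, int], fill=0) -> np.ndarray:
    out = np.full_like(img, fill)
    sy, sx = shift
    h, w = img.shape
    ys0, ys1 = max(0, sy), min(h, h + sy)
    xs0, xs1 = max(0, sx), min(w, w + sx)
    out[ys0:ys1, xs0:xs1] = img[ys0 - sy : ys1 - sy, xs0 - sx : xs1 - sx]
    return out


def generate_serial_sections(
    spec: PhantomSpec,
    fibre_type_probs: dict[str, float],
    imcl_by_type: dict[str, float],
    jitter_px: int = 3,
    noise_sd: float = 4.0,
    imcl_sd: float = 0.0,
    droplet_radius_px: int = 2,
) -> tuple[SectionSet, pd.DataFrame]:
    """Synthetic MyHC/Sudan-Black serial sections with a known truth table.

    Each fibre draws a type from ``fibre_type_probs`` (over types 1, 1/2a,
    2a, 2a/2x, 2x); the three antibody channels follow the serial-section
    positivity convention (e.g. type 1/2a positive on both BA-D5 and SC-71).
    Lipid droplets are placed until each fibre's Sudan-positive area fraction
    equals its drawn IMCL value, exact to the pixel (the last droplet is
    trimmed). Each non-reference section is shifted by a small random integer
    jitter to exercise cross-section matching.

    Returns the section set and a truth table with columns ``fibre_id``,
    ``fibre_type``, per-channel positivity, and ``imcl_true`` (%).
    """
    missing = set(fibre_type_probs) - set(FIBRE_TYPES)
    if missing:
        raise ValueError(f"unknown fibre types: {sorted(missing)}")
    p = np.array([fibre_type_probs.get(t, 0.0) for t in FIBRE_TYPES], float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("fibre type probabilities must be non-negative and sum to 1")
    if any(not (0 <= v <= 100) for v in imcl_by_type.values()):
        raise ValueError("IMCL values must be percentages in [0, 100]")

    rng = np.random.default_rng([int(spec.seed), 19])
    lab = _fibre_label_2d(spec, rng)
    ids = [int(i) for i in np.unique(lab) if i > 0]
    types = {fid: FIBRE_TYPES[rng.choice(len(FIBRE_TYPES), p=p)] for fid in ids}

    bg, neg, pos = 10.0, 60.0, 200.0
    channels: dict[str, np.ndarray] = {}
    labels: dict[str, np.ndarray] = {}
    shifts = {CHANNELS[0]: (0, 0)}  # BA-D5 is the reference section
    for name in (*CHANNELS[1:], "SB"):
        shifts[name] = tuple(rng.integers(-jitter_px, jitter_px + 1, size=2)) if jitter_px else (0, 0)
    for ci, name in enumerate(CHANNELS):
        img = np.full(lab.shape, bg)
        for fid in ids:
            level = pos if TYPE_POSITIVITY[types[fid]][ci] else neg
            img[lab == fid] = level + rng.normal(0.0, 3.0)
        if noise_sd > 0:
            img += rng.normal(0.0, noise_sd, size=img.shape)
        img = np.clip(img, 0, 255)
        channels[name] = _place_jittered(img, shifts[name], fill=bg)
        labels[name] = _place_jittered(lab, shifts[name])

    # Sudan Black: droplets until the drawn per-fibre fraction is met exactly
    lipid = np.zeros(lab.shape, bool)
    imcl_true: dict[int, float] = {}
    yy, xx = np.mgrid[-droplet_radius_px : droplet_radius_px + 1,
                      -droplet_radius_px : droplet_radius_px + 1]
    disc = (yy**2 + xx**2) <= droplet_radius_px**2
    for fid in ids:
        fibre_px = np.argwhere(lab == fid)
        n_px = len(fibre_px)
        target_pct = float(imcl_by_type.get(types[fid], 0.0))
        if imcl_sd > 0:
            target_pct = float(np.clip(rng.normal(target_pct, imcl_sd), 0.0, 100.0))
        need = int(round(target_pct / 100.0 * n_px))
        placed = 0
        guard = 0
        while placed < need and guard < 50 * need + 100:
            guard += 1
            cy, cx = fibre_px[rng.integers(n_px)]
            ys = np.clip(yy[disc] + cy, 0, lab.shape[0] - 1)
            xs = np.clip(xx[disc] + cx, 0, lab.shape[1] - 1)
            cand = (lab[ys, xs] == fid) & ~lipid[ys, xs]
            new_y, new_x = ys[cand], xs[cand]
            if len(new_y) == 0:
                continue
            if placed + len(new_y) > need:
                keep = need - placed
                new_y, new_x = new_y[:keep], new_x[:keep]
            lipid[new_y, new_x] = True
            placed += len(new_y)
        imcl_true[fid] = 100.0 * placed / n_px
    lipid = _place_jittered(lipid, shifts["SB"])
    labels["SB"] = _place_jittered(lab, shifts["SB"])

    sections = SectionSet(
        channels=channels, labels=labels, lipid_mask=lipid, pixel_size=spec.voxel_size[0]
    )
    truth = pd.DataFrame(
        {
            "fibre_id": ids,
            "fibre_type": [types[f] for f in ids],
            "BA-D5": [TYPE_POSITIVITY[types[f]][0] for f in ids],
            "SC-71": [TYPE_POSITIVITY[types[f]][1] for f in ids],
            "6H1": [TYPE_POSITIVITY[types[f]][2] for f in ids],
            "imcl_true": [imcl_true[f] for f in ids],
        }
    )
    return sections, truth
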