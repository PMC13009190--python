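"""Laplace-coordinate geometry of the hippocampal gray-matter sheet.

Coordinate conventions (documented once, used everywhere):

* voxel indices are 0-based; the native coordinate of voxel ``i`` along an
  axis with voxel size ``h`` mm is ``(i + 0.5) h`` (voxel centres);
* the three Laplace fields psi_AP, psi_PD, psi_IO take values in [0, 1] on
  the gray matter, 0 on the source and 1 on the sink boundary layer;
* unfolded coordinates (AP, PD) live in [0, 1]^2 on a regular grid.

The module provides the Laplace relaxation solver, gradient vector fields,
primary-orientation extraction (external peak volume or the principal
diffusion-tensor eigenvector), the three cosine-similarity maps
(long-axis / tangential / radial), midthickness-surface construction with
subfield and long-axis parcel labels, enclosing-voxel surface sampling,
and the macrostructure metrics (thickness, gyrification, parcel volume).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SUBFIELD_LABELS",
    "AP_LABELS",
    "HippDomain",
    "VectorField",
    "SurfaceModel",
    "solve_laplace",
    "gradient_field",
    "primary_peak",
    "cosine_similarity_maps",
    "build_midthickness_surface",
    "sample_to_surface",
    "macrostructure",
    "save_surface_gifti",
    "save_func_gifti",
    "load_func_gifti",
]

SUBFIELD_LABELS = ("Sub", "CA1", "CA2", "CA3", "DG/CA4")
AP_LABELS = ("ant_uncus", "ant_lateral", "body_ant", "body_post", "post_tail")

_AXES = ("AP", "PD", "IO")
_SIX_NEIGHBORS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                  (0, -1, 0), (0, 0, 1), (0, 0, -1)]


# --------------------------------------------------------------------------
# Domain
# --------------------------------------------------------------------------

@dataclass
class HippDomain:
    """Gray-matter voxel domain with Laplace coordinate machinery.

    ``true_coords`` holds the analytic (generator) coordinate fields used
    to define boundary layers and to validate solved fields; ``psi`` holds
    the relaxation solutions filled in by :func:`solve_laplace`.
    """

    mask: np.ndarray
    voxel_size: float = 1.0
    true_coords: dict = field(default_factory=dict)
    psi: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be a 3-D array")
        if not self.mask.any():
            raise ValueError("empty gray-matter mask")

    # -- connectivity -----------------------------------------------------
    def assert_connected(self):
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        _, n = ndimage.label(self.mask, structure=structure)
        if n != 1:
            raise ValueError(f"gray-matter mask has {n} connected components")

    # -- boundary layers --------------------------------------------------
    def boundary_masks(self, axis: str):
        """(source, sink) voxel layers for one Laplace axis.

        The source (sink) layer is the set of mask voxels lying within one
        coordinate step of the minimum (maximum) of the analytic coordinate,
        i.e. the first/last voxel layer of that axis.
        """
        if axis not in _AXES:
            raise ValueError(f"unknown axis {axis!r}")
        f = self.true_coords[axis]
        m = self.mask
        vals = f[m]
        # one-voxel coordinate step: largest |df| between 6-neighbours
        step = 0.0
        for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            sl_a = tuple(slice(None, -1) if dd else slice(None) for dd in d)
            sl_b = tuple(slice(1, None) if dd else slice(None) for dd in d)
            both = m[sl_a] & m[sl_b]
            if both.any():
                step = max(step, np.abs(f[sl_b][both] - f[sl_a][both]).max())
        if step == 0.0:
            raise ValueError("degenerate coordinate field")
        source = m & (f <= vals.min() + 0.5 * step)
        sink = m & (f >= vals.max() - 0.5 * step)
        if not source.any() or not sink.any():
            raise ValueError(f"missing boundary faces for axis {axis}")
        if (source & sink).any():
            raise ValueError(f"source and sink overlap for axis {axis}")
        return source, sink

    # -- parcellation ------------------------------------------------------
    def parcel_labels(self, axis: str = "PD", n_bins: int = 5,
                      use: str = "true") -> np.ndarray:
        """Equal-width coordinate bands as integer labels (-1 off mask)."""
        f = self.true_coords[axis] if use == "true" else self.psi[axis]
        idx = np.clip(np.floor(f * n_bins).astype(int), 0, n_bins - 1)
        idx[~self.mask] = -1
        return idx

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class VectorField:
    """3-vector per voxel with a provenance tag."""

    vectors: np.ndarray           # (x, y, z, 3)
    provenance: str               # gradient-of-psi | fODF-peak1 | DTI-e1
    valid: np.ndarray = None      # bool (x, y, z); defaults to finite+nonzero

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.valid is None:
            norm = np.linalg.norm(self.vectors, axis=-1)
            self.valid = np.isfinite(norm) & (norm > 0)


# --------------------------------------------------------------------------
# Laplace solver
# --------------------------------------------------------------------------

def solve_laplace(domain: HippDomain, axis: str, tol: float = 1e-6,
                  max_iter: int = 50000, omega: float = 1.9) -> np.ndarray:
    """Relaxation solution of the Laplace equation on the gray matter.

    Red-black successive over-relaxation with Dirichlet values 0 / 1 on the
    source / sink boundary layers and Neumann (no-flux) conditions on all
    other mask walls, implemented by averaging over in-mask neighbours
    only.  Iterates until the update max-norm falls below ``tol``.  The
    solution is stored in ``domain.psi[axis]`` and returned (0 off mask).
    """
    domain.assert_connected()
    source, sink = domain.boundary_masks(axis)
    m = domain.mask
    free = m & ~source & ~sink
    psi = np.zeros(m.shape)
    psi[m] = 0.5
    psi[source] = 0.0
    psi[sink] = 1.0

    # 6-neighbour sums via padded views
    pad_m = np.pad(m, 1).astype(float)
    count = np.zeros(m.shape)
    for dx, dy, dz in _SIX_NEIGHBORS:
        count += pad_m[1 + dx:pad_m.shape[0] - 1 + dx,
                       1 + dy:pad_m.shape[1] - 1 + dy,
                       1 + dz:pad_m.shape[2] - 1 + dz]
    ii, jj, kk = np.indices(m.shape)
    colors = [(free & (((ii + jj + kk) % 2) == c)) for c in (0, 1)]

    def neighbor_avg(p):
        pad = np.pad(p * m, 1)
        s = np.zeros(m.shape)
        for dx, dy, dz in _SIX_NEIGHBORS:
            s += pad[1 + dx:pad.shape[0] - 1 + dx,
                     1 + dy:pad.shape[1] - 1 + dy,
                     1 + dz:pad.shape[2] - 1 + dz]
        return s / np.maximum(count, 1.0)

    for it in range(max_iter):
        for color in colors:
            avg = neighbor_avg(psi)
            psi[color] += omega * (avg[color] - psi[color])
        if it % 10 == 0 or it == max_iter - 1:
            resid = np.abs(neighbor_avg(psi) - psi)[free]
            if resid.size == 0 or resid.max() <= tol:
                break
    else:
        raise RuntimeError(
            f"Laplace relaxation did not reach tol={tol} in {max_iter} "
            f"iterations (axis {axis})")
    psi[~m] = 0.0
    domain.psi[axis] = psi
    return psi


def gradient_field(psi: np.ndarray, mask: np.ndarray,
                   voxel_size: float = 1.0) -> VectorField:
    """Masked finite-difference gradient of a scalar field (units 1/mm).

    Central differences where both neighbours are in the mask, one-sided at
    mask edges; voxels with no in-mask neighbour along an axis get a zero
    component.  Voxels whose full gradient is zero are flagged invalid
    (degenerate, e.g. single-voxel-thick regions or constant fields).
    """
    mask = np.asarray(mask, dtype=bool)
    grad = np.zeros(mask.shape + (3,))
    for ax in range(3):
        fwd = np.zeros(mask.shape, dtype=bool)
        bwd = np.zeros(mask.shape, dtype=bool)
        sl_c = [slice(None)] * 3
        sl_p = [slice(None)] * 3
        sl_m = [slice(None)] * 3
        sl_c[ax], sl_p[ax], sl_m[ax] = (slice(None, -1), slice(1, None),
                                        slice(None, -1))
        fwd[tuple(sl_m)] = mask[tuple(sl_m)] & mask[tuple(sl_p)]
        bwd[tuple(sl_p)] = mask[tuple(sl_p)] & mask[tuple(sl_m)]
        shift_p = np.roll(psi, -1, axis=ax)
        shift_m = np.roll(psi, 1, axis=ax)
        central = fwd & bwd
        only_f = fwd & ~bwd
        only_b = bwd & ~fwd
        comp = np.zeros(mask.shape)
        comp[central] = (shift_p[central] - shift_m[central]) / 2.0
        comp[only_f] = shift_p[only_f] - psi[only_f]
        comp[only_b] = psi[only_b] - shift_m[only_b]
        grad[..., ax] = comp / voxel_size
    grad[~mask] = 0.0
    vf = VectorField(grad, provenance="gradient-of-psi")
    vf.valid &= mask
    return vf


# --------------------------------------------------------------------------
# Orientation
# --------------------------------------------------------------------------

def _canonicalize_signs(vec: np.ndarray) -> np.ndarray:
    """Flip vectors so the first nonzero component is positive."""
    v = vec.reshape(-1, 3).copy()
    sign = np.where(v[:, 0] != 0, np.sign(v[:, 0]),
                    np.where(v[:, 1] != 0, np.sign(v[:, 1]),
                             np.where(v[:, 2] != 0, np.sign(v[:, 2]), 1.0)))
    v *= sign[:, None]
    return v.reshape(vec.shape)


def primary_peak(tensor_field: np.ndarray | None = None,
                 peak_volume: np.ndarray | None = None,
                 mask: np.ndarray | None = None) -> VectorField:
    """Primary diffusion orientation as a unit vector field.

    Either ingests a precomputed (x, y, z, 3) peak volume (e.g. the first
    fiber-ODF peak exported by an external tool) or falls back to the
    principal eigenvector of a (x, y, z, 3, 3) diffusion-tensor field.
    Vectors are normalized and sign-canonicalized; zero-norm voxels are
    flagged invalid.
    """
    if (tensor_field is None) == (peak_volume is None):
        raise ValueError("provide exactly one of tensor_field, peak_volume")
    if peak_volume is not None:
        vec = np.asarray(peak_volume, dtype=float)
        provenance = "fODF-peak1"
    else:
        T = np.asarray(tensor_field, dtype=float)
        shape = T.shape[:-2]
        flat = T.reshape(-1, 3, 3)
        finite = np.isfinite(flat).all(axis=(1, 2))
        safe = np.where(finite[:, None, None], flat, 0.0)
        lam, V = np.linalg.eigh(safe)
        vec = V[np.arange(flat.shape[0]), :, 2]
        vec[~finite] = 0.0
        vec = vec.reshape(shape + (3,))
        provenance = "DTI-e1"
    norm = np.linalg.norm(vec, axis=-1)
    valid = norm > 0
    unit = np.where(valid[..., None], vec / np.maximum(norm[..., None],
                                                       1e-30), 0.0)
    unit = _canonicalize_signs(unit)
    if mask is not None:
        valid = valid & np.asarray(mask, dtype=bool)
        unit = np.where(valid[..., None], unit, 0.0)
    vf = VectorField(unit, provenance=provenance)
    vf.valid = valid
    return vf


def cosine_similarity_maps(peaks: VectorField, grads: dict) -> dict:
    """Voxel-wise |cos| between the primary peak and each axis gradient.

    ``grads`` maps axis name ("AP", "PD", "IO") to a gradient
    :class:`VectorField`.  Returns the three orientation maps keyed
    "long_axis" (AP), "tangential" (PD) and "radial" (IO); values in
    [0, 1], NaN where either vector is zero / invalid.  The absolute value
    makes the maps invariant to sign flips, and normalization to positive
    rescaling, of either field.
    """
    key_of = {"AP": "long_axis", "PD": "tangential", "IO": "radial"}
    out = {}
    p = peaks.vectors
    p_norm = np.linalg.norm(p, axis=-1)
    for axis, name in key_of.items():
        g = grads[axis].vectors
        g_norm = np.linalg.norm(g, axis=-1)
        valid = peaks.valid & grads[axis].valid & (p_norm > 0) & (g_norm > 0)
        dot = np.abs(np.einsum("...i,...i->...", p, g))
        with np.errstate(invalid="ignore", divide="ignore"):
            cs = dot / (p_norm * g_norm)
        cs = np.clip(cs, 0.0, 1.0)
        cs[~valid] = np.nan
        out[name] = cs
    return out


# --------------------------------------------------------------------------
# Surface
# --------------------------------------------------------------------------

@dataclass
class SurfaceModel:
    """Midthickness surface on a regular unfolded grid.

    ``vertices_native`` are mm coordinates (voxel centre convention);
    ``vertices_unfolded`` are (AP, PD) in [0, 1]^2.  Subfield labels are
    fixed proximal-distal bands, long-axis labels fixed AP bands.  Vertex
    areas are one third of the area of incident triangles, computed in
    native space and in unfolded space.
    """

    vertices_native: np.ndarray     # (N, 3) mm
    vertices_unfolded: np.ndarray   # (N, 2)
    faces: np.ndarray               # (M, 3) int
    subfield: np.ndarray            # (N,) int index into SUBFIELD_LABELS
    ap_band: np.ndarray             # (N,) int index into AP_LABELS
    native_area: np.ndarray         # (N,) mm^2
    unfolded_area: np.ndarray       # (N,)
    grid_shape: tuple               # (n_ap, n_pd)
    valid: np.ndarray               # (N,) bool

    @property
    def n_vertices(self) -> int:
        return self.vertices_native.shape[0]

    def subfield_names(self):
        return SUBFIELD_LABELS

    def ap_names(self):
        return AP_LABELS


def _trilinear(vol: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinear interpolation at continuous voxel-index coordinates."""
    shape = np.array(vol.shape)
    p = np.clip(pts, 0.0, shape - 1.000001)
    i0 = np.floor(p).astype(int)
    frac = p - i0
    out = np.zeros(pts.shape[0])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                     * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                out += w * vol[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


def _filled_field(psi: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """psi extended outside the mask by nearest-mask-voxel values, so that
    interpolation near mask walls stays well defined."""
    idx = ndimage.distance_transform_edt(~mask, return_distances=False,
                                         return_indices=True)
    return psi[tuple(idx)]


def _vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-vertex area: one third of each incident triangle's area."""
    v = vertices
    if v.shape[1] == 2:
        v = np.column_stack([v, np.zeros(len(v))])
    a = v[faces[:, 1]] - v[faces[:, 0]]
    b = v[faces[:, 2]] - v[faces[:, 0]]
    tri = 0.5 * np.linalg.norm(np.cross(a, b), axis=1)
    area = np.zeros(len(vertices))
    for c in range(3):
        np.add.at(area, faces[:, c], tri / 3.0)
    return area


def build_midthickness_surface(domain: HippDomain, n_ap: int = 121,
                               n_pd: int = 60, newton_iter: int = 12,
                               tol: float = 0.02) -> SurfaceModel:
    """Surface at the mid inner-outer depth (psi_IO = 0.5).

    A regular (n_ap x n_pd) unfolded grid (default 121 x 60 = 7260
    vertices) is mapped into native space by solving, per grid point
    (u, v), for the location where (psi_AP, psi_PD, psi_IO) = (u, v, 0.5):
    a nearest-voxel seed followed by damped Newton iterations through the
    interpolated coordinate fields (equivalently, sliding along the
    inner-outer streamline while keeping the in-plane coordinates matched).
    Vertices whose residual coordinate mismatch exceeds ``tol`` are
    flagged invalid.
    """
    for axis in _AXES:
        if axis not in domain.psi:
            raise ValueError(f"psi_{axis} not solved; run solve_laplace")
    m = domain.mask
    fields = {ax: _filled_field(domain.psi[ax], m) for ax in _AXES}
    grads = {ax: np.stack(np.gradient(fields[ax]), axis=-1) for ax in _AXES}

    u = (np.arange(n_ap) + 0.5) / n_ap
    v = (np.arange(n_pd) + 0.5) / n_pd
    uu, vv = np.meshgrid(u, v, indexing="ij")
    targets = np.column_stack([uu.ravel(), vv.ravel(),
                               np.full(n_ap * n_pd, 0.5)])
    n_vert = targets.shape[0]

    # nearest-voxel seeds
    vox = np.argwhere(m).astype(float)
    coords = np.column_stack([domain.psi[ax][m] for ax in _AXES])
    seeds = np.empty((n_vert, 3))
    chunk = 2048
    for s in range(0, n_vert, chunk):
        t = targets[s:s + chunk]
        d2 = ((coords[None, :, :] - t[:, None, :]) ** 2).sum(axis=2)
        seeds[s:s + chunk] = vox[np.argmin(d2, axis=1)]

    # damped Newton through the interpolated coordinate fields
    p = seeds.copy()
    for _ in range(newton_iter):
        F = np.column_stack([_trilinear(fields[ax], p) for ax in _AXES])
        F -= targets
        J = np.empty((n_vert, 3, 3))
        for r, ax in enumerate(_AXES):
            for c in range(3):
                J[:, r, c] = _trilinear(grads[ax][..., c], p)
        # regularized solve; cap the step at one voxel
        det_ok = np.abs(np.linalg.det(J)) > 1e-12
        dp = np.zeros_like(p)
        if det_ok.any():
            dp[det_ok] = np.linalg.solve(J[det_ok],
                                         -F[det_ok][..., None])[..., 0]
        step = np.linalg.norm(dp, axis=1, keepdims=True)
        dp *= np.minimum(1.0, 1.0 / np.maximum(step, 1e-30))
        p += dp
        p = np.clip(p, 0.0, np.array(m.shape) - 1.0)

    F = np.column_stack([_trilinear(fields[ax], p) for ax in _AXES])
    resid = np.abs(F - targets).max(axis=1)
    valid = resid <= tol

    native = (p + 0.5) * domain.voxel_size
    unfolded = targets[:, :2]

    # faces of the regular grid (two triangles per quad)
    faces = []
    for i in range(n_ap - 1):
        for j in range(n_pd - 1):
            a = i * n_pd + j
            b = a + 1
            c = a + n_pd
            d = c + 1
            faces.append((a, b, c))
            faces.append((b, d, c))
    faces = np.array(faces, dtype=int)

    subfield = np.clip((unfolded[:, 1] * len(SUBFIELD_LABELS)).astype(int),
                       0, len(SUBFIELD_LABELS) - 1)
    ap_band = np.clip((unfolded[:, 0] * len(AP_LABELS)).astype(int),
                      0, len(AP_LABELS) - 1)
    native_area = _vertex_areas(native, faces)
    unfolded_area = _vertex_areas(unfolded, faces)
    return SurfaceModel(
        vertices_native=native, vertices_unfolded=unfolded, faces=faces,
        subfield=subfield, ap_band=ap_band, native_area=native_area,
        unfolded_area=unfolded_area, grid_shape=(n_ap, n_pd), valid=valid)


def sample_to_surface(volume: np.ndarray, surface: SurfaceModel,
                      domain: HippDomain) -> np.ndarray:
    """Per-vertex map sampled with the enclosing-voxel method.

    Each vertex takes the value of the voxel containing its native
    coordinate (no interpolation); vertices falling outside the volume
    bounds raise, vertices outside the gray-matter mask (or flagged
    invalid) are returned as NaN.
    """
    h = domain.voxel_size
    idx = np.floor(surface.vertices_native / h).astype(int)
    shape = np.array(volume.shape[:3])
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("vertex outside volume bounds")
    vals = volume[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    in_mask = domain.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
    vals[~(in_mask & surface.valid)] = np.nan
    return vals


# --------------------------------------------------------------------------
# Macrostructure
# --------------------------------------------------------------------------

def _streamline_lengths(domain: HippDomain, starts: np.ndarray,
                        step_frac: float = 0.25, max_steps: int = 2000):
    """Arc length of inner-outer streamlines through the given native-mm
    start points (RK4 through the normalized psi_IO gradient, both
    directions, until psi_IO reaches 0 or 1)."""
    m = domain.mask
    psi = _filled_field(domain.psi["IO"], m)
    grad = np.stack(np.gradient(psi), axis=-1)
    h = domain.voxel_size
    step = step_frac  # in voxel units

    def unit_grad(p):
        g = np.column_stack([_trilinear(grad[..., c], p) for c in range(3)])
        n = np.linalg.norm(g, axis=1, keepdims=True)
        return np.where(n > 1e-12, g / np.maximum(n, 1e-30), 0.0), n[:, 0]

    lengths = np.zeros(starts.shape[0])
    degenerate = np.zeros(starts.shape[0], dtype=bool)
    for direction in (+1.0, -1.0):
        p = starts / h - 0.5  # to voxel-index space
        active = np.ones(starts.shape[0], dtype=bool)
        for _ in range(max_steps):
            if not active.any():
                break
            pa = p[active]
            k1, n1 = unit_grad(pa)
            k2, _ = unit_grad(pa + 0.5 * step * direction * k1)
            k3, _ = unit_grad(pa + 0.5 * step * direction * k2)
            k4, _ = unit_grad(pa + step * direction * k3)
            dp = (step * direction / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            moved = np.linalg.norm(dp, axis=1)
            newp = pa + dp
            val = _trilinear(psi, newp)
            stop = (val <= 1e-9) | (val >= 1 - 1e-9) | (moved < 1e-9) \
                | (n1 < 1e-12)
            lengths[np.nonzero(active)[0]] += moved * h
            degenerate[np.nonzero(active)[0]] |= (n1 < 1e-12)
            p[active] = newp
            idx = np.nonzero(active)[0]
            active[idx[stop]] = False
    return lengths, degenerate


def macrostructure(domain: HippDomain, surface: SurfaceModel):
    """Per-vertex thickness and gyrification; per-parcel volume.

    * thickness: arc length (mm) of the inner-outer streamline through each
      vertex, i.e. the laminar extent of the sheet at that point;
    * gyrification: native vertex area relative to unfolded vertex area,
      each normalized by its surface total, so an undistorted mapping gives
      exactly 1 everywhere;
    * volume: gray-matter voxel count times voxel volume per subfield
      (proximal-distal bands of psi_PD), summing exactly to the total GM
      volume.

    Returns ``(thickness, gyrification, volume_table)``.
    """
    thickness, degenerate = _streamline_lengths(
        domain, surface.vertices_native)
    thickness[degenerate | ~surface.valid] = np.nan
    rel_native = surface.native_area / surface.native_area.sum()
    rel_unfolded = surface.unfolded_area / surface.unfolded_area.sum()
    gyrification = rel_native / rel_unfolded
    use = "psi" if "PD" in domain.psi else "true"
    labels = domain.parcel_labels(axis="PD", n_bins=len(SUBFIELD_LABELS),
                                  use=use)
    voxvol = domain.voxel_size ** 3
    rows = [{"parcel": SUBFIELD_LABELS[b],
             "volume": float(np.sum(labels == b) * voxvol)}
            for b in range(len(SUBFIELD_LABELS))]
    return thickness, gyrification, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# GIFTI I/O
# --------------------------------------------------------------------------

def save_surface_gifti(surface: SurfaceModel, path) -> None:
    import nibabel as nib
    from nibabel import gifti
    img = gifti.GiftiImage(darrays=[
        gifti.GiftiDataArray(surface.vertices_native.astype(np.float32),
                             intent="NIFTI_INTENT_POINTSET"),
        gifti.GiftiDataArray(surface.faces.astype(np.int32),
                             intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def save_func_gifti(values: np.ndarray, path) -> None:
    import nibabel as nib
    from nibabel import gifti
    img = gifti.GiftiImage(darrays=[
        gifti.GiftiDataArray(np.asarray(values, dtype=np.float32),
                             intent="NIFTI_INTENT_NONE")])
    nib.save(img, str(path))


def load_func_gifti(path) -> np.ndarray:
    import nibabel as nib
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)
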