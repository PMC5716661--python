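"""Trajectory post-processing for pore hydration and side-chain geometry.

Operates on small structure ensembles (multi-model PDB or in-memory arrays)
with a designated straight pore axis:

* on-axis pore radius profiles (a simplified stand-in for HOLE: the radius at
  height z is the clearance from the axis point to the nearest atom surface,
  with no center-line optimization),
* 3-D occupancy grids (fraction of frames a bin is occupied),
* XY-integrated water linear density along the pore in 1/Angstrom, bounded by
  the pore radius profile,
* grid-based solvent-accessible surface area of a target residue, normalized
  to the residue's maximal (isolated) surface,
* orientation of planar side-chain groups relative to the pore axis,
* per-frame pore-continuity classification from the water density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "PoreEnsemble",
    "PoreRadiusProfile",
    "OccupancyGrid",
    "LinearDensityProfile",
    "SasaSeries",
    "pore_radius_profile",
    "occupancy_grid",
    "water_linear_density",
    "grid_sasa",
    "ring_orientation",
    "pore_continuity",
    "write_pdb",
    "read_pdb",
]

#: Element -> van der Waals radius (Angstrom) used when reading PDB files.
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}
DEFAULT_VDW = 1.7
WATER_RESNAMES = ("HOH", "WAT", "TIP3", "SOL")


@dataclass
class PoreEnsemble:
    """Atom ensemble over frames with a designated straight pore axis.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Angstrom; label and
    radius arrays have length n_atoms and are shared by all frames.  The axis
    is a point (``axis_origin``) plus a unit vector (``axis_direction``); the
    axial coordinate z of an atom is measured along the direction from the
    origin.
    """

    coordinates: np.ndarray
    resnames: np.ndarray
    atomnames: np.ndarray
    chain_ids: np.ndarray
    resids: np.ndarray
    vdw_radii: np.ndarray
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim == 2:
            self.coordinates = self.coordinates[None]
        n_atoms = self.coordinates.shape[1]
        for name in ("resnames", "atomnames", "chain_ids", "resids", "vdw_radii"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n_atoms:
                raise ValueError(f"{name} must have one entry per atom")
            setattr(self, name, arr)
        if np.any(self.vdw_radii <= 0):
            raise ValueError("vdw radii must be positive")
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        norm = np.linalg.norm(self.axis_direction)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("axis_direction must be a unit vector")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def water_mask(self) -> np.ndarray:
        return np.isin(self.resnames, WATER_RESNAMES)

    def select(self, resname: str | None = None, chain: str | None = None,
               resid: int | None = None, exclude_water: bool = False) -> np.ndarray:
        """Boolean atom mask combining simple label criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if resname is not None:
            mask &= self.resnames == resname
        if chain is not None:
            mask &= self.chain_ids == chain
        if resid is not None:
            mask &= self.resids == resid
        if exclude_water:
            mask &= ~self.water_mask
        return mask

    def axial_coords(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """Per-atom (z, radial distance) relative to the pore axis."""
        rel = self.coordinates[frame] - self.axis_origin
        z = rel @ self.axis_direction
        perp = rel - np.outer(z, self.axis_direction)
        return z, np.linalg.norm(perp, axis=1)


@dataclass
class PoreRadiusProfile:
    """Pore radius (Angstrom) versus axial position z (Angstrom)."""

    z_grid: np.ndarray
    radius: np.ndarray

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if np.any(np.diff(self.z_grid) <= 0):
            raise ValueError("z_grid must be strictly increasing")
        if np.any(self.radius < 0):
            raise ValueError("radius must be non-negative")

    def at(self, z) -> np.ndarray:
        """Radius interpolated at axial positions ``z``."""
        return np.interp(z, self.z_grid, self.radius)


@dataclass
class OccupancyGrid:
    """Fraction-of-frames occupancy on a regular 3-D grid."""

    edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    occupancy: np.ndarray
    selection: str = ""
    mode: str = "center"


@dataclass
class LinearDensityProfile:
    """Water linear density (1/Angstrom) per frame and axial slab."""

    z_edges: np.ndarray
    time_grid: np.ndarray
    density: np.ndarray  # shape (n_frames, n_slabs)

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


@dataclass
class SasaSeries:
    """Normalized grid SASA of a residue per sub-trajectory window."""

    window_times: np.ndarray
    sasa_norm: np.ndarray
    residue: str
    grid_spacing: float
    occupancy_threshold: float
    shell: float = 1.5


def pore_radius_profile(coords: np.ndarray, radii: np.ndarray, z_grid,
                        axis_origin=(0.0, 0.0, 0.0),
                        axis_direction=(0.0, 0.0, 1.0)) -> PoreRadiusProfile:
    """On-axis pore radius profile for one frame.

    For each z, the radius is min over atoms of (distance from the axis point
    at height z to the atom center, minus the atom's vdW radius), floored at
    zero.  A simplified, fixed-axis version of the HOLE construction;
    adequate when the pore axis is straight.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    if coords.size == 0:
        raise ValueError("empty frame")
    origin = np.asarray(axis_origin, dtype=float)
    direction = np.asarray(axis_direction, dtype=float)
    points = origin[None, :] + z_grid[:, None] * direction[None, :]
    dist = np.linalg.norm(coords[None, :, :] - points[:, None, :], axis=2)
    radius = np.clip((dist - radii[None, :]).min(axis=1), 0.0, None)
    return PoreRadiusProfile(z_grid=z_grid, radius=radius)


def _snapped_edges(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Bin edges at integer multiples of ``spacing`` covering [lo, hi]."""
    first = np.floor(lo / spacing)
    last = np.ceil(hi / spacing)
    return np.arange(first, last + 1) * spacing


def occupancy_grid(coordinates: np.ndarray, spacing: float,
                   selection: str = "", mode: str = "center",
                   vdw_radii: np.ndarray | None = None) -> OccupancyGrid:
    """Per-bin fraction of frames occupied by the selected atoms.

    ``coordinates`` is (n_frames, n_atoms, 3) for the already-selected atoms.
    ``mode='center'`` (default) marks a bin occupied in a frame when at least
    one atom center falls in it; ``mode='vdw'`` marks bins whose centers lie
    inside any atom's vdW sphere (requires ``vdw_radii``).  The grid covers
    the selection's bounding box with edges snapped to multiples of
    ``spacing``.
    """
    coords = np.asarray(coordinates, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if coords.shape[1] == 0:
        raise ValueError("empty selection")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if mode not in ("center", "vdw"):
        raise ValueError("mode must be 'center' or 'vdw'")
    pad = 0.0
    if mode == "vdw":
        if vdw_radii is None:
            raise ValueError("mode='vdw' requires vdw_radii")
        vdw_radii = np.asarray(vdw_radii, dtype=float)
        pad = float(vdw_radii.max()) + spacing

    lo = coords.reshape(-1, 3).min(axis=0) - pad
    hi = coords.reshape(-1, 3).max(axis=0) + pad
    edges = tuple(_snapped_edges(lo[d], hi[d], spacing) for d in range(3))
    shape = tuple(len(e) - 1 for e in edges)

    counts = np.zeros(shape)
    for f in range(coords.shape[0]):
        if mode == "center":
            hist, _ = np.histogramdd(coords[f], bins=edges)
            counts += hist > 0
        else:
            counts += _vdw_binary(coords[f], vdw_radii, edges)
    return OccupancyGrid(edges=edges, occupancy=counts / coords.shape[0],
                         selection=selection, mode=mode)


def _vdw_binary(coords: np.ndarray, radii: np.ndarray,
                edges: tuple[np.ndarray, ...]) -> np.ndarray:
    """Binary grid: bin centers inside any atom's vdW sphere."""
    centers = [0.5 * (e[:-1] + e[1:]) for e in edges]
    shape = tuple(len(c) for c in centers)
    occ = np.zeros(shape, dtype=bool)
    spacing = [float(e[1] - e[0]) for e in edges]
    for xyz, r in zip(coords, radii):
        idx = []
        for d in range(3):
            i0 = int(np.searchsorted(centers[d], xyz[d] - r))
            i1 = int(np.searchsorted(centers[d], xyz[d] + r, side="right"))
            if i0 >= shape[d] or i1 <= 0:
                idx = None
                break
            idx.append((max(i0, 0), min(i1, shape[d])))
        if idx is None:
            continue
        (x0, x1), (y0, y1), (z0, z1) = idx
        dx = centers[0][x0:x1] - xyz[0]
        dy = centers[1][y0:y1] - xyz[1]
        dz = centers[2][z0:z1] - xyz[2]
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2
              + dz[None, None, :] ** 2)
        occ[x0:x1, y0:y1, z0:z1] |= d2 <= r * r
    return occ


def water_linear_density(ensemble: PoreEnsemble, profile: PoreRadiusProfile,
                         z_edges) -> LinearDensityProfile:
    """XY-integrated water density along the pore, in 1/Angstrom.

    For each frame and axial slab of width dz, counts water oxygens whose
    radial distance from the axis is within the pore radius at the slab
    center and divides by dz.  Integrating the density over z recovers the
    per-frame in-boundary water count exactly.
    """
    z_edges = np.asarray(z_edges, dtype=float)
    centers = 0.5 * (z_edges[:-1] + z_edges[1:])
    widths = np.diff(z_edges)
    boundary = profile.at(centers)
    mask = ensemble.water_mask & (ensemble.atomnames == "O")
    density = np.zeros((ensemble.n_frames, centers.size))
    for f in range(ensemble.n_frames):
        z, rho = ensemble.axial_coords(f)
        z, rho = z[mask], rho[mask]
        slab = np.digitize(z, z_edges) - 1
        ok = (slab >= 0) & (slab < centers.size)
        slab, rho = slab[ok], rho[ok]
        inside = rho <= boundary[slab]
        counts = np.bincount(slab[inside], minlength=centers.size)
        density[f] = counts / widths
    return LinearDensityProfile(z_edges=z_edges,
                                time_grid=np.arange(ensemble.n_frames),
                                density=density)


def _ball_structure(shell: float, spacing: float) -> np.ndarray:
    """Neighbourhood of bin-center offsets with distance <= shell (ties in)."""
    r = int(np.floor(shell / spacing + 1e-9))
    ax = np.arange(-r, r + 1)
    d2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
          + ax[None, None, :] ** 2) * spacing ** 2
    return d2 <= shell ** 2 + 1e-9


def _surface_bins(binary: np.ndarray, shell: float, spacing: float) -> np.ndarray:
    """Value-1 bins with a value-0 bin center within ``shell``; outside the
    grid counts as empty."""
    ball = _ball_structure(shell, spacing)
    near_empty = ndimage.binary_dilation(~binary, structure=ball, border_value=1)
    return binary & near_empty


def grid_sasa(ensemble: PoreEnsemble, residue_mask: np.ndarray,
              window: int = 10, spacing: float = 0.5,
              occupancy_threshold: float = 0.5, shell: float = 1.5,
              residue_label: str = "") -> SasaSeries:
    """Grid-based normalized SASA of a residue per sub-trajectory window.

    Per window of ``window`` consecutive frames: (1) occupancy grid of all
    non-water atoms (fraction of frames each bin center lies inside a vdW
    sphere); (2) binarize at ``occupancy_threshold``; (3) surface bins =
    occupied bins with an empty bin center within ``shell`` (ties at exactly
    the shell distance included; outside the grid counts as empty); (4) raw
    SASA = number of surface bins also covered by the target residue's atoms;
    (5) normalize by the same computation on the isolated residue (its
    maximal surface) on the same lattice.
    """
    residue_mask = np.asarray(residue_mask, dtype=bool)
    if not residue_mask.any():
        raise ValueError("residue not found (empty residue mask)")
    if window > ensemble.n_frames:
        raise ValueError("window exceeds the number of frames")
    if spacing > shell:
        raise ValueError("spacing must not exceed the shell distance")

    heavy = ~ensemble.water_mask
    coords = ensemble.coordinates[:, heavy]
    radii = ensemble.vdw_radii[heavy]
    res_in_heavy = residue_mask[heavy]
    if residue_mask[~heavy].any():
        raise ValueError("residue mask selects water atoms")

    pad = float(radii.max()) + shell + spacing
    flat = coords.reshape(-1, 3)
    edges = tuple(_snapped_edges(flat[:, d].min() - pad,
                                 flat[:, d].max() + pad, spacing)
                  for d in range(3))

    n_windows = ensemble.n_frames // window
    sasa = np.empty(n_windows)
    times = np.empty(n_windows)
    for w in range(n_windows):
        sel = slice(w * window, (w + 1) * window)
        frames = coords[sel]
        occ_all = np.zeros(tuple(len(e) - 1 for e in edges))
        occ_res = np.zeros_like(occ_all)
        for f in range(frames.shape[0]):
            occ_all += _vdw_binary(frames[f], radii, edges)
            occ_res += _vdw_binary(frames[f][res_in_heavy],
                                   radii[res_in_heavy], edges)
        occ_all /= window
        occ_res /= window
        solid = occ_all >= occupancy_threshold
        res_solid = occ_res >= occupancy_threshold
        surface = _surface_bins(solid, shell, spacing)
        raw = int((surface & res_solid).sum())
        max_surface = int(_surface_bins(res_solid, shell, spacing).sum())
        if max_surface == 0:
            raise ValueError("residue produced no occupied bins")
        sasa[w] = raw / max_surface
        times[w] = w * window + (window - 1) / 2
    return SasaSeries(window_times=times, sasa_norm=sasa,
                      residue=residue_label, grid_spacing=spacing,
                      occupancy_threshold=occupancy_threshold, shell=shell)


def ring_orientation(coords: np.ndarray, group_atom_sets,
                     axis_direction=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Angle (degrees) between each group's plane normal and the pore axis.

    The plane is the least-squares plane of the group's atoms (smallest
    principal component).  Angles are folded into [0, 90]; a ring lying in
    the membrane plane (normal along the axis) gives 0, a group plane
    containing the axis gives 90.
    """
    coords = np.asarray(coords, dtype=float)
    axis = np.asarray(axis_direction, dtype=float)
    axis = axis / np.linalg.norm(axis)
    angles = []
    for idx in group_atom_sets:
        pts = coords[np.asarray(idx)]
        if pts.shape[0] < 3:
            raise ValueError("each group needs at least 3 atoms")
        centered = pts - pts.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] < 1e-8 * max(s[0], 1e-30):
            raise ValueError("collinear group: plane is undefined")
        normal = vt[2]
        cosang = np.clip(abs(normal @ axis), 0.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
    return np.array(angles)


def pore_continuity(density: LinearDensityProfile,
                    z_range: tuple[float, float]) -> tuple[np.ndarray, float]:
    """Per-frame hydration continuity and the fraction of continuous frames.

    A frame is continuous when every slab whose center lies in ``z_range``
    has strictly positive water density - the proxy for a conductive,
    fully hydrated pore.
    """
    lo, hi = z_range
    cols = (density.z_centers >= lo) & (density.z_centers <= hi)
    if not cols.any():
        raise ValueError("z_range contains no slabs")
    continuous = np.all(density.density[:, cols] > 0, axis=1)
    return continuous, float(continuous.mean())


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (via biotite)


def write_pdb(ensemble: PoreEnsemble, path) -> None:
    """Write the ensemble as a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n_frames, n_atoms = ensemble.n_frames, ensemble.n_atoms
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = ensemble.coordinates.astype(np.float32)
    stack.chain_id = ensemble.chain_ids.astype("U4")
    stack.res_id = ensemble.resids.astype(int)
    stack.res_name = ensemble.resnames.astype("U5")
    stack.atom_name = ensemble.atomnames.astype("U6")
    stack.element = np.array([name[0] for name in ensemble.atomnames], dtype="U2")
    stack.hetero = np.isin(ensemble.resnames, WATER_RESNAMES)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb(path, axis_origin=(0.0, 0.0, 0.0),
             axis_direction=(0.0, 0.0, 1.0)) -> PoreEnsemble:
    """Read a multi-model PDB into a :class:`PoreEnsemble`.

    Van der Waals radii are assigned from the element (first letter of the
    atom name when the element record is missing).
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    elements = [el if el else name[0]
                for el, name in zip(stack.element, stack.atom_name)]
    radii = np.array([VDW_RADII.get(el.upper(), DEFAULT_VDW) for el in elements])
    return PoreEnsemble(
        coordinates=np.asarray(stack.coord, dtype=float),
        resnames=np.asarray(stack.res_name),
        atomnames=np.asarray(stack.atom_name),
        chain_ids=np.asarray(stack.chain_id),
        resids=np.asarray(stack.res_id, dtype=int),
        vdw_radii=radii,
        axis_origin=np.asarray(axis_origin, dtype=float),
        axis_direction=np.asarray(axis_direction, dtype=float),
    )
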