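"""Locally oriented voxel cubes around interfacial residues.

Each cube is a 24x24x24 grid of 0.8 Å voxels (19.2 Å per side) expressed
in a local orthonormal frame built from the residue's backbone N, CA and
C atoms.  Because the frame co-rotates with the structure, the cube values
are invariant to any rigid motion of the input complex.  Atoms are spread
onto the grid as truncated Gaussian densities, one channel per atom type.

For self-supervised training the central residue's neighbourhood is
partially hidden by deleting every atom inside a sphere (default radius
5 Å) centred on one of the central residue's heavy atoms; a fixed masked
volume avoids leaking amino-acid-specific size or shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .structure import Atom, ChannelScheme, Structure, channel_index

__all__ = [
    "GRID_SIZE",
    "VOXEL_SIDE",
    "LocalFrame",
    "CubeMap",
    "MaskSpec",
    "CubeAtom",
    "build_local_frame",
    "frame_for_residue",
    "extract_cube_atoms",
    "voxelize",
    "mask_sphere",
    "build_cube",
]

GRID_SIZE: int = 24
VOXEL_SIDE: float = 0.8  # Å
CUBE_HALF: float = GRID_SIZE * VOXEL_SIDE / 2.0  # 9.6 Å
#: Gaussian width of the atom density kernel (Å); truncated at 2 sigma.
KERNEL_SIGMA: float = VOXEL_SIDE
KERNEL_CUTOFF_SIGMAS: float = 2.0


@dataclass(frozen=True)
class LocalFrame:
    """Residue-local right-handed orthonormal frame (rows of ``axes``)."""

    origin: np.ndarray
    axes: np.ndarray  # 3x3, rows are basis vectors

    def to_local(self, coords: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(coords) - self.origin) @ self.axes.T


@dataclass(frozen=True)
class CubeAtom:
    """An atom together with its frame-local coordinates."""

    atom: Atom
    local: np.ndarray


@dataclass
class CubeMap:
    """Voxelized local environment of one residue."""

    grid: np.ndarray  # (24, 24, 24, n_channels)
    voxel_side: float
    center_residue: tuple[str, int, str]
    frame: LocalFrame
    scheme_mode: str

    @property
    def n_channels(self) -> int:
        return self.grid.shape[-1]


@dataclass(frozen=True)
class MaskSpec:
    """How the self-supervision mask is placed.

    ``center_policy`` is one of ``"CA"``, ``"CB"`` (falls back to CA for
    glycine) or ``"random"`` (uniform over the central residue's heavy
    atoms, drawn with ``seed``).
    """

    radius: float = 5.0
    center_policy: str = "random"
    seed: int = 0


def build_local_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> LocalFrame:
    """Orthonormal frame from the backbone scaffold of one residue.

    origin = CA; e1 = unit(N - CA); e3 = unit(e1 x (C - CA)); e2 = e3 x e1.
    Depends only on backbone atoms, hence defined for every residue type
    including glycine.  Raises ``ValueError`` for (near-)collinear input.
    """
    n, ca, c = (np.asarray(v, dtype=float) for v in (n, ca, c))
    v1 = n - ca
    v2 = c - ca
    norm1 = np.linalg.norm(v1)
    if norm1 < 1e-8:
        raise ValueError("N and CA coincide; cannot build local frame")
    e1 = v1 / norm1
    cross = np.cross(e1, v2)
    norm3 = np.linalg.norm(cross)
    if norm3 < 1e-8:
        raise ValueError("backbone N, CA, C are collinear; frame undefined")
    e3 = cross / norm3
    e2 = np.cross(e3, e1)
    return LocalFrame(origin=ca.copy(), axes=np.vstack([e1, e2, e3]))


def frame_for_residue(structure: Structure, key: tuple[str, int, str]) -> LocalFrame:
    """Frame of the residue identified by (chain, number, insertion code)."""
    atoms = {a.atom_name: a for a in structure.atoms if a.residue_key == key}
    missing = [nm for nm in ("N", "CA", "C") if nm not in atoms]
    if missing:
        raise ValueError(f"residue {key} lacks backbone atom(s) {missing}")
    return build_local_frame(atoms["N"].position, atoms["CA"].position,
                             atoms["C"].position)


def extract_cube_atoms(
    structure: Structure,
    center: tuple[str, int, str],
    frame: LocalFrame | None = None,
) -> list[CubeAtom]:
    """All heavy atoms (both partners) inside the 19.2 Å cube around ``center``.

    Voxel ownership is half-open and lower-inclusive: the cube covers
    [-9.6, 9.6) Å along each frame axis.
    """
    if frame is None:
        frame = frame_for_residue(structure, center)
    coords = structure.coords()
    local = frame.to_local(coords)
    inside = np.all((local >= -CUBE_HALF) & (local < CUBE_HALF), axis=1)
    return [
        CubeAtom(atom=structure.atoms[i], local=local[i])
        for i in np.flatnonzero(inside)
    ]


def _axis_weights(x: float, sigma: float, cutoff: float) -> tuple[int, np.ndarray]:
    """Integrated 1D kernel weights over the voxels intersecting the window.

    Returns (first voxel index, weights).  The Gaussian is truncated at
    ``cutoff`` sigmas and renormalized, so an atom far from the cube faces
    deposits exactly unit mass.
    """
    lo_w, hi_w = x - cutoff * sigma, x + cutoff * sigma
    i0 = max(int(np.floor((lo_w + CUBE_HALF) / VOXEL_SIDE)), 0)
    i1 = min(int(np.floor((hi_w + CUBE_HALF) / VOXEL_SIDE)), GRID_SIZE - 1)
    if i1 < i0:
        return 0, np.empty(0)
    edges = -CUBE_HALF + VOXEL_SIDE * np.arange(i0, i1 + 2)
    a = np.clip(edges[:-1], lo_w, hi_w)
    b = np.clip(edges[1:], lo_w, hi_w)
    z = ndtr((b - x) / sigma) - ndtr((a - x) / sigma)
    z /= ndtr(cutoff) - ndtr(-cutoff)
    return i0, z


def voxelize(
    cube_atoms: Sequence[CubeAtom],
    scheme: ChannelScheme,
    center_residue: tuple[str, int, str] = ("", 0, ""),
    frame: LocalFrame | None = None,
    sigma: float = KERNEL_SIGMA,
    cutoff_sigmas: float = KERNEL_CUTOFF_SIGMAS,
    dtype=np.float32,
) -> CubeMap:
    """Project atoms to the voxel grid as truncated Gaussian densities.

    Each atom contributes a separable Gaussian (width ``sigma``, truncated
    at ``cutoff_sigmas`` per axis, renormalized) integrated analytically
    over each voxel, into the atom's channel.  Contributions sum over
    atoms; density escaping through the cube boundary is lost.  An empty
    atom list yields an all-zero map.
    """
    grid = np.zeros((GRID_SIZE, GRID_SIZE, GRID_SIZE, scheme.n_channels),
                    dtype=dtype)
    for ca in cube_atoms:
        ch = channel_index(scheme, ca.atom)
        ix, wx = _axis_weights(float(ca.local[0]), sigma, cutoff_sigmas)
        iy, wy = _axis_weights(float(ca.local[1]), sigma, cutoff_sigmas)
        iz, wz = _axis_weights(float(ca.local[2]), sigma, cutoff_sigmas)
        if wx.size == 0 or wy.size == 0 or wz.size == 0:
            continue
        block = wx[:, None, None] * wy[None, :, None] * wz[None, None, :]
        grid[ix:ix + wx.size, iy:iy + wy.size, iz:iz + wz.size, ch] += \
            block.astype(dtype)
    if frame is None:
        frame = LocalFrame(np.zeros(3), np.eye(3))
    return CubeMap(grid=grid, voxel_side=VOXEL_SIDE,
                   center_residue=center_residue, frame=frame,
                   scheme_mode=scheme.mode)


def mask_sphere(
    cube_atoms: Sequence[CubeAtom],
    center_residue_atoms: Sequence[CubeAtom],
    spec: MaskSpec = MaskSpec(),
) -> tuple[list[CubeAtom], np.ndarray]:
    """Delete every atom strictly inside the masking sphere.

    The sphere centre is one of the central residue's heavy atoms, chosen
    per ``spec.center_policy``; atoms of *any* residue or partner whose
    centre lies at distance < ``spec.radius`` from it are removed (distance
    exactly equal to the radius is kept).  Deterministic given the seed.

    Returns (remaining atoms, sphere centre in frame-local coordinates).
    """
    if not center_residue_atoms:
        raise ValueError("central residue has no heavy atoms to centre the mask on")
    by_name = {ca.atom.atom_name: ca for ca in center_residue_atoms}
    policy = spec.center_policy
    if policy == "CA":
        chosen = by_name.get("CA")
        if chosen is None:
            raise ValueError("central residue lacks a CA atom")
    elif policy == "CB":
        chosen = by_name.get("CB", by_name.get("CA"))
        if chosen is None:
            raise ValueError("central residue lacks both CB and CA atoms")
    elif policy == "random":
        rng = np.random.default_rng(spec.seed)
        chosen = center_residue_atoms[rng.integers(len(center_residue_atoms))]
    else:
        raise ValueError(f"unknown mask centre policy {policy!r}")
    center = np.asarray(chosen.local, dtype=float)
    kept = [
        ca for ca in cube_atoms
        if np.linalg.norm(np.asarray(ca.local) - center) >= spec.radius
    ]
    return kept, center


def build_cube(
    structure: Structure,
    center: tuple[str, int, str],
    scheme: ChannelScheme,
    mask: MaskSpec | None = None,
) -> CubeMap:
    """Full pipeline: frame, atom extraction, optional masking, voxelization."""
    frame = frame_for_residue(structure, center)
    cube_atoms = extract_cube_atoms(structure, center, frame)
    if mask is not None:
        central = [ca for ca in cube_atoms if ca.atom.residue_key == center]
        cube_atoms, _ = mask_sphere(cube_atoms, central, mask)
    return voxelize(cube_atoms, scheme, center_residue=center, frame=frame)
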