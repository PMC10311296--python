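"""Synthetic structures, cubes and mutation datasets with known truth.

Everything here is deliberately idealized rather than physically
realistic: the geometry code and the networks only require consistent,
reproducible shapes.  Three generators cover the needs of offline
testing and desk-scale experiments:

* :func:`make_toy_complex` — a two-chain complex whose interface is a
  designed contact patch, emitted as a valid PDB structure;
* :func:`make_labeled_cubes` — masked voxel cubes whose central-residue
  label is encoded in a distinctive planted environment, for the
  masked-residue recovery task;
* :func:`make_synthetic_ddg` — wild-type/mutant cube pairs whose target
  is a known linear function of a cube-visible quantity (the atom-count
  difference near the mutation site) plus one auxiliary scalar and
  Gaussian noise, for parameter-recovery experiments.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure import (Atom, ChannelScheme, HEAVY_ATOMS, ONE_TO_THREE,
                        Structure, build_channel_scheme)
from .voxels import (CubeAtom, LocalFrame, MaskSpec, build_local_frame,
                     mask_sphere, voxelize)

__all__ = [
    "AMINO_ACIDS",
    "ToyComplexSpec",
    "ToyComplex",
    "make_toy_complex",
    "residue_template",
    "LabeledCubes",
    "make_labeled_cube_atoms",
    "make_labeled_cubes",
    "SyntheticDdg",
    "make_synthetic_ddg",
]

#: Amino acids in one-letter alphabetical order; the label index space of
#: the masked-residue task.
AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

# Idealized backbone internal coordinates (Å), CA at the origin.
_N = np.array([-1.458, 0.0, 0.0])
_C = np.array([0.551, 1.420, 0.0])
_O = np.array([1.790, 1.560, 0.280])
_CB = np.array([0.540, -0.780, -1.210])
_SC_DIR = np.array([0.20, -0.50, -1.00]) / np.linalg.norm([0.20, -0.50, -1.00])
_SC_PERP = np.array([1.0, 0.20, 0.0]) / np.linalg.norm([1.0, 0.20, 0.0])


def residue_template(res3: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of one idealized residue, CA at origin.

    Backbone atoms use canonical local geometry; side-chain atoms are
    laid out along a fixed zig-zag from CB.  Deterministic per type.
    """
    coords = {"N": _N.copy(), "CA": np.zeros(3), "C": _C.copy(), "O": _O.copy()}
    names = HEAVY_ATOMS[res3]
    side = [nm for nm in names if nm not in coords]
    for i, nm in enumerate(side):
        if nm == "CB":
            coords[nm] = _CB.copy()
        else:
            coords[nm] = (_CB + 1.25 * (i) * _SC_DIR
                          + 0.55 * ((-1) ** i) * _SC_PERP)
    return {nm: coords[nm] for nm in names}


@dataclass(frozen=True)
class ToyComplexSpec:
    """Recipe for a synthetic two-chain complex.

    ``gap`` adds extra separation between the chains on top of the
    designed contact distance: 0 gives a contacting interface, large
    values pull the partners apart entirely.
    """

    n_residues: int = 12
    patch_size: int = 6
    gap: float = 0.0
    seed: int = 0


@dataclass
class ToyComplex:
    structure: Structure
    patch_keys: set  # residue keys designed to bury surface on binding


# CA-plane separation at which the facing patch residues bury surface
# against each other even for the smallest side chains.
_CONTACT_DISTANCE: float = 5.5
# Lateral displacement isolating non-patch residues from the interface.
_TAIL_OFFSET: float = 30.0
_CA_SPACING: float = 3.8


def make_toy_complex(spec: ToyComplexSpec = ToyComplexSpec()) -> ToyComplex:
    """Build the two-chain complex described by ``spec``.

    Chain A lies along x with side chains pointing -z; chain B is the
    180°-about-x flip placed underneath, side chains pointing up, so the
    central ``patch_size`` residues of both chains bury surface against
    each other.  Non-patch residues are displaced laterally (chain A one
    way, chain B the other) so that burial is confined to exactly the
    designed patch.  Residue types are drawn from the seed.
    """
    if spec.patch_size > spec.n_residues:
        raise ValueError("patch size exceeds chain length")
    if spec.n_residues < 1:
        raise ValueError("need at least one residue per chain")
    rng = np.random.default_rng(spec.seed)
    start = (spec.n_residues - spec.patch_size) // 2
    patch_idx = set(range(start, start + spec.patch_size))

    atoms: list[Atom] = []
    patch_keys: set = set()
    plane_z = -(_CONTACT_DISTANCE + spec.gap)
    for chain, flip in (("A", False), ("B", True)):
        seq = [AMINO_ACIDS[i] for i in rng.integers(0, 20, spec.n_residues)]
        for j, aa in enumerate(seq):
            res3 = ONE_TO_THREE[aa]
            template = residue_template(res3)
            base = np.array([_CA_SPACING * j, 0.0, 0.0])
            in_patch = j in patch_idx
            for nm, local in template.items():
                pos = local.copy()
                if flip:
                    pos = pos * np.array([1.0, -1.0, -1.0])
                    pos += base + np.array([0.0, 0.0, plane_z])
                    if not in_patch:
                        pos += np.array([0.0, -_TAIL_OFFSET, 0.0])
                else:
                    pos += base
                    if not in_patch:
                        pos += np.array([0.0, _TAIL_OFFSET, 0.0])
                atoms.append(Atom(
                    chain_id=chain, residue_number=j + 1, insertion_code="",
                    residue_name=res3, atom_name=nm, element=nm[0],
                    position=pos,
                ))
            if in_patch:
                patch_keys.add((chain, j + 1, ""))
    structure = Structure(atoms, frozenset({"A"}), frozenset({"B"}))
    return ToyComplex(structure=structure, patch_keys=patch_keys)


# ---------------------------------------------------------------------------
# labeled cubes for the masked-residue task

_ENV_ELEMENTS = ("C", "N", "O", "S")
_ENV_ATOM_OF = {"C": "CA", "N": "N", "O": "O", "S": None}


def _env_atom(element: str, pos: np.ndarray, idx: int) -> Atom:
    """A free-standing environment atom encoded as a standard heavy atom.

    Carbon/nitrogen/oxygen ride on glycine backbone channels; sulfur uses
    the cysteine SG channel, so both channel schemes accept every atom.
    """
    if element == "S":
        res, name = "CYS", "SG"
    else:
        res, name = "GLY", _ENV_ATOM_OF[element]
    return Atom(chain_id="E", residue_number=1000 + idx, insertion_code="",
                residue_name=res, atom_name=name, element=element,
                position=pos)


def _central_residue_atoms(aa: str) -> list[CubeAtom]:
    res3 = ONE_TO_THREE[aa]
    template = residue_template(res3)
    return [
        CubeAtom(
            atom=Atom(chain_id="A", residue_number=1, insertion_code="",
                      residue_name=res3, atom_name=nm, element=nm[0],
                      position=pos.copy()),
            local=pos.copy(),
        )
        for nm, pos in template.items()
    ]


def make_labeled_cube_atoms(
    label: int, rng: np.random.Generator
) -> tuple[list[CubeAtom], list[CubeAtom]]:
    """Pre-mask atoms of one labeled cube: (all atoms, central residue atoms).

    The environment plants a label-specific constellation on a shell
    around the central residue, outside the reach of the default 5 Å
    mask: ``6 + label`` atoms whose angular layout, shell radius and
    element pattern all depend on the label, plus 0.25 Å jitter so
    repeated samples of one class differ.
    """
    aa = AMINO_ACIDS[label]
    central = _central_residue_atoms(aa)
    n_env = 6 + label
    radius = 8.0 + 0.4 * np.sin(label * 1.7)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    env: list[CubeAtom] = []
    for k in range(n_env):
        # deterministic spherical spiral, phase-shifted by label
        z = 1.0 - 2.0 * (k + 0.5) / n_env
        r_xy = np.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * k + 0.35 * label
        direction = np.array([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
        pos = radius * direction + rng.normal(0.0, 0.25, 3)
        pos = np.clip(pos, -9.3, 9.3)
        element = _ENV_ELEMENTS[(label + k) % 4]
        env.append(CubeAtom(atom=_env_atom(element, pos, k), local=pos.copy()))
    return central + env, central


@dataclass
class LabeledCubes:
    cubes: np.ndarray     # (n, 24, 24, 24, C)
    labels: np.ndarray    # (n,) int in [0, 20)
    scheme_mode: str


def make_labeled_cubes(
    n: int,
    scheme: ChannelScheme | None = None,
    seed: int = 0,
    mask: MaskSpec | None = None,
) -> LabeledCubes:
    """Masked, voxelized cubes with ground-truth central-residue labels.

    Labels cycle through the 20 amino acids so every class appears for
    n >= 20.  Each cube is masked with the default self-supervision
    policy (5 Å sphere, random centre) before voxelization.
    """
    if n < 20:
        raise ValueError("need n >= 20 to cover the amino-acid classes")
    if scheme is None:
        scheme = build_channel_scheme("element4")
    rng = np.random.default_rng(seed)
    cubes = np.zeros((n, 24, 24, 24, scheme.n_channels), dtype=np.float32)
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        label = i % 20
        atoms, central = make_labeled_cube_atoms(label, rng)
        spec = mask if mask is not None else MaskSpec(seed=seed * 100003 + i)
        kept, _ = mask_sphere(atoms, central, spec)
        cubes[i] = voxelize(kept, scheme).grid
        labels[i] = label
    return LabeledCubes(cubes=cubes, labels=labels, scheme_mode=scheme.mode)


# ---------------------------------------------------------------------------
# synthetic mutation dataset with planted linear signal

@dataclass
class SyntheticDdg:
    wt_cubes: np.ndarray
    mu_cubes: np.ndarray
    aux: np.ndarray          # (n, 9) encoded auxiliary vectors
    targets: np.ndarray      # (n,) kcal/mol
    alpha: float             # weight of the cube-visible atom-count difference
    beta: float              # weight of the auxiliary scalar
    count_diff: np.ndarray   # (n,) planted atom-count differences
    scheme_mode: str


def make_synthetic_ddg(
    n: int,
    noise_sd: float = 0.3,
    seed: int = 0,
    scheme: ChannelScheme | None = None,
    alpha: float = 0.4,
    beta: float = 1.0,
) -> SyntheticDdg:
    """Wild-type/mutant cube pairs with a known linear target.

    Both cubes of a pair share a random far environment; they differ in
    the number of atoms placed inside a 4.5 Å sphere around the centre
    (the "mutation site").  The regression target is

        target = alpha * (n_wt - n_mu) + beta * aux_scalar + noise

    with ``aux_scalar`` standard normal, stored in the substitution-score
    slot of the 9-dim auxiliary vector, and Gaussian noise of standard
    deviation ``noise_sd``.  With ``noise_sd=0`` the targets are an exact
    deterministic function of the inputs.
    """
    if n < 20:
        raise ValueError("need n >= 20 pairs")
    if scheme is None:
        scheme = build_channel_scheme("element4")
    rng = np.random.default_rng(seed)
    shape = (n, 24, 24, 24, scheme.n_channels)
    wt_cubes = np.zeros(shape, dtype=np.float32)
    mu_cubes = np.zeros(shape, dtype=np.float32)
    aux = np.zeros((n, 9), dtype=np.float32)
    count_diff = np.zeros(n, dtype=int)
    targets = np.zeros(n)

    for i in range(n):
        env: list[CubeAtom] = []
        n_far = int(rng.integers(15, 25))
        for k in range(n_far):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = direction * rng.uniform(6.0, 9.0)
            env.append(CubeAtom(
                atom=_env_atom(_ENV_ELEMENTS[k % 4], pos, k), local=pos))

        def site_atoms(count: int, offset: int) -> list[CubeAtom]:
            out = []
            for k in range(count):
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = direction * rng.uniform(0.5, 4.5)
                out.append(CubeAtom(
                    atom=_env_atom("C", pos, 100 + offset + k), local=pos))
            return out

        n_wt = int(rng.integers(2, 11))
        n_mu = int(rng.integers(2, 11))
        wt_cubes[i] = voxelize(env + site_atoms(n_wt, 0), scheme).grid
        mu_cubes[i] = voxelize(env + site_atoms(n_mu, 50), scheme).grid
        scalar = rng.normal()
        aux[i, 8] = scalar  # substitution-score slot
        aux[i, 3] = 1.0     # SR one-hot: SUR (constant across the set)
        count_diff[i] = n_wt - n_mu
        targets[i] = (alpha * (n_wt - n_mu) + beta * scalar
                      + rng.normal(0.0, noise_sd))
    return SyntheticDdg(wt_cubes=wt_cubes, mu_cubes=mu_cubes, aux=aux,
                        targets=targets, alpha=alpha, beta=beta,
                        count_diff=count_diff, scheme_mode=scheme.mode)
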