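"""Auxiliary residue descriptors for the mutation-effect predictor.

Five features accompany the two voxel cubes: the wild-type residue's
evolutionary conservation level (T_JET, in [0,1]), its interface
physicochemical propensity (PC), its protrusion measured by circular
variance (CV), its structural region (SR, 5-way one-hot), and a
mutation-specific substitution score (GEMME-style, computed externally
and parsed here).  The encoded vector is
``[t_jet, pc, cv, sr one-hot x5, gemme]`` of fixed length 9.

Also provides the categorical schemes used for stratified evaluation:
the seven amino-acid similarity classes and the three-way side-chain
volume-change classification of substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import REGION_LABELS, RegionLabel
from .structure import ONE_TO_THREE

__all__ = [
    "AMINO_CLASSES",
    "RESIDUE_VOLUME",
    "INTERFACE_PROPENSITY",
    "AuxFeatures",
    "circular_variance",
    "amino_class",
    "size_change_class",
    "load_conservation",
    "load_gemme",
    "assemble_aux",
    "minmax_scale_aux",
]

#: Indices of the scalar slots in the encoded auxiliary vector.
AUX_SCALAR_SLOTS: tuple[int, ...] = (0, 1, 2, 8)

# Seven similarity classes partitioning the 20 amino acids:
# aromatic; small/hydroxyl+Cys+Ala; aliphatic hydrophobic; positive;
# polar & negative; glycine; proline.
AMINO_CLASSES: dict[str, tuple[str, ...]] = {
    "ARO": ("F", "W", "Y", "H"),
    "CAST": ("C", "A", "S", "T"),
    "PHOB": ("I", "L", "M", "V"),
    "POS": ("K", "R"),
    "POL-N": ("N", "Q", "D", "E"),
    "GLY": ("G",),
    "PRO": ("P",),
}
_CLASS_OF: dict[str, str] = {
    aa: cls for cls, members in AMINO_CLASSES.items() for aa in members
}

# Mean residue volumes, Å³ (Zamyatnin 1972 consensus values).
RESIDUE_VOLUME: dict[str, float] = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Bundled default interface-propensity scale (log-odds of occurrence in
# protein-protein interfaces vs. whole surface; hydrophobic and aromatic
# residues favoured, charged/polar disfavoured).  Swappable: any
# per-residue scalar table can be passed to `assemble_aux`.
INTERFACE_PROPENSITY: dict[str, float] = {
    "A": -0.17, "R": -0.07, "N": -0.24, "D": -0.38, "C": 0.43,
    "Q": -0.11, "E": -0.50, "G": -0.14, "H": 0.25, "I": 0.44,
    "L": 0.40, "K": -0.55, "M": 0.66, "F": 0.82, "P": -0.25,
    "S": -0.33, "T": -0.18, "W": 0.83, "Y": 0.66, "V": 0.27,
}

#: Neighbour cutoff for circular variance, Å.
CV_CUTOFF: float = 12.0

#: Threshold on side-chain volume change, Å³.
SIZE_CHANGE_THRESHOLD: float = 10.0

AUX_LENGTH: int = 9  # 4 scalars + 5-way SR one-hot
#: Named ablation configurations: which scalar slots stay active.
ABLATIONS: dict[str, tuple[str, ...]] = {
    "SR": (),
    "SR-Tjet": ("t_jet",),
    "SR-GEMME": ("gemme",),
    "All": ("t_jet", "pc", "cv", "gemme"),
}


@dataclass(frozen=True)
class AuxFeatures:
    """The five auxiliary descriptors of one mutation.

    All but ``gemme`` describe the wild-type residue; ``gemme`` is
    specific to the substitution.
    """

    t_jet: float
    pc: float
    cv: float
    sr: RegionLabel
    gemme: float


def circular_variance(center: np.ndarray, neighbors: np.ndarray) -> float:
    """Protrusion of a point amid its neighbours, in [0, 1].

    CV = 1 - || mean of unit vectors from ``center`` to each neighbour ||.
    Values near 0 indicate a protruding point (all neighbours on one
    side), values near 1 a buried one (neighbours all around).  Raises
    ``ValueError`` with zero neighbours.
    """
    center = np.asarray(center, dtype=float)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if neighbors.size == 0:
        raise ValueError("circular variance undefined for an isolated atom")
    vecs = neighbors - center
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("a neighbour coincides with the centre")
    units = vecs / norms[:, None]
    return float(1.0 - np.linalg.norm(units.mean(axis=0)))


def residue_circular_variance(
    structure, key: tuple[str, int, str], cutoff: float = CV_CUTOFF
) -> float:
    """CV of a residue's CA against heavy atoms of other residues within cutoff."""
    ca = next(
        (a for a in structure.atoms
         if a.residue_key == key and a.atom_name == "CA"), None)
    if ca is None:
        raise ValueError(f"residue {key} has no CA atom")
    others = np.asarray([
        a.position for a in structure.atoms
        if a.residue_key != key
        and np.linalg.norm(a.position - ca.position) <= cutoff
    ])
    return circular_variance(ca.position, others)


def amino_class(code: str) -> str:
    """Similarity class of a one-letter amino-acid code."""
    try:
        return _CLASS_OF[code.upper()]
    except KeyError:
        raise KeyError(f"unknown amino-acid code {code!r}") from None


def size_change_class(
    wt: str,
    mut: str,
    volumes: dict[str, float] | None = None,
    threshold: float = SIZE_CHANGE_THRESHOLD,
) -> str:
    """Classify a substitution by side-chain volume change.

    δV = V(mut) - V(wt); |δV| < threshold (default 10 Å³) is
    ``size-neutral``, larger positive changes ``small-to-large``, larger
    negative ones ``large-to-small``.
    """
    vols = volumes if volumes is not None else RESIDUE_VOLUME
    for code in (wt, mut):
        if code.upper() not in vols:
            raise KeyError(f"unknown amino-acid code {code!r}")
    dv = vols[mut.upper()] - vols[wt.upper()]
    if dv > threshold:
        return "small-to-large"
    if dv < -threshold:
        return "large-to-small"
    return "size-neutral"


def _read_table(path: str | Path, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing column(s) {missing}; found {list(df.columns)}"
        )
    return df


def load_conservation(path: str | Path) -> dict[tuple[str, int], float]:
    """Parse a per-residue conservation file.

    Expects a whitespace- or tab-delimited table with a header containing
    columns ``chain``, ``resnum`` and ``tjet``.  Duplicated (chain,
    resnum) keys with conflicting values raise ``ValueError``.
    """
    df = _read_table(path, ["chain", "resnum", "tjet"])
    out: dict[tuple[str, int], float] = {}
    for _, row in df.iterrows():
        key = (str(row["chain"]), int(row["resnum"]))
        val = float(row["tjet"])
        if key in out and out[key] != val:
            raise ValueError(f"conflicting conservation values for {key}")
        out[key] = val
    return out


def load_gemme(path: str | Path) -> dict[tuple[str, int, str], float]:
    """Parse a per-mutation substitution-score file.

    Columns: ``chain``, ``resnum``, ``mut`` (one-letter target amino
    acid), ``score``.  Conflicting duplicates raise ``ValueError``.
    """
    df = _read_table(path, ["chain", "resnum", "mut", "score"])
    out: dict[tuple[str, int, str], float] = {}
    for _, row in df.iterrows():
        key = (str(row["chain"]), int(row["resnum"]), str(row["mut"]).upper())
        val = float(row["score"])
        if key in out and out[key] != val:
            raise ValueError(f"conflicting substitution scores for {key}")
        out[key] = val
    return out


def encode_sr(sr: RegionLabel) -> np.ndarray:
    """5-way one-hot over (INT, SUR, SUP, COR, RIM)."""
    if sr not in REGION_LABELS:
        raise ValueError(f"unknown region label {sr!r}")
    vec = np.zeros(len(REGION_LABELS))
    vec[REGION_LABELS.index(sr)] = 1.0
    return vec


def assemble_aux(features: AuxFeatures, ablation: str = "All") -> np.ndarray:
    """Encode the auxiliary features as a fixed-length vector.

    Order: ``[t_jet, pc, cv, sr one-hot x5, gemme]`` (length 9).  Under an
    ablation configuration the inactive scalar slots are zeroed; the SR
    one-hot and the vector length are always kept, so trained heads remain
    shape-compatible across configurations.
    """
    if ablation not in ABLATIONS:
        raise ValueError(
            f"unknown ablation {ablation!r}; choose from {sorted(ABLATIONS)}")
    for name in ("t_jet", "pc", "cv", "gemme"):
        if getattr(features, name) is None or not np.isfinite(getattr(features, name)):
            raise ValueError(f"auxiliary feature {name!r} is missing or non-finite")
    active = ABLATIONS[ablation]
    scal = {n: (getattr(features, n) if n in active else 0.0)
            for n in ("t_jet", "pc", "cv", "gemme")}
    return np.concatenate([
        [scal["t_jet"], scal["pc"], scal["cv"]],
        encode_sr(features.sr),
        [scal["gemme"]],
    ])


def minmax_scale_aux(
    aux_train: np.ndarray, aux_other: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Min-max scale the scalar slots of encoded auxiliary vectors.

    The four scalar slots (t_jet, pc, cv, gemme) are mapped to [0, 1]
    using minima/maxima estimated on ``aux_train`` only; ``aux_other``
    (e.g. a test set) is transformed with the same training-set bounds.
    Constant slots are left unchanged.  The SR one-hot block is never
    touched.  Returns scaled copies.
    """
    train = np.array(aux_train, dtype=float)
    other = None if aux_other is None else np.array(aux_other, dtype=float)
    for j in AUX_SCALAR_SLOTS:
        lo, hi = train[:, j].min(), train[:, j].max()
        if hi - lo < 1e-12:
            continue
        train[:, j] = (train[:, j] - lo) / (hi - lo)
        if other is not None:
            other[:, j] = (other[:, j] - lo) / (hi - lo)
    return train, other
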