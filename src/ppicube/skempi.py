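"""Mutation/affinity table handling, splits, and evaluation metrics.

Reads SKEMPI-v2-style semicolon-separated tables of point mutations with
measured dissociation constants for wild-type and mutant complexes,
derives the binding free-energy change

    ΔΔG_bind = ΔG_mut − ΔG_wt,   ΔG = R T ln(Kd)   [kcal/mol]

(positive = destabilizing), filters to single-point mutations measured
by reliable techniques, builds mutation-level k-fold or complex-level
held-out splits, and computes Pearson correlation / RMSE overall and per
stratum.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "RELIABLE_METHODS",
    "MutationRecord",
    "SplitPlan",
    "parse_skempi",
    "ddg_from_affinities",
    "make_split",
    "filter_by_identity",
    "evaluate",
]

#: Gas constant, kcal / (mol K).
GAS_CONSTANT_KCAL: float = 1.9872e-3
#: Temperature assumed when a row does not state one, K.
DEFAULT_TEMPERATURE: float = 298.0

# Reliable measurement techniques (SKEMPI method codes and long names).
RELIABLE_METHODS: frozenset[str] = frozenset({
    "ITC", "ISOTHERMAL TITRATION CALORIMETRY",
    "SPR", "SURFACE PLASMON RESONANCE",
    "SP", "SPECTROSCOPY",
    "FL", "FLUORESCENCE",
    "SF", "STOPPED-FLOW FLUORIMETRY", "STOPPED FLOW", "SFFL",
})

FUNCTION_CLASSES: tuple[str, ...] = ("AB/AG", "Pr/PI", "TCR/pMHC", "other")

_MUTATION_RE = re.compile(r"^([A-Z])([A-Za-z0-9])(\d+)([A-Za-z]?)([A-Z])$")


@dataclass(frozen=True)
class MutationRecord:
    """One single-point mutation with its derived ground truth."""

    complex_id: str           # PDB code + partner chains, e.g. "1CSE_E_I"
    chain: str
    residue_number: int
    insertion_code: str
    wt_aa: str
    mut_aa: str
    affinity_wt: float        # Kd, M
    affinity_mut: float       # Kd, M
    temperature: float        # K
    method: str
    ddg: float                # kcal/mol
    function_class: str = "other"

    @property
    def mutation_id(self) -> str:
        icode = self.insertion_code or ""
        return (f"{self.wt_aa}{self.chain}{self.residue_number}"
                f"{icode}{self.mut_aa}")


def ddg_from_affinities(
    kd_wt: float, kd_mut: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """Binding free-energy change from wild-type and mutant Kd.

    ΔG = R·T·ln(Kd); ΔΔG = ΔG_mut − ΔG_wt.  Positive values mean the
    mutation weakens binding.  Antisymmetric under swapping wt and mut.
    """
    if kd_wt <= 0 or kd_mut <= 0:
        raise ValueError("dissociation constants must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd_mut / kd_wt)


def parse_mutation_string(s: str) -> tuple[str, str, int, str, str]:
    """Decompose e.g. ``"KI38A"`` into (wt, chain, position, icode, mut)."""
    m = _MUTATION_RE.match(s.strip())
    if not m:
        raise ValueError(f"malformed mutation string {s!r}")
    wt, chain, pos, icode, mut = m.groups()
    return wt, chain, int(pos), icode, mut


def _parse_temperature(raw) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return DEFAULT_TEMPERATURE
    m = re.search(r"(\d+(?:\.\d+)?)", str(raw))
    return float(m.group(1)) if m else DEFAULT_TEMPERATURE


def parse_skempi(
    path: str | Path,
    allowed_methods: frozenset[str] | None = RELIABLE_METHODS,
    aggregate: str = "median",
) -> list[MutationRecord]:
    """Parse a SKEMPI-v2-dialect table into clean mutation records.

    Keeps rows that (i) carry a single-point mutation, (ii) were measured
    by an allowed method (``allowed_methods=None`` disables the filter),
    and (iii) have positive wild-type and mutant affinities.  Every drop
    is logged with its reason.  Replicate measurements of the same
    (complex, mutation) are aggregated to their median ΔΔG (policy
    configurable: ``"median"`` or ``"mean"``); the replicate count is
    logged.
    """
    df = pd.read_csv(path, sep=";")
    required = ["#Pdb", "Mutation(s)_cleaned", "Affinity_mut_parsed",
                "Affinity_wt_parsed", "Method"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if aggregate not in ("median", "mean"):
        raise ValueError(f"unknown aggregation policy {aggregate!r}")

    records: list[MutationRecord] = []
    for i, row in df.iterrows():
        mut_str = str(row["Mutation(s)_cleaned"]).strip()
        if "," in mut_str:
            logger.info("row %d dropped: multi-point mutation %r", i, mut_str)
            continue
        method = str(row["Method"]).strip().upper()
        if allowed_methods is not None and method not in allowed_methods:
            logger.info("row %d dropped: method %r not allowed", i, method)
            continue
        try:
            wt, chain, pos, icode, mut = parse_mutation_string(mut_str)
        except ValueError as exc:
            logger.warning("row %d rejected: %s", i, exc)
            continue
        try:
            kd_mut = float(row["Affinity_mut_parsed"])
            kd_wt = float(row["Affinity_wt_parsed"])
        except (TypeError, ValueError):
            logger.info("row %d dropped: unparsable affinity", i)
            continue
        if not (kd_mut > 0 and kd_wt > 0) or np.isnan(kd_mut) or np.isnan(kd_wt):
            logger.info("row %d dropped: non-positive or missing affinity", i)
            continue
        temp = _parse_temperature(row.get("Temperature"))
        func = str(row.get("Hold_out_type", "") or "").strip()
        records.append(MutationRecord(
            complex_id=str(row["#Pdb"]).strip(),
            chain=chain, residue_number=pos, insertion_code=icode,
            wt_aa=wt, mut_aa=mut,
            affinity_wt=kd_wt, affinity_mut=kd_mut,
            temperature=temp, method=method,
            ddg=ddg_from_affinities(kd_wt, kd_mut, temp),
            function_class=func if func in FUNCTION_CLASSES[:-1] else "other",
        ))

    # replicate aggregation
    groups: dict[tuple[str, str], list[MutationRecord]] = {}
    for rec in records:
        groups.setdefault((rec.complex_id, rec.mutation_id), []).append(rec)
    out: list[MutationRecord] = []
    for key, reps in groups.items():
        if len(reps) == 1:
            out.append(reps[0])
            continue
        logger.info("aggregating %d replicate measurements for %s", len(reps), key)
        vals = [r.ddg for r in reps]
        agg = float(np.median(vals) if aggregate == "median" else np.mean(vals))
        first = reps[0]
        out.append(MutationRecord(
            **{**asdict(first), "ddg": agg}))
    return out


@dataclass
class SplitPlan:
    """A train/test partitioning of mutation records.

    ``level`` is ``"mutation"`` (k-fold over records) or ``"complex"``
    (whole complexes held out; no complex id appears on both sides).
    """

    level: str
    seed: int
    folds: list[dict[str, list[int]]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"level": self.level, "seed": self.seed,
                       "folds": self.folds}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(level=d["level"], seed=d["seed"], folds=d["folds"])


def make_split(
    records: list[MutationRecord],
    level: str = "mutation",
    k: int = 10,
    held_out_fraction: float | None = None,
    seed: int = 0,
) -> SplitPlan:
    """Build a mutation-level k-fold or complex-level held-out split.

    Mutation level: seeded, shuffled k-fold over individual records.
    Complex level: when ``held_out_fraction`` is given, a single split
    holding out that fraction of complexes (at least one); otherwise a
    k-fold over complexes.  Complex-level plans never let a complex id
    appear in both train and test of the same fold.
    """
    n = len(records)
    plan = SplitPlan(level=level, seed=seed)
    if level == "mutation":
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        for train_idx, test_idx in kf.split(np.arange(n)):
            plan.folds.append({"train": train_idx.tolist(),
                               "test": test_idx.tolist()})
        return plan
    if level != "complex":
        raise ValueError(f"unknown split level {level!r}")

    complexes = sorted({r.complex_id for r in records})
    if len(complexes) < 2:
        raise ValueError("complex-level split needs at least 2 complexes")
    rng = np.random.default_rng(seed)
    by_complex: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_complex.setdefault(r.complex_id, []).append(i)

    def fold_from(test_cplx: set[str]) -> dict[str, list[int]]:
        test = sorted(i for c in test_cplx for i in by_complex[c])
        train = sorted(i for c in complexes if c not in test_cplx
                       for i in by_complex[c])
        return {"train": train, "test": test}

    if held_out_fraction is not None:
        n_test = max(1, round(held_out_fraction * len(complexes)))
        if n_test >= len(complexes):
            raise ValueError("held-out fraction leaves no training complexes")
        test_cplx = set(rng.choice(complexes, size=n_test, replace=False).tolist())
        plan.folds.append(fold_from(test_cplx))
    else:
        order = rng.permutation(len(complexes))
        for chunk in np.array_split(order, k):
            plan.folds.append(fold_from({complexes[j] for j in chunk}))
    return plan


def filter_by_identity(
    records: list[MutationRecord],
    identity: dict[tuple[str, str], float],
    test_complexes: set[str],
    max_identity: float = 0.30,
) -> list[MutationRecord]:
    """Drop training records from complexes similar to any test complex.

    ``identity`` maps unordered complex-id pairs to fractional sequence
    identity (precomputed externally; this package does not align).  A
    record survives if its complex shares less than ``max_identity`` with
    every test complex; pairs absent from the matrix are treated as
    dissimilar.  Records belonging to a test complex are dropped.
    """
    def ident(a: str, b: str) -> float:
        return max(identity.get((a, b), 0.0), identity.get((b, a), 0.0))

    kept = []
    for rec in records:
        if rec.complex_id in test_complexes:
            continue
        if all(ident(rec.complex_id, t) < max_identity for t in test_complexes):
            kept.append(rec)
    return kept


def _pcc_rmse(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    pcc = float(stats.pearsonr(pred, truth).statistic)
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    return pcc, rmse


def evaluate(
    predictions: np.ndarray,
    truths: np.ndarray,
    strata: np.ndarray | list | None = None,
) -> dict:
    """Pearson correlation and RMSE, overall and per stratum.

    Strata with fewer than 2 points are reported with ``None`` metrics
    rather than silently dropped.  Returns a dict::

        {"overall": {"pcc", "rmse", "n"},
         "strata": {label: {"pcc", "rmse", "n"}, ...}}
    """
    pred = np.asarray(predictions, dtype=float)
    truth = np.asarray(truths, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {pred.shape} predictions vs {truth.shape} truths")
    if pred.size < 2:
        raise ValueError("need at least 2 points to evaluate")
    pcc, rmse = _pcc_rmse(pred, truth)
    out = {"overall": {"pcc": pcc, "rmse": rmse, "n": int(pred.size)},
           "strata": {}}
    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape[0] != pred.size:
            raise ValueError("strata labels length mismatch")
        for label in np.unique(strata):
            m = strata == label
            if m.sum() < 2:
                out["strata"][str(label)] = {"pcc": None, "rmse": None,
                                             "n": int(m.sum())}
            else:
                p, r = _pcc_rmse(pred[m], truth[m])
                out["strata"][str(label)] = {"pcc": p, "rmse": r,
                                             "n": int(m.sum())}
    return out


def write_predictions(
    records: list[MutationRecord],
    predictions: np.ndarray,
    path: str | Path,
) -> None:
    """TSV: complex, mutation, predicted ΔΔG, measured ΔΔG."""
    with open(path, "w") as fh:
        fh.write("complex\tmutation\tpredicted_ddg\tmeasured_ddg\n")
        for rec, p in zip(records, predictions):
            fh.write(f"{rec.complex_id}\t{rec.mutation_id}\t{p:.4f}\t"
                     f"{rec.ddg:.4f}\n")
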