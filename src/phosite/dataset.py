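"""Labeled, windowed, ratio-balanced training instances.

Candidate sites are every S/T/Y residue of a profiled protein.  A
non-annotated candidate is *negative* only when it lies more than
``distance_threshold`` (default 50) positions away from every annotated
phosphosite of the protein, of any residue type; nearer non-annotated
candidates are *excluded* from both classes.  The heavy negative excess
is reduced by keeping every r-th negative, with r chosen from the target
negatives-per-positive factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from phosite.errors import ConfigError, DataError
from phosite.profile_io import PHOSPHO_RESIDUES, PssmProfile, SiteAnnotation

DISTANCE_THRESHOLD = 50
RATIO_FACTORS = (2.0, 1.5, 1.0, 0.5)
WINDOW_SIZES = (7, 9, 11, 13, 15)


@dataclass(frozen=True)
class Instance:
    """One training/testing example: flattened window scores + target label."""

    features: np.ndarray
    target: int
    protein_id: str
    position: int
    residue: str

    def __post_init__(self):
        if self.target not in (+1, -1):
            raise DataError(f"target must be +1 or -1, got {self.target}")
        object.__setattr__(
            self, "features", np.asarray(self.features, dtype=np.float64)
        )


@dataclass(frozen=True)
class BalancePlan:
    """Stride-subsampling plan reducing n negatives toward factor * p."""

    p: int
    n: int
    factor: float

    def __post_init__(self):
        if self.factor <= 0:
            raise ConfigError(f"ratio factor must be positive, got {self.factor}")
        if self.p < 1:
            raise DataError("balance plan requires at least one positive instance")
        if self.n < 0:
            raise DataError("negative count cannot be negative")

    @property
    def r(self) -> int:
        """Stride: max(1, floor(n / (factor * p)))."""
        return max(1, math.floor(self.n / (self.factor * self.p)))

    @property
    def kept(self) -> int:
        """Number of negatives surviving stride selection: ceil(n / r)."""
        return math.ceil(self.n / self.r) if self.n else 0


def _validate_window(w: int) -> int:
    if w < 1 or w % 2 == 0:
        raise ConfigError(f"window size must be a positive odd integer, got {w}")
    return (w - 1) // 2


def label_sites(
    profile: PssmProfile,
    positives: Iterable[int],
    distance_threshold: int = DISTANCE_THRESHOLD,
) -> list[SiteAnnotation]:
    """Assign positive/negative/excluded to every S/T/Y site of one protein.

    ``positives`` are 1-based annotated positions.  Each must fall on an
    S/T/Y residue.  Every other S/T/Y site within ``distance_threshold``
    of any annotated position (any residue type) is excluded; the rest
    are negatives.  Non-S/T/Y positions are never labeled.
    """
    positive_set = set()
    for pos in positives:
        residue = profile.residue(pos)
        if residue not in PHOSPHO_RESIDUES:
            raise DataError(
                f"{profile.protein_id}: annotated position {pos} is {residue}, not S/T/Y"
            )
        positive_set.add(pos)

    annotated = sorted(positive_set)
    labels: list[SiteAnnotation] = []
    for pos in profile.sty_positions():
        if pos in positive_set:
            label = "positive"
        elif any(abs(pos - a) <= distance_threshold for a in annotated):
            label = "excluded"
        else:
            label = "negative"
        labels.append(SiteAnnotation(profile.protein_id, pos, profile.residue(pos), label))
    return labels


def extract_window(profile: PssmProfile, position: int, w: int) -> np.ndarray:
    """Flatten the w score rows centered on a 1-based position into 20*w values.

    Rows falling outside the sequence contribute 20 zeros each, so the
    output length is always exactly ``20 * w``.
    """
    half = _validate_window(w)
    if not 1 <= position <= profile.length:
        raise DataError(
            f"{profile.protein_id}: position {position} outside [1, {profile.length}]"
        )
    out = np.zeros((w, 20), dtype=np.float64)
    lo = max(1, position - half)
    hi = min(profile.length, position + half)
    out[lo - (position - half) : hi - (position - half) + 1] = profile.scores[lo - 1 : hi]
    return out.reshape(-1)


def build_instances(
    profiles: Mapping[str, PssmProfile],
    annotations: Sequence[SiteAnnotation],
    residue: str,
    w: int,
    distance_threshold: int = DISTANCE_THRESHOLD,
) -> tuple[list[Instance], list[Instance]]:
    """Build (positives, negatives) instance lists for one residue type.

    ``annotations`` are the positive sites (label ``positive``) across all
    proteins; labeling, windowing and filtering to ``residue`` happen here.
    Only proteins carrying at least one positive annotation contribute
    instances.  Order is deterministic: proteins in sorted-id order, then
    ascending position.
    """
    if residue not in PHOSPHO_RESIDUES:
        raise ConfigError(f"residue must be one of S, T, Y; got {residue!r}")
    _validate_window(w)
    by_protein: dict[str, list[int]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann.position)
    missing = sorted(pid for pid in by_protein if pid not in profiles)
    if missing:
        raise DataError(f"no PSSM profile for annotated protein(s): {', '.join(missing)}")

    positives: list[Instance] = []
    negatives: list[Instance] = []
    for pid in sorted(by_protein):
        profile = profiles[pid]
        for site in label_sites(profile, by_protein[pid], distance_threshold):
            if site.residue != residue or site.label == "excluded":
                continue
            instance = Instance(
                features=extract_window(profile, site.position, w),
                target=+1 if site.label == "positive" else -1,
                protein_id=pid,
                position=site.position,
                residue=site.residue,
            )
            (positives if site.label == "positive" else negatives).append(instance)
    return positives, negatives


def balance(negatives: Sequence[Instance], plan: BalancePlan) -> list[Instance]:
    """Keep negatives at indices 0, r, 2r, ... — positives are never touched."""
    if plan.n != len(negatives):
        raise DataError(
            f"plan was computed for n={plan.n} but {len(negatives)} negatives given"
        )
    return list(negatives[:: plan.r])


def split_folds(
    instances: Sequence[Instance],
    folds: int = 3,
    seed: int = 0,
) -> list[tuple[list[Instance], list[Instance]]]:
    """Class-stratified k-fold partition; returns (train, test) per fold.

    Each class is shuffled with the seed and dealt round-robin, so fold
    sizes per class differ by at most one and every instance appears in
    exactly one test fold.
    """
    if folds < 2:
        raise ConfigError(f"need at least 2 folds, got {folds}")
    rng = np.random.default_rng(seed)
    assignment: dict[int, int] = {}
    for cls in (+1, -1):
        idx = [i for i, inst in enumerate(instances) if inst.target == cls]
        if len(idx) < folds:
            raise DataError(
                f"only {len(idx)} instance(s) of class {cls:+d} for {folds} folds"
            )
        order = rng.permutation(len(idx))
        for rank, j in enumerate(order):
            assignment[idx[j]] = rank % folds
    splits = []
    for fold in range(folds):
        train = [inst for i, inst in enumerate(instances) if assignment[i] != fold]
        test = [inst for i, inst in enumerate(instances) if assignment[i] == fold]
        splits.append((train, test))
    return splits


def write_libsvm(instances: Sequence[Instance], path: str | Path) -> None:
    """Serialize instances in the sparse libsvm "label index:value" format.

    A sidecar ``<path>.prov.tsv`` records (protein_id, position, residue)
    per line, same order.
    """
    path = Path(path)
    with open(path, "w") as handle:
        for inst in instances:
            pairs = " ".join(
                f"{j + 1}:{v:g}" for j, v in enumerate(inst.features) if v != 0
            )
            handle.write(f"{inst.target:+d} {pairs}".rstrip() + "\n")
    with open(path.with_suffix(path.suffix + ".prov.tsv"), "w") as handle:
        handle.write("protein_id\tposition\tresidue\n")
        for inst in instances:
            handle.write(f"{inst.protein_id}\t{inst.position}\t{inst.residue}\n")


def read_libsvm(path: str | Path, k: int) -> list[Instance]:
    """Read instances written by :func:`write_libsvm` (dense vectors of length k)."""
    path = Path(path)
    provenance: list[tuple[str, int, str]] = []
    prov_path = path.with_suffix(path.suffix + ".prov.tsv")
    if prov_path.exists():
        with open(prov_path) as handle:
            next(handle)
            for line in handle:
                pid, pos, res = line.rstrip("\n").split("\t")
                provenance.append((pid, int(pos), res))
    instances: list[Instance] = []
    with open(path) as handle:
        for i, line in enumerate(handle):
            tokens = line.split()
            if not tokens:
                continue
            target = int(tokens[0])
            features = np.zeros(k, dtype=np.float64)
            for pair in tokens[1:]:
                idx, value = pair.split(":")
                j = int(idx) - 1
                if not 0 <= j < k:
                    raise DataError(f"{path}: feature index {idx} outside 1..{k}")
                features[j] = float(value)
            pid, pos, res = provenance[i] if i < len(provenance) else (f"inst{i}", 1, "S")
            instances.append(Instance(features, target, pid, pos, res))
    return instances
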