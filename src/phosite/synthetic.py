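"""Self-contained phosphoproteome fixtures with a planted window signal.

The simulator emits exactly the formats the readers consume — multi-record
FASTA, per-protein blastpgp-style ASCII PSSMs, and a positive-site TSV —
plus a gold-label TSV holding the true positive/negative/excluded status
of every S/T/Y site, so labeling can be checked against ground truth.

Construction guarantees the gold labels: S, T and Y letters appear in a
sequence only where a site was deliberately placed.  Planted positives
sit in the left part of each protein; planted negatives live beyond the
exclusion distance of every positive; planted decoys sit inside the
exclusion zone.  Background PSSM scores are i.i.d. bounded integers;
rows inside the signal span of a positive site get a constant shift, so
window size is a meaningful experimental variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from phosite.dataset import label_sites
from phosite.errors import ConfigError, DataError
from phosite.profile_io import (
    PssmProfile,
    SiteAnnotation,
    parse_pssm,
    read_annotations,
    read_sequences,
    write_pssm,
)

# Background alphabet deliberately excludes S, T and Y.
_BACKGROUND_AA = "ACDEFGHIKLMNPQRVW"

_MIN_POSITIVE_OFFSET = 55   # first positive sits at >= this position
_POSITIVE_SPACING = 110     # consecutive positives at least this far apart


@dataclass(frozen=True)
class SimConfig:
    n_proteins: int = 50
    length_range: tuple[int, int] = (400, 600)
    positives_range: tuple[int, int] = (1, 1)
    residue_weights: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.6, "T": 0.25, "Y": 0.15}
    )
    effect_size: float = 0.0
    signal_width: int = 7
    background_range: tuple[int, int] = (-2, 2)
    imbalance: float = 5.6
    decoys_per_positive: float = 1.0
    distance_threshold: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ConfigError(f"effect size must be >= 0, got {self.effect_size}")
        if self.signal_width < 1 or self.signal_width % 2 == 0:
            raise ConfigError(
                f"signal width must be a positive odd integer, got {self.signal_width}"
            )
        if self.n_proteins < 1:
            raise ConfigError("need at least one protein")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ConfigError(f"bad length range {self.length_range}")
        if self.positives_range[0] < 1 or self.positives_range[0] > self.positives_range[1]:
            raise ConfigError(f"bad positives range {self.positives_range}")
        if self.imbalance < 0:
            raise ConfigError("imbalance target must be >= 0")
        if not self.residue_weights or any(w < 0 for w in self.residue_weights.values()):
            raise ConfigError("residue weights must be non-negative and non-empty")
        if set(self.residue_weights) - set("STY"):
            raise ConfigError("residue weights may only name S, T and Y")


@dataclass
class SimResult:
    profiles: dict[str, PssmProfile]
    positives: list[SiteAnnotation]
    gold: list[SiteAnnotation]

    def gold_by_site(self) -> dict[tuple[str, int], str]:
        return {(g.protein_id, g.position): g.label for g in self.gold}


def _draw_residues(rng: np.random.Generator, weights: Mapping[str, float], n: int) -> list[str]:
    letters = sorted(weights)
    probs = np.array([weights[aa] for aa in letters], dtype=float)
    probs = probs / probs.sum()
    return [letters[i] for i in rng.choice(len(letters), size=n, p=probs)]


def _simulate_protein(
    pid: str, config: SimConfig, rng: np.random.Generator
) -> tuple[PssmProfile, list[SiteAnnotation], list[SiteAnnotation]]:
    length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    n_pos = int(rng.integers(config.positives_range[0], config.positives_range[1] + 1))
    n_neg = int(rng.poisson(config.imbalance * n_pos))
    d = config.distance_threshold

    pos_positions = [
        _MIN_POSITIVE_OFFSET + _POSITIVE_SPACING * i + int(rng.integers(0, 10))
        for i in range(n_pos)
    ]
    neg_zone_start = pos_positions[-1] + d + 1
    free_slots = max(0, length - neg_zone_start + 1)
    if pos_positions[-1] > length or free_slots < n_neg:
        raise DataError(
            f"{pid}: protein of length {length} cannot host {n_pos} positive(s) "
            f"and {n_neg} negative(s) under the distance-{d} rule"
        )
    neg_positions = sorted(
        int(p) for p in rng.choice(free_slots, size=n_neg, replace=False) + neg_zone_start
    )

    taken = set(pos_positions) | set(neg_positions)
    decoy_positions: list[int] = []
    for p in pos_positions:
        for _ in range(int(rng.poisson(config.decoys_per_positive))):
            offset = int(rng.integers(3, min(d, 48) + 1)) * int(rng.choice([-1, 1]))
            candidate = p + offset
            if 1 <= candidate <= length and candidate not in taken:
                # must stay inside SOME exclusion zone; by |offset| <= d it does
                decoy_positions.append(candidate)
                taken.add(candidate)

    sequence = list(
        rng.choice(list(_BACKGROUND_AA), size=length)
    )
    site_residues = _draw_residues(
        rng, config.residue_weights, n_pos + n_neg + len(decoy_positions)
    )
    gold: list[SiteAnnotation] = []
    positives: list[SiteAnnotation] = []
    for (positions, label) in (
        (pos_positions, "positive"),
        (neg_positions, "negative"),
        (decoy_positions, "excluded"),
    ):
        for position in positions:
            residue = site_residues.pop()
            sequence[position - 1] = residue
            gold.append(SiteAnnotation(pid, position, residue, label))
            if label == "positive":
                positives.append(SiteAnnotation(pid, position, residue, "positive"))
    gold.sort(key=lambda g: g.position)

    scores = rng.integers(
        config.background_range[0], config.background_range[1] + 1, size=(length, 20)
    ).astype(np.int64)
    shift = int(np.rint(config.effect_size))
    half = (config.signal_width - 1) // 2
    for p in pos_positions:
        lo, hi = max(1, p - half), min(length, p + half)
        scores[lo - 1 : hi] += shift
    profile = PssmProfile(pid, "".join(sequence), scores)
    return profile, positives, gold


def simulate(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate a synthetic phosphoproteome; optionally write it to disk.

    When ``out_dir`` is given, writes ``proteins.fasta``, one
    ``<protein_id>.pssm`` per protein, ``annotations.tsv`` (positive sites
    only) and ``gold.tsv`` (true label of every S/T/Y site).  Identical
    configs produce byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_proteins))
    profiles: dict[str, PssmProfile] = {}
    positives: list[SiteAnnotation] = []
    gold: list[SiteAnnotation] = []
    for i in range(config.n_proteins):
        pid = f"SYN{i + 1:0{width}d}"
        profile, pos, gld = _simulate_protein(pid, config, rng)
        profiles[pid] = profile
        positives.extend(pos)
        gold.extend(gld)
    result = SimResult(profiles=profiles, positives=positives, gold=gold)
    if out_dir is not None:
        _write_result(result, Path(out_dir))
    return result


def _write_result(result: SimResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "proteins.fasta", "w") as handle:
        for pid, profile in result.profiles.items():
            handle.write(f">{pid}\n")
            seq = profile.sequence
            for start in range(0, len(seq), 60):
                handle.write(seq[start : start + 60] + "\n")
    for pid, profile in result.profiles.items():
        write_pssm(profile, out_dir / f"{pid}.pssm")
    with open(out_dir / "annotations.tsv", "w") as handle:
        handle.write("protein_id\tposition\tresidue\n")
        for ann in result.positives:
            handle.write(f"{ann.protein_id}\t{ann.position}\t{ann.residue}\n")
    with open(out_dir / "gold.tsv", "w") as handle:
        handle.write("protein_id\tposition\tresidue\tlabel\n")
        for g in result.gold:
            handle.write(f"{g.protein_id}\t{g.position}\t{g.residue}\t{g.label}\n")


def read_gold(path: str | Path) -> list[SiteAnnotation]:
    gold: list[SiteAnnotation] = []
    with open(path) as handle:
        next(handle)
        for line in handle:
            pid, pos, res, label = line.rstrip("\n").split("\t")
            gold.append(SiteAnnotation(pid, int(pos), res, label))
    return gold


@dataclass
class AgreementReport:
    n_sites: int
    disagreements: list[tuple[str, int, str, str]]  # (protein, pos, gold, computed)

    @property
    def n_disagree(self) -> int:
        return len(self.disagreements)

    @property
    def ok(self) -> bool:
        return self.n_disagree == 0

    @property
    def agreement(self) -> float:
        return 1.0 - self.n_disagree / self.n_sites if self.n_sites else 1.0


def gold_check(
    fixture_dir: str | Path, distance_threshold: int = 50
) -> AgreementReport:
    """Re-label a simulated fixture from its files and compare to gold.tsv."""
    fixture_dir = Path(fixture_dir)
    sequences = read_sequences(fixture_dir / "proteins.fasta")
    annotations = read_annotations(fixture_dir / "annotations.tsv", sequences=sequences)
    gold = read_gold(fixture_dir / "gold.tsv")
    gold_map = {(g.protein_id, g.position): g.label for g in gold}

    by_protein: dict[str, list[int]] = {}
    for ann in annotations:
        by_protein.setdefault(ann.protein_id, []).append(ann.position)

    computed: dict[tuple[str, int], str] = {}
    n_sites = 0
    for pid in sorted(sequences):
        profile = parse_pssm(fixture_dir / f"{pid}.pssm", protein_id=pid)
        if profile.sequence != sequences[pid]:
            raise DataError(f"{pid}: FASTA and PSSM sequences disagree")
        for site in label_sites(profile, by_protein.get(pid, []), distance_threshold):
            computed[(pid, site.position)] = site.label
            n_sites += 1

    disagreements = []
    all_sites = sorted(set(gold_map) | set(computed))
    for key in all_sites:
        g = gold_map.get(key, "<missing>")
        c = computed.get(key, "<missing>")
        if g != c:
            disagreements.append((key[0], key[1], g, c))
    return AgreementReport(n_sites=max(n_sites, len(all_sites)), disagreements=disagreements)
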