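"""Readers and writers for sequences, PSSM profiles and site annotations.

The PSSM dialect supported here is the ASCII matrix that PSI-BLAST's
``blastpgp -Q`` option writes: a header line naming the 20 amino-acid
columns (twice: once for the log-odds block, once for the weighted
percentage block), followed by one numbered row per sequence position.
Only the first 20 (log-odds) columns are ever used; the percentage block
and the trailing statistics lines are ignored.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np

from phosite.errors import DataError, ParseError

logger = logging.getLogger(__name__)

#: Canonical amino-acid column order used when a PSSM file has no header.
CANONICAL_AA_ORDER = tuple("ARNDCQEGHILKMFPSTWYV")

#: Residue types that can carry a phosphate group.
PHOSPHO_RESIDUES = frozenset("STY")

_VALID_LABELS = frozenset({"positive", "negative", "excluded"})


@dataclass(frozen=True)
class PssmProfile:
    """A protein sequence with its L x 20 position-specific score matrix.

    Row ``i`` (0-based) of ``scores`` holds the 20 log-odds scores for
    sequence position ``i + 1``; all public position arguments in this
    package are 1-based.
    """

    protein_id: str
    sequence: str
    scores: np.ndarray
    aa_order: tuple[str, ...] = CANONICAL_AA_ORDER

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=np.int64)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise DataError(
                f"{self.protein_id}: score matrix must be L x 20, got shape {scores.shape}"
            )
        if scores.shape[0] != len(self.sequence):
            raise DataError(
                f"{self.protein_id}: {scores.shape[0]} score rows for a "
                f"sequence of length {len(self.sequence)}"
            )
        seq = self.sequence
        if len(seq) > 0 and (seq != seq.upper() or not seq.isalpha()):
            raise DataError(f"{self.protein_id}: sequence must be uppercase letters")
        if len(self.aa_order) != 20:
            raise DataError(f"{self.protein_id}: amino-acid order must list 20 letters")
        object.__setattr__(self, "scores", scores)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= self.length:
            raise DataError(
                f"{self.protein_id}: position {position} outside [1, {self.length}]"
            )
        return self.sequence[position - 1]

    def sty_positions(self) -> list[int]:
        """All 1-based positions holding an S, T or Y residue."""
        return [i + 1 for i, aa in enumerate(self.sequence) if aa in PHOSPHO_RESIDUES]


@dataclass(frozen=True)
class SiteAnnotation:
    """Label for one candidate site: (protein, 1-based position, residue)."""

    protein_id: str
    position: int
    residue: str
    label: str = "positive"

    def __post_init__(self):
        if self.position < 1:
            raise DataError(
                f"{self.protein_id}: position {self.position} violates the 1-based convention"
            )
        if self.label not in _VALID_LABELS:
            raise DataError(f"invalid label {self.label!r}")


def _is_aa_header(tokens: list[str]) -> bool:
    return len(tokens) in (20, 40) and all(len(t) == 1 and t.isalpha() for t in tokens)


def parse_pssm(source: str | Path | TextIO, protein_id: str | None = None) -> PssmProfile:
    """Parse a blastpgp ``-Q`` ASCII PSSM file into a :class:`PssmProfile`.

    ``source`` may be a path or an open text stream.  The sequence is
    reconstructed from the residue-letter column; only the log-odds block
    (first 20 numeric columns) is read.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if protein_id is None:
            protein_id = path.stem
        with open(path) as handle:
            return _parse_pssm_stream(handle, protein_id)
    return _parse_pssm_stream(source, protein_id or "<stream>")


def _parse_pssm_stream(handle: TextIO, protein_id: str) -> PssmProfile:
    aa_order: tuple[str, ...] | None = None
    sequence: list[str] = []
    rows: list[list[int]] = []
    expected_index = 1
    for lineno, raw in enumerate(handle, start=1):
        tokens = raw.split()
        if not tokens:
            continue
        if aa_order is None and not rows and _is_aa_header(tokens):
            aa_order = tuple(tokens[:20])
            continue
        # Data rows start with the 1-based position index then the residue.
        if not tokens[0].lstrip("-").isdigit():
            if rows:
                break  # trailing statistics block
            continue  # leading commentary
        if len(tokens) < 2 or not (len(tokens[1]) == 1 and tokens[1].isalpha()):
            if rows:
                break
            continue
        index = int(tokens[0])
        if index != expected_index:
            raise ParseError(
                f"row index {index} out of order (expected {expected_index})", line=lineno
            )
        values: list[int] = []
        for tok in tokens[2:22]:
            try:
                values.append(int(tok))
            except ValueError:
                break
        if len(values) != 20:
            raise ParseError(
                f"expected 20 integer log-odds columns, found {len(values)}", line=lineno
            )
        sequence.append(tokens[1].upper())
        rows.append(values)
        expected_index += 1
    if not rows:
        raise ParseError(f"{protein_id}: no PSSM rows found (empty or unrecognized file)")
    return PssmProfile(
        protein_id=protein_id,
        sequence="".join(sequence),
        scores=np.array(rows, dtype=np.int64),
        aa_order=aa_order or CANONICAL_AA_ORDER,
    )


def write_pssm(profile: PssmProfile, target: str | Path | TextIO) -> None:
    """Write a profile in the blastpgp ASCII layout (percentages as zeros)."""
    if profile.length == 0:
        raise DataError(f"{profile.protein_id}: refusing to write an empty profile")
    if isinstance(target, (str, Path)):
        with open(target, "w") as handle:
            _write_pssm_stream(profile, handle)
    else:
        _write_pssm_stream(profile, target)


def _write_pssm_stream(profile: PssmProfile, handle: TextIO) -> None:
    handle.write("\n")
    handle.write(
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    letters = "  ".join(profile.aa_order)
    handle.write(f"            {letters}   {letters}\n")
    for i, (aa, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        scores = " ".join(f"{int(v):3d}" for v in row)
        percents = " ".join("  0" for _ in range(20))
        handle.write(f"{i:5d} {aa}  {scores}  {percents}  0.00 0.00\n")
    handle.write("\n")
    handle.write("                      K         Lambda\n")
    handle.write("Standard Ungapped    0.1337     0.3190\n")


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA (multi-record) or raw text.

    A file whose first non-blank character is ``>`` is treated as FASTA;
    anything else is read as a single raw sequence named after the file.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped.startswith(">"):
        from Bio import SeqIO

        records = {}
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            records[rec.id] = str(rec.seq).upper()
        if not records:
            raise ParseError(f"{path}: no FASTA records found")
        return records
    sequence = "".join(stripped.split())
    if not sequence:
        raise ParseError(f"{path}: empty sequence file")
    return {path.stem: sequence.upper()}


def read_annotations(
    path: str | Path,
    sequences: Mapping[str, str] | None = None,
    keep_all_residues: bool = False,
) -> list[SiteAnnotation]:
    """Read a positive-site annotation table (TSV: protein_id, position, residue).

    Rows whose residue is not S, T or Y (e.g. a histidine phosphosite) are
    dropped with a logged count, unless ``keep_all_residues`` is set (used
    for dataset bookkeeping before residue filtering).  When ``sequences``
    is given, each kept row is validated against the protein: the position
    must lie inside the sequence and the residue letter must match.
    """
    path = Path(path)
    annotations: list[SiteAnnotation] = []
    dropped = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError("expected 3 columns: protein_id, position, residue", line=lineno)
            protein_id, pos_text, residue = fields[0], fields[1], fields[2].upper()
            if lineno == 1 and not pos_text.lstrip("-").isdigit():
                continue  # header row
            if not pos_text.lstrip("-").isdigit():
                raise ParseError(f"position {pos_text!r} is not an integer", line=lineno)
            position = int(pos_text)
            if position < 1:
                raise DataError(
                    f"row {lineno}: position {position} violates the 1-based convention"
                )
            if residue not in PHOSPHO_RESIDUES and not keep_all_residues:
                dropped += 1
                continue
            if sequences is not None:
                seq = sequences.get(protein_id)
                if seq is not None:
                    if position > len(seq):
                        raise DataError(
                            f"row {lineno}: position {position} outside protein "
                            f"{protein_id} of length {len(seq)}"
                        )
                    if seq[position - 1] != residue:
                        raise DataError(
                            f"row {lineno}: residue {residue} does not match "
                            f"{protein_id}[{position}] = {seq[position - 1]}"
                        )
            annotations.append(SiteAnnotation(protein_id, position, residue, "positive"))
    if dropped:
        logger.info("dropped %d annotation(s) on non-S/T/Y residues", dropped)
    return annotations


def write_annotations(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    """Write annotations as a TSV (protein_id, position, residue[, label])."""
    with open(path, "w") as handle:
        handle.write("protein_id\tposition\tresidue\n")
        for ann in annotations:
            handle.write(f"{ann.protein_id}\t{ann.position}\t{ann.residue}\n")


def blastpgp_command(
    seq_path: str,
    pssm_path: str,
    database: str = "nr",
    iterations: int = 3,
    evalue: float = 0.001,
) -> str:
    """Return (never run) the external PSI-BLAST command that builds a profile.

    Running PSI-BLAST against nr is an optional external step; this helper
    only documents the exact invocation whose ``-Q`` output this package
    parses.
    """
    return (
        f'blastpgp -d {database} -i "{seq_path}" -j {iterations} '
        f'-h {evalue} -Q "{pssm_path}"'
    )
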