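"""Dataset-lineage bookkeeping over annotation tables.

Given the full training annotation table (dataset A) and the independent
benchmark table (dataset B), this module recomputes the counts that
describe the dataset lineage A -> A' -> A'':

* A' drops every protein carrying a non-S/T/Y (e.g. histidine) phosphosite
  annotation;
* A'' additionally drops every protein whose identifier also appears in B.
"""

from __future__ import annotations

from pathlib import Path

from phosite.profile_io import read_annotations


def dataset_bookkeeping(file_a: str | Path, file_b: str | Path) -> dict[str, int]:
    """Recompute entry/annotation counts of the A/A'/A''/B dataset lineage.

    Returns a dict with keys:

    - ``a_proteins``: distinct protein identifiers in A
    - ``a_serine`` / ``a_threonine`` / ``a_tyrosine``: annotation counts in A
      by residue, before any residue filtering
    - ``a_prime_proteins``: proteins of A' (A minus non-S/T/Y-annotated proteins)
    - ``overlap_proteins``: proteins shared between A' and B
    - ``a_doubleprime_proteins``: proteins of A'' (A' minus the overlap)
    - ``b_proteins`` and ``b_serine`` / ``b_threonine`` / ``b_tyrosine``
    """
    a = read_annotations(file_a, keep_all_residues=True)
    b = read_annotations(file_b, keep_all_residues=True)

    a_proteins = {ann.protein_id for ann in a}
    b_proteins = {ann.protein_id for ann in b}
    non_sty_proteins = {ann.protein_id for ann in a if ann.residue not in "STY"}
    a_prime = a_proteins - non_sty_proteins
    overlap = a_prime & b_proteins
    a_doubleprime = a_prime - overlap

    def by_residue(annotations, residue):
        return sum(1 for ann in annotations if ann.residue == residue)

    return {
        "a_proteins": len(a_proteins),
        "a_serine": by_residue(a, "S"),
        "a_threonine": by_residue(a, "T"),
        "a_tyrosine": by_residue(a, "Y"),
        "a_prime_proteins": len(a_prime),
        "overlap_proteins": len(overlap),
        "a_doubleprime_proteins": len(a_doubleprime),
        "b_proteins": len(b_proteins),
        "b_serine": by_residue(b, "S"),
        "b_threonine": by_residue(b, "T"),
        "b_tyrosine": by_residue(b, "Y"),
    }
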