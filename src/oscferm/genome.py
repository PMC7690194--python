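"""Assembly summary statistics (scaffold count, total length, N50, GC%).

N50 follows the standard convention: sort scaffold lengths descending and
take the length at which the cumulative sum first reaches half the total.
GC% is computed over unambiguous bases (A/C/G/T) by default, since
ambiguity codes inflate the denominator; an all-bases variant is
available because reporting conventions differ between assemblers.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = ["AssemblySummary", "assembly_stats", "n50"]


@dataclass(frozen=True)
class AssemblySummary:
    n_scaffolds: int
    total_length: int
    n50: int
    gc_percent: float  # rounded to 2 decimals
    ambiguous_bases: int = 0


def n50(lengths) -> int:
    """Length of the scaffold at which the descending cumulative sum
    first reaches half the assembly total."""
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths or lengths[0] <= 0:
        raise ValueError("need at least one positive length")
    total = sum(lengths)
    cum = 0
    for ln in lengths:
        cum += ln
        if cum >= total / 2:
            return ln
    raise AssertionError("unreachable")


def assembly_stats(
    fasta: str | Path, gc_all_bases: bool = False
) -> AssemblySummary:
    """Summarize a (plain or gzipped) FASTA assembly.

    Non-ACGT residues count toward ``total_length`` but are excluded from
    the GC denominator unless ``gc_all_bases`` is set.  Case- and
    order-insensitive.
    """
    path = Path(fasta)
    opener = gzip.open if path.suffix == ".gz" else open
    lengths: list[int] = []
    at = gc = ambig = 0
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            lengths.append(len(seq))
            gc += seq.count("G") + seq.count("C")
            at += seq.count("A") + seq.count("T")
            ambig += len(seq) - (
                seq.count("G") + seq.count("C") + seq.count("A") + seq.count("T")
            )
    if not lengths:
        raise ValueError(f"{path}: no sequences found")
    total = sum(lengths)
    denom = total if gc_all_bases else (at + gc)
    if denom == 0:
        raise ValueError(f"{path}: no unambiguous bases for GC computation")
    return AssemblySummary(
        n_scaffolds=len(lengths),
        total_length=total,
        n50=n50(lengths),
        gc_percent=round(100.0 * gc / denom, 2),
        ambiguous_bases=ambig,
    )
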