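#!/usr/bin/env python
"""Assembly summary statistics.

Computes scaffold count, total length, N50 and GC% for a FASTA assembly.
Pass the assembly path as the first argument (e.g. a local copy of a
deposited genome); without an argument the script demonstrates the
statistics on a synthetic multi-scaffold assembly it generates itself.
Writes results/genome_stats.json.
"""

import json
import sys
import tempfile
from pathlib import Path

import numpy as np

from oscferm.genome import assembly_stats

ROOT = Path(__file__).resolve().parents[1] / "results"


def synthetic_assembly(path: Path, n_scaffolds: int = 30, seed: int = 19) -> None:
    """Low-GC synthetic scaffolds (labelled synthetic; not a real genome)."""
    rng = np.random.default_rng(seed)
    with path.open("w") as fh:
        for i in range(n_scaffolds):
            n = int(rng.integers(2_000, 80_000))
            seq = "".join(
                rng.choice(list("ACGT"), size=n, p=[0.357, 0.143, 0.143, 0.357])
            )
            fh.write(f">synthetic_scaffold_{i}\n")
            for j in range(0, n, 80):
                fh.write(seq[j : j + 80] + "\n")


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    if len(sys.argv) > 1:
        fasta = Path(sys.argv[1])
        label = str(fasta)
    else:
        tmp = Path(tempfile.mkdtemp())
        fasta = tmp / "synthetic_assembly.fasta"
        synthetic_assembly(fasta)
        label = "synthetic demo assembly"
    s = assembly_stats(fasta)
    print(f"{label}: {s.n_scaffolds} scaffolds, {s.total_length} bp, "
          f"N50 {s.n50} bp, GC {s.gc_percent}% "
          f"({s.ambiguous_bases} ambiguous bases excluded from GC)")
    payload = {
        "input": label,
        "n_scaffolds": s.n_scaffolds,
        "total_length": s.total_length,
        "n50": s.n50,
        "gc_percent": s.gc_percent,
    }
    (ROOT / "genome_stats.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True)
    )
    print(f"wrote {ROOT / 'genome_stats.json'}")


if __name__ == "__main__":
    sys.exit(main())
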