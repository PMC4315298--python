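#!/usr/bin/env python
"""Classify the simulated read pairs and audit the filter against truth.

Reads the pairs written by 01_simulate_inputs.py (regenerating them if
absent), applies the four-way filter (apparent-insert, self-ligation,
too-close, interchromosomal insert), and writes the class census and the
confusion against the planted labels to results/.
"""

import subprocess
import sys
from collections import Counter
from pathlib import Path

from hiclocal import classify_pair, filter_pairs
from hiclocal import io as hio
from hiclocal.genome import cut_positions

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "inputs"
RESULTS = ROOT / "results"

TRUTH_TO_FILTER = {
    "valid_intra": "valid_intra", "valid_inter": "valid_inter",
    "self_ligation": "self_ligation", "undigested_loop": "too_close",
    "short_insert": "short_insert",
}


def main() -> None:
    if not (SCRATCH / "pairs.tsv").exists():
        subprocess.run(
            [sys.executable, str(ROOT / "analysis" / "01_simulate_inputs.py")],
            check=True,
        )
    genome = hio.read_fasta(SCRATCH / "genome.fa")
    pairs = hio.read_pairs(SCRATCH / "pairs.tsv")
    labels = (SCRATCH / "pair_labels.txt").read_text().split()
    cuts = {c: cut_positions(genome.sequences[c], "GATC")
            for c in genome.chrom_names}
    lens = genome.lengths()

    valid, census = filter_pairs(pairs, cuts, lens)
    confusion = Counter(
        (lab, classify_pair(p, cuts, lens)) for p, lab in zip(pairs, labels)
    )
    correct = sum(
        n for (lab, got), n in confusion.items()
        if TRUTH_TO_FILTER[lab] == got
    )

    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "pair_filter_census.tsv", "w") as fh:
        fh.write("class\tcount\n")
        for cls, n in sorted(census.items()):
            fh.write(f"{cls}\t{n}\n")
    with open(RESULTS / "pair_filter_confusion.tsv", "w") as fh:
        fh.write("planted\tcalled\tcount\n")
        for (lab, got), n in sorted(confusion.items()):
            fh.write(f"{lab}\t{got}\t{n}\n")

    print(f"{len(valid)} valid contacts kept of {len(pairs)} pairs")
    print(f"filter agrees with planted labels on "
          f"{correct / len(pairs):.2%} of pairs")
    for cls, n in sorted(census.items()):
        print(f"  {cls}: {n}")


if __name__ == "__main__":
    main()
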