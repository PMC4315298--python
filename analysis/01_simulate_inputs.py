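#!/usr/bin/env python
"""Build the synthetic study inputs and record what was planted.

Generates the two study chromosomes (2 Mb with ten planted strip bins over
an end-count coverage bias; 6 Mb tiled with alternating 60-kb
directionality blocks), the labelled read-pair population, and the
six-state epigenome.  Writes the genome and pairs to scratch/ (bulky,
regenerable) and a compact simulation summary to results/.
"""

from pathlib import Path

import numpy as np

from hiclocal import gen_genome, gen_read_pairs, run_demo
from hiclocal import io as hio
from hiclocal.genome import cut_positions, digest

SEED = 0
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "inputs"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    genome = gen_genome(2, [2_000_000, 6_000_000], gc=0.36,
                        site="GATC", site_rate=1 / 250, seed=SEED)
    hio.write_fasta(genome, SCRATCH / "genome.fa")
    frags = digest(genome, "GATC", 0)
    sizes = np.array([f.length for f in frags])
    cuts = {c: cut_positions(genome.sequences[c], "GATC")
            for c in genome.chrom_names}

    pairs, truth = gen_read_pairs(
        genome, cuts, 10_000,
        class_mix={"valid_intra": 0.5, "self_ligation": 0.2,
                   "undigested_loop": 0.2, "short_insert": 0.1},
        seed=SEED + 3,
    )
    hio.write_pairs(pairs, SCRATCH / "pairs.tsv", [f"seed={SEED + 3}"])
    with open(SCRATCH / "pair_labels.txt", "w") as fh:
        fh.writelines(lab + "\n" for lab in truth.pair_labels)

    with open(RESULTS / "simulation_summary.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"n_chromosomes\t{len(genome.chrom_names)}\n")
        fh.write(f"n_fragments\t{len(frags)}\n")
        fh.write(f"median_fragment_bp\t{np.median(sizes):.0f}\n")
        fh.write(f"n_read_pairs\t{len(pairs)}\n")
        for cls in sorted(set(truth.pair_labels)):
            fh.write(f"pairs_{cls}\t{truth.pair_labels.count(cls)}\n")

    print(f"genome: {sum(genome.lengths().values()) / 1e6:.0f} Mb, "
          f"{len(frags)} fragments (median {np.median(sizes):.0f} bp)")
    print(f"pairs: {len(pairs)} across "
          f"{len(set(truth.pair_labels))} planted classes")
    print(f"wrote {SCRATCH / 'genome.fa'} and {RESULTS / 'simulation_summary.tsv'}")


if __name__ == "__main__":
    main()
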