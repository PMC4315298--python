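#!/usr/bin/env python
"""Fit the Poisson bias regression and summarize the residual maps.

The strips chromosome carries a planted end-count coverage bias, so its
fitted end-count slope should be clearly positive, while the unbiased
domains chromosome should fit a near-zero slope.  Writes the per-chromosome
coefficients and residual summaries to results/.
"""

import numpy as np

from common import RESULTS, demo_bundle


def main() -> None:
    bundle = demo_bundle()
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "bias_regression_fits.tsv", "w") as fh:
        fh.write(
            "chrom\tintercept\tbeta_len\tbeta_gc\tbeta_end\t"
            "deviance\tn_pairs\tresidual_mean\n"
        )
        for chrom, fit in bundle["fits"].items():
            norm = bundle["normalized"][chrom]
            i, j = np.triu_indices(norm.n_bins, 1)
            ok = norm.mask[i] & norm.mask[j]
            rmean = norm.values[i, j][ok].mean()
            fh.write(
                f"{chrom}\t{fit.intercept:.4f}\t{fit.beta_len:.4f}\t"
                f"{fit.beta_gc:.4f}\t{fit.beta_end:.4f}\t{fit.deviance:.1f}\t"
                f"{fit.n_pairs_fit}\t{rmean:.4f}\n"
            )
            print(
                f"{chrom}: beta_end = {fit.beta_end:+.3f}, "
                f"Pearson-residual mean {rmean:+.4f} "
                f"over {fit.n_pairs_fit} pairs"
            )
    print("chr1 carries the planted end-count bias; "
          "chr2 was generated unbiased.")
    print(f"wrote {RESULTS / 'bias_regression_fits.tsv'}")


if __name__ == "__main__":
    main()
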