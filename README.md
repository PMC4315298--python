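# hiclocal

Local chromatin-packing analysis for kilobase-resolution Hi-C maps of
compact plant genomes, built around the features that dominate
*Arabidopsis thaliana* nuclear organization instead of the TADs of animal
genomes: **positive strips** (2-kb bins with locally extreme contact
rates), **insulator-like regions** (U→D directionality junctions where the
flanks interact away from each other), and **TAD-boundary-like /
TAD-interior-like regions**, together with a six-state chromatin-state
segmentation of a 16-mark epigenome.

The package is for computational biologists who have mapped Hi-C read
pairs (or want to test callers against synthetic maps with planted ground
truth) and need the full chain: pair filtering → bias-model normalization
→ strip/DI statistics → region calls → epigenomic annotation.

## The statistics at the core

**Bias model.** Binned pair counts are Poisson,

    u_ij ~ Poisson(λ_ij),
    log λ_ij = β0 + β_len·log(L_i L_j) + β_gc·log(G_i G_j)
                  + β_end·log(F_i F_j) + log(M_i M_j),

with per-bin effective fragment length L, fragment-end GC G, fragment-end
count F, and mappability M (a fixed offset). The residual matrix
(Pearson residuals by default) is the normalized map. Distance is not a
covariate, so genuine local contact-rate differences survive — which is
why strips are visible here and invisible to depth-equalizing balancing.

**Strip index.** For each bin, its contacts at offsets ±(3..25) bins are
percentile-ranked against the same-offset contacts of the 200 nearest
bins; offsets score +3/+1/0/−1/−3 at the 95/80/20/5th percentiles and the
46 scores are summed. |index| ≥ 45 calls a strip.

**Directionality.** DI(i) contrasts upstream/downstream contact sums A, B
within 60 kb: `DI = sign(B−A)·[(A−E)²/E + (B−E)²/E]`, `E = (A+B)/2`. A
3-state Gaussian HMM on the signed root of DI decodes U/D/N states, and
sliding-window grammars (`XXUUDDXX` and friends) extract insulator-like,
boundary-like, and interior-like regions.

See `docs/methods.md` for the full model description and design
rationale.

## Worked example

The whole pipeline runs on synthetic data with planted truth in about a
minute:

```python
from hiclocal import run_demo

bundle = run_demo(seed=1)
print(bundle["metrics"])
```

which prints (seed 1):

```
pair_filter_accuracy          1.0
strip_precision               1.0
strip_recall                  1.0
insulator_junction_recovery   1.0
cs_agreement                  0.9822
n_insulator_calls             50
n_boundary_calls              100
n_interior_calls              102
```

Reading: all 10,000 labelled read pairs were classified into their true
class; all ten planted strip bins were called with no false positives;
all 50 planted up→down block junctions were recovered as insulator-like
regions within one bin; and k-means recovered the six planted chromatin
states with adjusted Rand index 0.98. The 100 boundary-like and 102
interior-like calls line up with the 50 up→down plus 50 down→up block
transitions of the 6-Mb domains chromosome.

The same stages can be run as a narrative analysis, one driver per step:

```sh
cd analysis
python 01_simulate_inputs.py   # 8 Mb genome, 31,749 fragments (median 177 bp)
python 02_filter_pairs.py      # filter agrees with planted labels on 100% of pairs
python 03_normalize_maps.py    # beta_end = +1.006 on the biased chromosome, +0.004 on the unbiased one
python 04_call_strips.py       # precision 1.00, recall 1.00
python 05_call_domains.py      # 50/50 junctions recovered; U=0.17, D=0.16, N=0.67
python 06_chromatin_states.py  # adjusted agreement 0.976
python 07_profile_features.py  # focal strength 789.6 vs flank 255.8 at strips
```

Each driver writes its tables under `results/` (bulky intermediates go to
`scratch/`). The `beta_end` line is the bias regression doing its job:
chromosome 1 was simulated with per-bin bias proportional to its
fragment-end count, and the fitted end-count slope comes back at 1.006;
the unbiased chromosome fits 0.004.

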