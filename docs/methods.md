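# Methods

`hiclocal` implements a local-packing analysis of kilobase-resolution Hi-C
maps of the sort produced for *Arabidopsis thaliana* with a 4-cutter
restriction enzyme. This note records the models, the tunable parameters,
the numerical choices, and what the synthetic study conditions do and do
not establish.

## Read-pair filtering

A mapped pair is assigned exactly one class from the geometry of the two
reads relative to the restriction digest (all coordinates 0-based,
half-open; pairs are first ordered so the left read comes first):

| orientation | rule | class |
| --- | --- | --- |
| interchromosomal | `len1 + len2 + d1 + d2 < 600` bp, where `d` is each read's 3'-end distance to the first cut site in its 5'→3' direction | `valid_inter`, else `short_insert` |
| FR (paired-end mode) | apparent insert `pos2 + len2 − pos1 > 600` bp | `valid_intra`, else `short_insert` |
| RF (mate-pair mode) | no cut site strictly between the reads → `self_ligation`; else distance `< 1500` bp → `too_close`; else `valid_intra` | |
| FF / RR | kept as `valid_intra` | |

FF/RR pairs cannot arise from self-ligation of a circle or from an
undigested linear fragment, so no distance filter applies to them; they
are counted separately in the census so the choice is auditable. "Strictly
between the reads" is realised as a cut position `c` with
`pos1 + len1 ≤ c ≤ pos2 − 1`, i.e. the cut lies in neither mapped read.
Duplicates are removed before classification using exact
coordinate-and-strand equality on canonically ordered sides; no fuzzy
window is used.

Defaults: `insert_max = 600` bp (the library size-selection bound),
`min_rf_distance = 1500` bp.

## Normalization covariates

Complete in-silico digestion scans the forward strand for the recognition
motif (DpnII `^GATC`, HindIII `A^AGCTT`; both palindromic at the cut, so
forward-strand scanning finds every cut site). Per analysis bin
(2 kb default) four covariates are computed:

* **fragment-end count** `F` — number of interior cut positions in the bin;
* **GC of fragment ends** `G` — GC fraction of the union of ±`end_flank`
  (200 bp) windows around the bin's cuts;
* **effective fragment length** `L` — fraction of the bin within
  `eff_flank` (500 bp) of any cut, i.e. the part of the bin close enough
  to a ligation junction to yield reads;
* **mappability** `M` — supplied externally, 1.0 on synthetic data.

The flank widths follow the conventions of fragment-feature-based Hi-C
normalization; they are parameters, not constants.

## Poisson bias regression

Pair counts `u_ij` between unmasked bins of one chromosome are modelled as

```
u_ij ~ Poisson(λ_ij)
log λ_ij = β0 + β_len·log(L_i L_j) + β_gc·log(G_i G_j)
              + β_end·log(F_i F_j) + log(M_i M_j)
```

with the mappability product as a fixed offset. The fit is by iteratively
reweighted least squares (statsmodels GLM) per chromosome over all
off-diagonal unmasked pairs; the diagonal is excluded (dominated by
self-structure) and written as 0. Genomic distance is deliberately **not**
a covariate: the downstream statistics (strip index, DI) compare
same-offset values, which cancels the distance decay, and leaving distance
out preserves genuine differences in local contact rates — the point of
the strip analysis, and the reason depth-equalizing balancing methods
(ICE) are not offered here.

The normalized map is the residual matrix. The default residual is
Pearson, `(u − λ̂)/√λ̂`, which is variance-stabilized and hence comparable
across the decay; the raw residual `u − λ̂` is available via
`residual="raw"`.

Masking is two-level: bins with mappability `< 0.5` or effective length
`< 0.1` are excluded from the regression and all downstream analysis;
centromeric bins (configurable spans; the built-in `TAIR10` table covers
the five *A. thaliana* pericentromeres) stay in the regression but are
excluded from pattern analysis. Bins with a zero covariate (no cut in the
bin) have an undefined log-covariate and are auto-masked with a warning. A
covariate that is constant across bins is unidentifiable from the
intercept and is dropped from the design; its slope is reported as 0.

## Contact strength

`strength(i) = Σ_{o=1..5} v(i, i−o) + v(i, i+o)` on the normalized map —
the sum of a 2-kb bin's contacts within 10 kb. Masked or out-of-range
neighbors are skipped; masked focal bins are undefined.

## Strip index

For focal bin `i` and each signed offset `o ∈ ±{3..25}` (6–50 kb at 2-kb
bins), the value `v = M[i, i+o]` is ranked among the same-offset values of
the 200 nearest unmasked bins (100 per side — a 400-kb local context).
Percentiles use midranks, so ties sit at 50 and a flat background scores
exactly 0. The offset score is +3 (p ≥ 95), +1 (p ≥ 80), −3 (p ≤ 5),
−1 (p ≤ 20), else 0; the index is the sum over the 46 offsets, bounded in
[−138, +138]. Bins with index ≥ +45 form positive strips, ≤ −45 negative
strips (maximal runs; both polarities are reported, and negative strips
are flagged as sequencing-bias artifacts rather than biology).

Reference sets are per-offset and never pooled — this is what makes the
statistic decay-free. Neighbors that are masked are skipped, not
zero-filled. Near chromosome ends the context truncates; bins with fewer
than 100 reference neighbors in total are undefined rather than scored on
thin support.

## Directionality index and U/D/N decoding

For bin `i`, `A` and `B` are its summed normalized contacts with the 30
bins (60 kb) upstream and downstream; with `E = (A+B)/2`,

```
DI(i) = sign(B − A) · [ (A − E)²/E + (B − E)²/E ],   DI = 0 if A = B or E ≤ 0.
```

Positive DI means downstream-biased interactions. Bins excluded from
normalization or centromeric are excluded and split the track into
independent segments.

The three-state HMM has Gaussian emissions on the **signed square root**
of DI. The DI is a signed chi-square-style statistic with heavy tails;
its signed root equals `(B − A)/√(A + B)`, a z-score-scale quantity that
is approximately Gaussian under symmetry. Two design choices matter and
were validated against the generator's planted structure:

* free per-state variances on raw DI let EM decompose an unstructured
  track by *magnitude* (one narrow state, one wide state) instead of by
  direction, producing spurious U/D imbalance;
* tied variances on raw DI chase the extreme tails on structured tracks
  (emission means far outside the bulk), erasing the U/D runs.

Tied-variance emissions on the signed root avoid both failure modes.
Means are initialized at terciles, transitions at 0.8/0.1/0.1; EM runs to
`tol = 1e−6` (max 500 iterations), decoding is by most-likely path, and
states are named by emission-mean rank (most negative → U, most positive
→ D, middle → N). A near-constant track decodes as all N.

## Region grammars

Matched by sliding window over each contiguous segment of decoded states
("X" = any decoded state; patterns cannot span masked gaps, so the
flanking X positions must exist within the segment):

| pattern | called region | type |
| --- | --- | --- |
| `XXUUDDXX` | central `UD` | insulator-like A |
| `XXUUNDDXX` | central `UND` | insulator-like B |
| `XXUUNNDDXX` | central `UNND` | insulator-like C |
| `UUUUU(D/N)(D/N)X` | 5th U + next bin | TAD-boundary-like `U(D/N)` |
| `X(U/N)(U/N)DDDDD` | bin before + first D | TAD-boundary-like `(U/N)D` |
| `X(D/N)(D/N)UUUUU` | bin before + first U | TAD-interior-like `(D/N)U` |
| `DDDDD(U/N)(U/N)X` | last D + next bin | TAD-interior-like `D(U/N)` |

The literal windows are matched as written — a run of six U still matches
the five-U window, so "at least five" does not need to be assumed. All
matches are reported; identical spans of one type are deduplicated, and
overlaps between types are expected. Extraction is verified against an
independent regular-expression oracle on random 10,000-state tracks.

## Epigenome scoring and chromatin states

Enrichment per mark is the fraction of each 400-bp (or 2-kb) bin covered
by the mark's enriched intervals (interval unions, never > 1). Per mark,
zero-coverage bins score 0; covered bins get integer quintile scores 0–4
by midrank percentile (quintile `q` iff percentile ∈ [20q, 20(q+1))).
Pinning zeros to 0 rather than ranking them keeps the "all 16 scores 0 ⇒
unclear" rule well-defined. Scoring is invariant to strictly monotone
transforms of the coverage, so any monotone enrichment summary yields the
same states.

Non-unclear bins are clustered by k-means (Euclidean, k = 6, 50 restarts,
fixed seed; best run by within-cluster sum of squares). Centroids are
named CS1–CS6 by optimal one-to-one cosine matching (Hungarian algorithm)
against editable canonical profiles: CS1 active euchromatin, CS2
H3K27me3/H3.1/H3.3 (Polycomb), CS3 heterochromatin, CS4 no particular
enrichment (matched via a small uniform reference vector), CS5 CS1-like
with stronger H3K36me2/H2Bub/H3.3, CS6 CS3-like with weaker
H3K9me2/H3K27me1.

RPKM is `10⁹·count/(total·length)`. Expression groups: group 1 =
undetected (RPKM 0), groups 2–9 = octiles of the positive values by
midrank percentile — the original grouping boundaries are not
recoverable, so zero-plus-octiles is the documented stand-in. Profile
aggregation aligns regions on their start bin and averages any numeric or
categorical per-bin track over ±flank bins, skipping positions beyond the
chromosome.

## Synthetic study conditions

The generators plant known structure so every stage is scored against
ground truth:

* **Genome** — i.i.d. background at 36% GC with the recognition motif
  scrubbed from the background and injected at 1/250 bp, giving
  DpnII-like fragment sizes (median ≈ 170–180 bp).
* **Contact maps** — `λ_ij = base·|i−j|^−1·bias_i·bias_j` with Poisson
  counts, `base = 50` per pair at 2-kb bins. Strip bins multiply all
  their contacts within 50 kb by 3 (symmetrically). Directional blocks
  multiply a block bin's contacts on its preferred side within the 60-kb
  DI window by 2. The demonstration plants ten isolated strip bins on a
  2-Mb chromosome whose bin bias follows its own fragment-end counts, and
  tiles a 6-Mb chromosome with alternating 30-bin (60-kb) up/down blocks
  — blocks the size of the DI window, i.e. fly-sized domains, which is
  the regime a 60-kb DI is designed for — yielding 50 up→down insulator
  junctions.
* **Epigenome** — six latent states in geometric runs (mean ≈ 13 bins);
  each state enriches a disjoint group of marks at probability 0.8 over a
  0.05 spurious-peak background present for every mark, as real ChIP
  tracks have. Coverage for probability `p` is drawn
  Uniform(max(0, 2p−1), min(1, 2p)) — mean exactly `p`.
* **Read pairs** — each class realized by geometric construction (e.g.
  self-ligations place both reads inside one restriction fragment), with
  no pairs on the exact decision thresholds.

What passing these conditions does **not** show: the generator draws
independent Poisson cells (no overdispersion, no translocation-like
long-range structure), plants rectangular directionality blocks rather
than nested domains, uses bias factors that are exact functions of the
modelled covariates, and never places reads on classification boundaries.
Real-data performance therefore depends on how far those assumptions are
violated; the pipeline's thresholds are the standard constants documented
above, not values tuned to the simulation.

## Sizes and determinism

The demonstration (`run_demo`) uses a 1000-bin strips chromosome, a
3000-bin domains chromosome, 10,000 read pairs, and a 3000-bin epigenome
(`quick=True` halves everything); one full run takes about a minute on a
single CPU. All randomness flows from `numpy.random.default_rng` seeded
per stage from the single demo seed; reruns are byte-identical, and the
seeded k-means/HMM restarts are recorded in each artifact's provenance
header.

## Known limitations

* Interchromosomal counts are reported raw; the regression indexes a
  single chromosome and is not defined across chromosomes.
* Mappability is consumed, never computed (it derives from a read-mapping
  protocol outside this package's scope).
* The HMM emission family, initialization, and decoding rule are
  documented choices; other choices (posterior decoding, per-state
  mixtures) would call slightly different region sets.
* Statistically-significant-contact calling and ChIP/methylation peak
  calling are out of scope; enriched intervals are inputs.
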