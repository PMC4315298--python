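"""End-to-end orchestration and the fully synthetic demonstration run.

``run_pipeline`` chains the stages — digestion, covariates, pair
filtering, binning, bias regression, contact strength, strip calling,
directionality index, HMM decoding, region grammars — over in-memory
inputs, optionally writing every artifact (with a provenance manifest) to
a directory.  ``run_demo`` builds synthetic inputs with planted ground
truth, runs the pipeline, and scores the recovery:

* pair-filter census vs. generated labels (per-class accuracy);
* planted strip bins vs. called positive strips (precision/recall);
* planted up->down block junctions vs. insulator-like calls (rate
  recovered within one bin);
* planted latent chromatin states vs. k-means states (adjusted Rand
  index).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import io as hio
from .domains import (
    StateTrack,
    directionality_index,
    extract_boundaries,
    extract_insulators,
    extract_interiors,
    fit_hmm,
)
from .genome import GenomeSequence, bin_features, centromere_mask, cut_positions, digest
from .matrix import ContactMatrix, bin_contacts, contact_strength, exclusion_mask, normalize
from .pairs import filter_pairs
from .states import classify_states, name_states, quintile_scores
from .strips import call_strips, strip_index
from .synthetic import (
    SyntheticTruth,
    gen_contact_map,
    gen_epigenome,
    gen_genome,
    gen_read_pairs,
)

__all__ = ["PipelineConfig", "run_pipeline", "run_demo"]


@dataclass
class PipelineConfig:
    """All tunable constants of the pipeline with their standard values."""

    bin_size: int = 2000
    epigenome_bin_size: int = 400
    site: str = "GATC"
    cut_offset: int = 0
    insert_max: int = 600
    min_rf_distance: int = 1500
    map_min: float = 0.5
    efflen_min: float = 0.1
    strip_cutoff: int = 45
    di_window_bp: int = 60_000
    residual: str = "pearson"
    seed: int = 0
    centromeres: dict = field(default_factory=dict)

    def digest_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(
    genome: GenomeSequence,
    pairs,
    config: PipelineConfig,
    raw_matrices: Mapping[str, ContactMatrix] | None = None,
    features_by_chrom: Mapping | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage over the given inputs; return the result bundle.

    ``raw_matrices``/``features_by_chrom`` override the pair-derived
    matrices and genome-derived covariates per chromosome (the synthetic
    demo supplies deeply sampled matrices this way).  When ``outdir`` is
    given, each artifact is written as text with a manifest recording the
    configuration hash and seed.
    """
    out: dict = {"config": config}
    frags = digest(genome, config.site, config.cut_offset)
    cut_index = {
        c: cut_positions(genome.sequences[c], config.site, config.cut_offset)
        for c in genome.chrom_names
    }
    chrom_lengths = genome.lengths()
    out["fragments"] = frags

    valid, census = filter_pairs(
        pairs, cut_index, chrom_lengths,
        config.insert_max, config.min_rf_distance,
    )
    out["valid_pairs"] = valid
    out["pair_census"] = census

    mats, inter = bin_contacts(valid, config.bin_size, chrom_lengths)
    if raw_matrices:
        mats = dict(mats, **dict(raw_matrices))
    out["interchromosomal_counts"] = inter

    cent = (
        centromere_mask(config.centromeres, config.bin_size)
        if config.centromeres
        else {}
    )

    normalized, fits, strengths = {}, {}, {}
    strips_by_chrom, tracks, regions = {}, {}, {}
    for chrom, raw in mats.items():
        if features_by_chrom and chrom in features_by_chrom:
            feats = features_by_chrom[chrom]
        else:
            feats = bin_features(
                frags, genome, chrom, config.bin_size
            ) if chrom in genome.sequences else None
        if feats is None or raw.values.sum() == 0:
            continue
        if feats.n_bins != raw.n_bins:
            raise ValueError(
                f"covariate track ({feats.n_bins} bins) does not match the "
                f"contact matrix ({raw.n_bins} bins) on {chrom}"
            )
        norm_ok, analysis_ok = exclusion_mask(
            feats, cent.get(chrom), config.map_min, config.efflen_min
        )
        norm, fit = normalize(
            raw, feats, norm_ok, analysis_ok, residual=config.residual,
        )
        normalized[chrom] = norm
        fits[chrom] = fit
        strengths[chrom] = contact_strength(norm)
        track = strip_index(norm)
        strips_by_chrom[chrom] = (track, call_strips(track, config.strip_cutoff))
        di = directionality_index(norm, config.di_window_bp)
        st = fit_hmm(di, chrom, seed=config.seed)
        tracks[chrom] = st
        regions[chrom] = {
            "insulators": extract_insulators(st),
            "boundaries": extract_boundaries(st),
            "interiors": extract_interiors(st),
        }
    out["normalized"] = normalized
    out["fits"] = fits
    out["contact_strength"] = strengths
    out["strips"] = strips_by_chrom
    out["state_tracks"] = tracks
    out["regions"] = regions

    if outdir is not None:
        _write_bundle(out, genome, Path(outdir), config)
    return out


def _write_bundle(out: dict, genome: GenomeSequence, outdir: Path, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    prov = [f"config_hash={config.digest_hash()} seed={config.seed}"]
    hio.write_bed(
        ((f.chrom, f.start, f.end) for f in out["fragments"]),
        outdir / "fragments.bed", prov,
    )
    hio.write_pairs(out["valid_pairs"], outdir / "valid_pairs.tsv", prov)
    with open(outdir / "pair_census.tsv", "w") as fh:
        fh.write("# " + prov[0] + "\nclass\tcount\n")
        for k, v in sorted(out["pair_census"].items()):
            fh.write(f"{k}\t{v}\n")
    for chrom, norm in out["normalized"].items():
        hio.write_contacts(norm, outdir / f"{chrom}.normalized.tsv", prov)
        hio.write_bedgraph(
            chrom, out["contact_strength"][chrom], norm.bin_size,
            outdir / f"{chrom}.contact_strength.bedgraph", prov,
        )
        track, calls = out["strips"][chrom]
        hio.write_bedgraph(
            chrom, np.where(track.defined, track.index, np.nan), norm.bin_size,
            outdir / f"{chrom}.strip_index.bedgraph", prov,
        )
        hio.write_bed(
            (
                (c.chrom, c.start_bin * norm.bin_size, c.end_bin * norm.bin_size,
                 c.polarity, abs(c.peak_index))
                for c in calls
            ),
            outdir / f"{chrom}.strips.bed", prov,
        )
        st = out["state_tracks"][chrom]
        hio.write_bedgraph(
            chrom, st.di, norm.bin_size, outdir / f"{chrom}.di.bedgraph", prov
        )
        all_regions = [
            r for group in out["regions"][chrom].values() for r in group
        ]
        hio.write_bed(
            (
                (r.chrom, r.start_bin * norm.bin_size, r.end_bin * norm.bin_size,
                 r.type)
                for r in sorted(all_regions, key=lambda r: r.start_bin)
            ),
            outdir / f"{chrom}.regions.bed", prov,
        )
    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "config_hash": config.digest_hash(),
        "chromosomes": list(out["normalized"]),
        "n_valid_pairs": len(out["valid_pairs"]),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


# --- synthetic demonstration -------------------------------------------------

def _plant_strips(rng, n_bins: int, n_strips: int, margin: int = 40) -> set[int]:
    """Isolated strip bins, pairwise at least 60 bins apart and away from
    the chromosome ends (so local percentile contexts do not interact)."""
    bins: list[int] = []
    candidates = list(range(margin, n_bins - margin))
    rng.shuffle(candidates)
    for b in candidates:
        if all(abs(b - x) >= 60 for x in bins):
            bins.append(b)
            if len(bins) == n_strips:
                break
    return set(bins)


def _plant_blocks(n_bins: int, block: int = 10) -> tuple[list, set]:
    """Alternating up/down blocks; each up->down boundary is an insulator
    junction (recorded as the first bin of the down block)."""
    spans = []
    direction = "up"
    pos = 0
    while pos + block <= n_bins:
        spans.append((pos, pos + block, direction))
        direction = "down" if direction == "up" else "up"
        pos += block
    junctions = {
        nxt[0]
        for cur, nxt in zip(spans[:-1], spans[1:])
        if cur[2] == "up" and nxt[2] == "down"
    }
    return spans, junctions


def _block_state_runs(rng, n_bins: int, mean_run: int = 12) -> np.ndarray:
    """Latent chromatin-state labels 1..6 in geometric-length runs."""
    labels = np.empty(n_bins, dtype=int)
    pos = 0
    state = int(rng.integers(1, 7))
    while pos < n_bins:
        run = 1 + int(rng.geometric(1.0 / mean_run))
        labels[pos : pos + run] = state
        pos += run
        nxt = int(rng.integers(1, 7))
        state = nxt if nxt != state else 1 + (nxt % 6)
    return labels


def run_demo(
    seed: int = 0,
    outdir: str | Path | None = None,
    quick: bool = False,
) -> dict:
    """Build synthetic inputs, run the pipeline, and score truth recovery.

    Sizes: a 2-Mb strips chromosome (1000 bins at 2 kb) with ten planted
    strip bins over an end-count-derived coverage bias, and a 6-Mb domains
    chromosome tiled with alternating 60-kb (30-bin) directionality blocks
    giving 50 up->down insulator junctions — 60 kb matches both the DI
    window and the fly-sized domains the blocks emulate — plus 10,000
    labelled read pairs and a 3000-bin 400-bp epigenome with six latent
    states.  ``quick`` halves the map sizes and read counts.
    """
    rng = np.random.default_rng(seed)
    scale = 0.5 if quick else 1.0
    len1 = int(2_000_000 * scale)
    len2 = int(6_000_000 * scale)
    n_pairs = int(10_000 * scale)
    n_epi = int(3_000 * scale)
    config = PipelineConfig(seed=seed)

    genome = gen_genome(
        2, [len1, len2], gc=0.36, site=config.site,
        site_rate=1 / 250, seed=seed,
    )
    cut_index = {
        c: cut_positions(genome.sequences[c], config.site, config.cut_offset)
        for c in genome.chrom_names
    }
    frags = digest(genome, config.site, config.cut_offset)
    n_bins1 = len1 // config.bin_size
    n_bins2 = len2 // config.bin_size

    # chromosome 1: planted strips over an end-count-derived coverage bias
    feats1 = bin_features(frags, genome, "chr1", config.bin_size)
    bias = np.maximum(feats1.end_count.astype(float), 1.0)
    bias /= bias.mean()
    truth1 = SyntheticTruth(
        strip_bins=_plant_strips(rng, n_bins1, 10), bin_bias=bias
    )
    raw1, truth1 = gen_contact_map(
        n_bins1, config.bin_size, decay_exponent=-1.0, base_count=50.0,
        truth=truth1, strip_boost=3.0, di_block_strength=1.0,
        seed=seed + 1, chrom="chr1",
    )

    # chromosome 2: alternating 30-bin directionality blocks
    feats2 = bin_features(frags, genome, "chr2", config.bin_size)
    spans, junctions = _plant_blocks(n_bins2, block=30)
    truth2 = SyntheticTruth(
        bias_block_spans=spans, insulator_bins=junctions,
        bin_bias=np.ones(n_bins2),
    )
    raw2, truth2 = gen_contact_map(
        n_bins2, config.bin_size, decay_exponent=-1.0, base_count=50.0,
        truth=truth2, strip_boost=3.0, di_block_strength=2.0,
        seed=seed + 2, chrom="chr2",
    )

    pairs, pair_truth = gen_read_pairs(
        genome, cut_index, n_pairs,
        class_mix={
            "valid_intra": 0.5, "self_ligation": 0.2,
            "undigested_loop": 0.2, "short_insert": 0.1,
        },
        seed=seed + 3,
    )

    bundle = run_pipeline(
        genome, pairs, config,
        raw_matrices={"chr1": raw1, "chr2": raw2},
        features_by_chrom={"chr1": feats1, "chr2": feats2},
        outdir=outdir,
    )

    # --- score the recovery --------------------------------------------
    from .pairs import classify_pair  # late import to avoid cycle noise

    truth_to_filter = {
        "valid_intra": "valid_intra", "valid_inter": "valid_inter",
        "self_ligation": "self_ligation", "undigested_loop": "too_close",
        "short_insert": "short_insert",
    }
    chrom_lengths = genome.lengths()
    correct = sum(
        classify_pair(p, cut_index, chrom_lengths,
                      config.insert_max, config.min_rf_distance)
        == truth_to_filter[lab]
        for p, lab in zip(pairs, pair_truth.pair_labels)
    )
    pair_accuracy = correct / len(pairs)

    _, strip_calls = bundle["strips"]["chr1"]
    called = {
        b for c in strip_calls if c.polarity == "positive"
        for b in range(c.start_bin, c.end_bin)
    }
    tp = len(called & truth1.strip_bins)
    strip_precision = tp / len(called) if called else 0.0
    strip_recall = tp / len(truth1.strip_bins)

    insulators = bundle["regions"]["chr2"]["insulators"]
    d_starts = set()
    for r in insulators:
        # first D bin of the call = position after the U(N*) prefix
        for k, ch in enumerate(r.matched_states):
            if ch == "D":
                d_starts.add(r.start_bin + k)
                break
    recovered = sum(
        any(abs(j - d) <= 1 for d in d_starts) for j in truth2.insulator_bins
    )
    junction_recovery = recovered / len(truth2.insulator_bins)

    state_labels = _block_state_runs(rng, n_epi)
    coverage = gen_epigenome(n_epi, state_labels, seed=seed + 4)
    scores = quintile_scores(coverage)
    km_labels, centroids = classify_states(scores, seed=seed)
    names = name_states(centroids)
    keep = km_labels >= 0
    cs_agreement = adjusted_rand_score(state_labels[keep], km_labels[keep])

    metrics = {
        "pair_filter_accuracy": pair_accuracy,
        "pair_census": dict(bundle["pair_census"]),
        "strip_precision": strip_precision,
        "strip_recall": strip_recall,
        "n_strip_bins_called": len(called),
        "insulator_junction_recovery": junction_recovery,
        "n_insulator_calls": len(insulators),
        "n_boundary_calls": len(bundle["regions"]["chr2"]["boundaries"]),
        "n_interior_calls": len(bundle["regions"]["chr2"]["interiors"]),
        "cs_agreement": cs_agreement,
        "state_names": names,
        "n_pairs": len(pairs),
        "n_bins": {"chr1": n_bins1, "chr2": n_bins2},
        "n_epigenome_bins": n_epi,
    }
    bundle["metrics"] = metrics
    bundle["truth"] = {"chr1": truth1, "chr2": truth2, "pairs": pair_truth}
    if outdir is not None:
        with open(Path(outdir) / "demo_metrics.json", "w") as fh:
            json.dump(
                {k: v for k, v in metrics.items() if k != "state_names"},
                fh, indent=2, default=str,
            )
    return bundle
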