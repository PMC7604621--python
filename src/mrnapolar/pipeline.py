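"""End-to-end synthetic pipeline: simulate -> enrich -> cluster -> scan ->
polarisation -> proximity, with a reproducibility manifest.

Every stage draws randomness from an independent substream derived from the
single global seed and the stage name, so two runs with the same
configuration produce byte-identical outputs and adding a stage does not
perturb the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as mio
from ._util import substream
from .enrichment import (
    cluster_foldchanges,
    filter_enriched,
    identify_universal_cluster,
    status_cluster_count,
)
from .motifs import ALPHABET, estimate_pwm, scan_sequence
from .proximity import filter_complete_events, proximity_analysis
from .spots import polarisation_index, cohort_pi_ratio, detect_spots
from .synthetic import (
    SimCellSpec,
    SimFoldChangeSpec,
    SimSequenceSpec,
    SimTimelapseSpec,
    gen_cell_with_spots,
    gen_foldchange_table,
    gen_timelapse,
    gen_utr_sequences,
    render_smfish_image,
)

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _seed_for(config: mio.RunConfig, stage: str) -> int:
    return int(substream(config.seed, stage).integers(2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: mio.RunConfig, out_dir: str | Path) -> dict:
    """Run every stage on synthetic inputs and write results to ``out_dir``.

    Returns the summary report (also written as ``summary.json``); a
    ``manifest.json`` records the configuration and the SHA-256 of every
    output file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # -- enrichment clustering -------------------------------------------
    fc_spec = SimFoldChangeSpec(
        n_genes_per_status=config.n_genes_per_status,
        noise_sd=config.foldchange_noise_sd,
        frac_null_pvalues=config.frac_null_pvalues,
        seed=_seed_for(config, "foldchange"),
    )
    table, truth = gen_foldchange_table(fc_spec)
    mio.write_foldchange_table(table, out / "foldchanges.tsv")
    mio.write_foldchange_table(truth, out / "foldchanges_truth.tsv")

    enriched, depleted = filter_enriched(
        table, "ref", config.fc_hi, config.fc_lo, config.q_max
    )
    filtered = table[table["gene_id"].isin(enriched)]
    datasets = list(fc_spec.comparison_datasets)
    k = status_cluster_count(len(datasets))
    if k != config.k:
        logger.warning("configured k=%d differs from combinatorial k=%d", config.k, k)
        k = config.k
    model = cluster_foldchanges(
        filtered, datasets, k=k, n_starts=config.n_starts, seed=_seed_for(config, "kmeans")
    )
    universal = identify_universal_cluster(model)
    cluster_df = filtered[["gene_id"] + [f"log2fc_{d}" for d in datasets]].copy()
    cluster_df["cluster"] = [model.assignments[g] for g in cluster_df["gene_id"]]
    cluster_df.to_csv(out / "clusters.tsv", sep="\t", index=False, float_format="%.10g")
    report["enrichment"] = {
        "n_genes": int(len(table)),
        "n_enriched": int(len(enriched)),
        "n_depleted": int(len(depleted)),
        "k": k,
        "universal_cluster": universal,
        "n_universal_genes": int(sum(1 for c in model.assignments.values() if c == universal)),
    }

    # -- motif scanning ---------------------------------------------------
    rng = substream(config.seed, "motif-consensus")
    consensus = "".join(rng.choice(list(ALPHABET), size=config.motif_width))
    pwm = estimate_pwm([consensus] * 10, pseudocount=0.1, name="sim_motif")
    mio.write_meme_motif(pwm, out / "motif.meme")

    genes = sorted(model.assignments)
    labels = {g: model.assignments[g] for g in genes}
    copies = [
        config.utr_copies_universal if labels[g] == universal else config.utr_copies_other
        for g in genes
    ]
    seq_spec = SimSequenceSpec(
        planted_pwm=pwm,
        n_sequences=len(genes),
        copies_per_sequence=copies,
        seed=_seed_for(config, "sequences"),
    )
    sequences, seq_truth = gen_utr_sequences(seq_spec)
    sequences = {g: s for g, s in zip(genes, sequences.values())}
    mio.write_fasta(sequences, out / "utrs.fasta")
    hits = []
    hit_counts = {}
    for gid, seq in sequences.items():
        h = scan_sequence(pwm, seq, config.p_max, sequence_id=gid)
        hits.extend(h)
        hit_counts[gid] = len(h)
    mio.write_hits_bed(hits, out / "motif_hits.tsv", name=pwm.name)
    from .motifs import motif_cluster_frequency

    freq = motif_cluster_frequency(hit_counts, labels, min_count=config.min_count)
    report["motif"] = {
        "n_hits": len(hits),
        "cluster_frequency_ge2": {str(k_): round(v, 6) for k_, v in sorted(freq.items())},
        "universal_cluster_frequency": freq.get(universal),
    }

    # -- polarisation index ----------------------------------------------
    cell_rows = []
    targets, controls = [], []
    cell_seed = substream(config.seed, "cells")
    for i in range(config.n_cells):
        s_t = SimCellSpec(
            n_spots=config.spots_per_cell,
            polarization_kappa=config.polarization_kappa,
            seed=int(cell_seed.integers(2**31)),
        )
        s_c = SimCellSpec(
            n_spots=config.spots_per_cell,
            polarization_kappa=0.0,
            seed=int(cell_seed.integers(2**31)),
        )
        geom_t, spots_t = gen_cell_with_spots(s_t)
        geom_c, spots_c = gen_cell_with_spots(s_c)
        pi_t = polarisation_index(spots_t, geom_t)
        pi_c = polarisation_index(spots_c, geom_c)
        targets.append(pi_t)
        controls.append(pi_c)
        cell_rows.append(
            {"cell_id": f"cell{i:03d}", "pi_target": pi_t.pi, "pi_control": pi_c.pi}
        )
    import pandas as pd

    pd.DataFrame(cell_rows).to_csv(
        out / "polarisation.tsv", sep="\t", index=False, float_format="%.10g"
    )
    mean_ratio, n_used, n_excluded = cohort_pi_ratio(targets, controls)
    # one rendered image through the detector as an imaging smoke check
    geom_img, spots_img = gen_cell_with_spots(
        SimCellSpec(n_spots=30, polarization_kappa=0.0, seed=_seed_for(config, "image"))
    )
    img = render_smfish_image(
        geom_img, spots_img, noise="poisson", seed=_seed_for(config, "image-noise")
    )
    mio.write_image(img.pixels, out / "example_smfish.tiff")
    detected = detect_spots(img.pixels, img.pixel_size, psf_sigma=0.2, snr_min=5)
    report["polarisation"] = {
        "n_cells": config.n_cells,
        "mean_pi_target": float(np.mean([r.pi for r in targets])),
        "mean_pi_control": float(np.mean([r.pi for r in controls])),
        "mean_pi_ratio": mean_ratio,
        "n_ratio_excluded": n_excluded,
        "image_spots_planted": len(spots_img),
        "image_spots_detected": len(detected),
    }

    # -- proximity --------------------------------------------------------
    tl_spec = SimTimelapseSpec(
        n_filopodia=config.n_filopodia,
        coupling_strength=config.coupling_strength,
        coupling_lambda=config.coupling_lambda,
        seed=_seed_for(config, "timelapse"),
    )
    tracks, events, roi = gen_timelapse(tl_spec)
    mio.write_track_table(tracks, out / "tracks.csv")
    mio.write_event_table(events, out / "filopodia.csv")
    mio.write_mask_stack(roi, out / "roi.tiff")
    kept = filter_complete_events(events, (0, tl_spec.n_frames - 1))
    prox = proximity_analysis(
        kept, tracks, roi, bin_width=config.bin_width_um, seed=_seed_for(config, "proximity")
    )
    report["proximity"] = {
        "n_events": prox.n_events,
        "pearson_observed_r": prox.pearson_observed[0],
        "pearson_observed_p": prox.pearson_observed[1],
        "pearson_control_r": prox.pearson_control[0],
        "pearson_control_p": prox.pearson_control[1],
        "spearman_observed_rho": prox.spearman_observed[0],
        "spearman_observed_p": prox.spearman_observed[1],
        "spearman_control_rho": prox.spearman_control[0],
        "spearman_control_p": prox.spearman_control[1],
        "median_observed_um": float(np.median(prox.observed)),
        "median_control_um": float(np.median(prox.control)),
    }

    # -- manifest ---------------------------------------------------------
    (out / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
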