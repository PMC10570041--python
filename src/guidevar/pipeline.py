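"""End-to-end demo recipe: simulate -> quantify -> train -> score -> triage.

Ties the modules together on a fully synthetic study so the complete
workflow is exercisable without external data.  Every stage writes its
tables into the output directory together with the resolved configuration,
and all randomness derives from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import dualtarget as dt
from . import offtarget as ot
from . import screenstats as ss
from . import synthdata as sd
from . import triage as tr
from .config import RunConfig
from .ontarget import (
    GuideVarOnRegressor,
    efficiency_from_zscores,
    pretrain_encoder,
)
from .seqfeat import Spacer

log = logging.getLogger("guidevar")


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the configured recipe; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.resolved.yaml")
    seed = int(config.seed)
    rng = np.random.default_rng(seed)

    # 1. library + planted truth ------------------------------------------
    log.info("simulating library of %d guides", config.n_guides)
    library = sd.gen_library(config.n_guides, seed=seed)
    truth = sd.make_truth(library, seed=seed + 1)
    library.to_csv(outdir / "library.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    spacers = [Spacer(s, i) for s, i in zip(library["sequence"], library["id"])]

    # 2. viability screens -------------------------------------------------
    screens = {}
    for k, enzyme in enumerate(dt.ENZYMES):
        screens[enzyme] = sd.gen_screen(
            library,
            truth,
            enzyme=enzyme,
            depth=config.screen.depth,
            n_reps=config.screen.n_reps,
            nb_size=config.screen.nb_size,
            seed=seed + 10 + k,
        )
        screens[enzyme].to_csv(outdir / f"screen_{enzyme}.tsv", sep="\t")

    # 3. efficiency groups + positional features --------------------------
    ess = library.set_index("id")["essential"].astype(bool)
    z_wt = screens["WT"].loc[ess, "z"]
    z_var = (screens["HiFi"].loc[ess, "z"] + screens["LZ3"].loc[ess, "z"]) / 2.0
    groups = ss.classify_efficiency_groups(z_wt, z_var, z_thr=config.thresholds.z_thr)
    groups.rename("group").to_csv(outdir / "efficiency_groups.tsv", sep="\t")
    spacer_by_id = {s.id: s for s in spacers}
    both = [spacer_by_id[i] for i in groups.index[groups == ss.BOTH_EFFICIENT]]
    wt_only = [spacer_by_id[i] for i in groups.index[groups == ss.WT_EFFICIENT_ONLY]]
    if both and wt_only:
        ss.position_log_odds(both, wt_only).to_csv(outdir / "log_odds.tsv", sep="\t")
        ss.position_kl(both, wt_only).rename("kl").to_csv(outdir / "kl.tsv", sep="\t")

    # 4. dual-target quantification ---------------------------------------
    log.info("simulating dual-target panels")
    counts, pairs, _dt_truth = sd.gen_dualtarget(
        library, truth, depth=config.dualtarget.depth, seed=seed + 20
    )
    ratios = dt.counts_table_to_records(counts)
    ratios.to_csv(outdir / "off_on_ratios.tsv", sep="\t")
    one_mm = [
        (pairs[pid], row.r_wt)
        for pid, row in ratios.iterrows()
        if pairs[pid].n_mismatches == 1
    ]
    two_mm = [
        (pairs[pid], row.r_wt)
        for pid, row in ratios.iterrows()
        if pairs[pid].n_mismatches == 2
    ]
    ime = dt.estimate_ime(one_mm)
    delta = dt.estimate_delta(two_mm, ime)
    ime.to_tsv(outdir / "ime.tsv")
    delta.to_tsv(outdir / "delta.tsv")

    # 5. single-mismatch off-target model (variant-averaged ratios) -------
    gmt = ot.LookupGMT(truth.gmt, default=float(np.mean(list(truth.gmt.values()))))
    X = ot.mismatch_features([p for p, _ in one_mm], ime, gmt)
    y_vt = np.array(
        [ratios.loc[pid, "r_vt"] for pid in ratios.index if pairs[pid].n_mismatches == 1]
    )
    sm_model = ot.SingleMismatchRegressor(kind="gbt", random_state=seed).fit(X, y_vt)
    scorer = ot.OffTargetScorer(model=sm_model, ime=ime, gmt=gmt, delta=delta)

    # 6. toy genome + per-guide aggregate off scores ----------------------
    promiscuous = [s for s in spacers if truth.off_burden[s.id] > 0]
    quiet = [s for s in spacers if truth.off_burden[s.id] == 0]
    genomes = {}
    if quiet:
        g, m = sd.gen_toy_genome(
            quiet,
            n_planted=config.genome.n_planted_quiet,
            mm_counts=(3,),
            size_bp=max(
                config.genome.size_bp,
                len(quiet) * config.genome.n_planted_quiet * 30,
            ),
            contig="quiet",
            seed=seed + 30,
        )
        genomes.update(g)
    if promiscuous:
        g, m = sd.gen_toy_genome(
            promiscuous,
            n_planted=config.genome.n_planted_promiscuous,
            mm_counts=(1,),
            size_bp=max(
                10000,
                len(promiscuous) * config.genome.n_planted_promiscuous * 30,
            ),
            contig="promiscuous",
            seed=seed + 31,
        )
        genomes.update(g)
    sd.write_fasta(genomes, outdir / "toy_genome.fa")
    off_scores = pd.Series(
        {
            s.id: scorer.aggregate_score(
                s, ot.enumerate_sites(s, genomes, max_mm=config.genome.max_mm)
            )
            for s in spacers
        }
    )

    # 7. on-target transfer model -----------------------------------------
    log.info("pretraining source encoders")
    pre_lib = sd.gen_library(config.ontarget.pretrain_n, seed=seed + 40)
    pre_spacers = [Spacer(s, i) for s, i in zip(pre_lib["sequence"], pre_lib["id"])]
    pre_truth = sd.make_truth(pre_lib, seed=seed + 41)
    y_wt_task = np.array([pre_truth.wt_efficiency(s) for s in pre_spacers])
    y_hf_task = np.array([pre_truth.variant_efficiency(s) for s in pre_spacers])
    enc_wt = pretrain_encoder(
        pre_spacers, y_wt_task, hidden=config.ontarget.hidden,
        epochs=config.ontarget.pretrain_epochs, seed=seed + 42, task_tag="WT-task",
    )
    enc_hf = pretrain_encoder(
        pre_spacers, y_hf_task, hidden=config.ontarget.hidden,
        epochs=config.ontarget.pretrain_epochs, seed=seed + 43, task_tag="HF1-task",
    )
    y_fit = efficiency_from_zscores(screens["HiFi"]["z"], screens["LZ3"]["z"])
    on_model = GuideVarOnRegressor(
        encoders=(enc_wt, enc_hf),
        features=config.ontarget.features,
        hidden_layer_sizes=tuple(config.ontarget.hidden_layer_sizes),
        max_iter=config.ontarget.max_iter,
        random_state=seed,
    ).fit(spacers, y_fit.to_numpy() if hasattr(y_fit, "to_numpy") else y_fit)
    on_scores = pd.Series(on_model.predict(spacers), index=library["id"])

    # 8. triage + evaluation ----------------------------------------------
    result = tr.classify(
        on_scores,
        off_scores,
        on_thr=config.thresholds.on_thr,
        off_thr=config.thresholds.off_thr,
    )
    result.to_csv(outdir / "triage.tsv", sep="\t")
    hifi = screens["HiFi"]
    ssmds = tr.evaluate_selection(result, hifi[["lfc", "essential"]], strict=False)
    summary = {
        "n_guides": int(config.n_guides),
        "category_counts": result["category"].value_counts().to_dict(),
        "ssmd": ssmds,
        "wt_efficient_only_fraction": float((groups == ss.WT_EFFICIENT_ONLY).mean()),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    log.info("pipeline complete: %s", outdir)
    return outdir
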