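"""End-to-end pipeline on synthetic data: simulate, score/classify,
differential methylation per generation, maintained differences, enrichment,
metagene/MDS summaries and the expression overlap, with a machine-readable
summary of every stage count and (in simulation mode) recovery metrics
against the planted ground truth."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import integration as integ
from . import io as tio
from . import methylome as meth
from . import synthetic as synth
from .config import RunConfig

logger = logging.getLogger(__name__)


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Run every stage on simulated inputs and return the summary dict.

    With ``out_dir`` set, all intermediate tables (session CSV, scores,
    coverage TSVs, DMC tables, maintained BED, enrichment JSON, metagene
    TSV, MDS CSV, overlap JSON, summary JSON) are written there.  Identical
    cfg+seed gives an identical bundle.
    """
    cfg.validate()
    thr = cfg.thresholds
    out = Path(out_dir) if out_dir is not None else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "thresholds": cfg.to_dict()["thresholds"]}

    # --- behaviour ---------------------------------------------------------
    stage = "behavior"
    try:
        sessions, latent = synth.simulate_behavior_cohort(cfg.behavior)
        scores = beh.score_cohort(sessions)
        scores = beh.classify(scores, beh.ClassifierConfig(thr.top_fraction, thr.bottom_fraction))
        addict = scores[scores["label"] == "Addict"]
        nonadd = scores[scores["label"] == "Non-addict"]
        z, p = beh.rank_sum_test(addict["break_point"], nonadd["break_point"])
        lat = latent.set_index("animal_id")["motivation"]
        summary["behavior"] = {
            "n_animals": int(len(scores)),
            "n_addict": int(len(addict)),
            "n_non_addict": int(len(nonadd)),
            "break_point_rank_sum_Z": float(z),
            "break_point_rank_sum_p": float(p),
            "mean_motivation_addict": float(lat.loc[addict["animal_id"]].mean()),
            "mean_motivation_non_addict": float(lat.loc[nonadd["animal_id"]].mean()),
        }
        if out:
            sessions.to_csv(out / "sessions.csv", index=False)
            scores.to_csv(out / "scores.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- methylome ---------------------------------------------------------
    stage = "methylome"
    try:
        gm = synth.simulate_gene_model(chrom_sizes=cfg.methylome.chrom_sizes, seed=cfg.seed)
        matrix, truth = synth.simulate_methyl_matrix(cfg.methylome, gene_model=gm)
        filtered = meth.filter_sites(
            matrix, meth.FilterConfig(thr.min_samples_detected, thr.min_coverage)
        )
        f0 = meth.dmc_test(filtered, "F0", alpha=thr.alpha, use_fdr=thr.use_fdr)
        f1 = meth.dmc_test(filtered, "F1", alpha=thr.alpha, use_fdr=thr.use_fdr)
        maintained = meth.maintained_differences(f0, f1)

        maintained_ids = set(
            maintained["chrom"].astype(str) + ":" + maintained["pos"].astype(str)
        )
        truly = truth.maintained_site_ids
        recovered = maintained_ids & truly
        sensitivity = len(recovered) / len(truly) if truly else float("nan")
        fdp = (
            len(maintained_ids - truth.planted_site_ids) / len(maintained_ids)
            if maintained_ids
            else 0.0
        )

        hypo = meth.hypo_flags(filtered, thr.hypo_threshold)
        site_ids = filtered.site_ids
        maint_mask = site_ids.isin(maintained_ids).to_numpy()
        hypo_enr = meth.feature_enrichment(hypo[maint_mask], hypo[~maint_mask])

        ann = meth.annotate_sites(filtered.sites, gm, thr.promoter_window)
        prom = (ann["element"] == "promoter").to_numpy()
        prom_enr = meth.feature_enrichment(
            pd.Series(prom[maint_mask], dtype=float), pd.Series(prom[~maint_mask], dtype=float)
        )

        profile = meth.metagene_profile(filtered, gm)
        mds = meth.mds_embedding(filtered, dims=2)
        d1_f0 = mds.loc[mds["generation"] == "F0", "dim1"]
        d1_f1 = mds.loc[mds["generation"] == "F1", "dim1"]
        _, mds_p = beh.rank_sum_test(d1_f0, d1_f1)

        summary["methylome"] = {
            "n_sites_simulated": int(matrix.n_sites),
            "n_sites_filtered": int(filtered.n_sites),
            "n_dmc_f0": int(f0["significant"].sum()),
            "n_dmc_f1": int(f1["significant"].sum()),
            "n_maintained": int(len(maintained_ids)),
            "n_truly_maintained": int(len(truly)),
            "maintained_sensitivity": float(sensitivity),
            "maintained_fdp": float(fdp),
            "hypo_fraction_maintained": float(np.nanmean(hypo[maint_mask]))
            if maint_mask.any()
            else float("nan"),
            "hypo_fraction_background": float(np.nanmean(hypo[~maint_mask])),
            "hypo_enrichment": hypo_enr.to_dict() if maint_mask.any() else None,
            "promoter_fraction_maintained": float(prom[maint_mask].mean())
            if maint_mask.any()
            else float("nan"),
            "promoter_fraction_background": float(prom[~maint_mask].mean()),
            "promoter_enrichment": prom_enr.to_dict() if maint_mask.any() else None,
            "mds_generation_rank_sum_p": float(mds_p),
        }
        if out:
            tio.write_coverage_tables(matrix, out / "coverage", coord_base=cfg.coord_base)
            truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
            tio.write_bed12(gm, out / "genes.bed12")
            f0.to_csv(out / "dmc_F0.tsv", sep="\t", index=False)
            f1.to_csv(out / "dmc_F1.tsv", sep="\t", index=False)
            tio.write_sites_bed(maintained, out / "maintained.bed")
            tio.write_json(
                {"hypomethylation": summary["methylome"]["hypo_enrichment"],
                 "promoter": summary["methylome"]["promoter_enrichment"]},
                out / "enrichment.json",
            )
            profile.to_csv(out / "metagene.tsv", sep="\t", index=False)
            mds.to_csv(out / "mds.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- integration -------------------------------------------------------
    stage = "integration"
    try:
        gene_ids = list(gm.genes["gene_id"])
        meth_genes = integ.maintained_promoter_genes(maintained, gm, thr.promoter_window)
        de_table = synth.simulate_de_table(gene_ids, enriched_genes=meth_genes, seed=cfg.seed)
        de_genes = integ.filter_de(de_table, thr.min_fold_change, thr.max_de_p)
        universe = set(gene_ids) & set(de_table["gene_id"].astype(str))
        overlap = integ.overlap_enrichment(meth_genes & universe, de_genes & universe, universe)
        summary["integration"] = overlap.to_dict()
        if out:
            de_table.to_csv(out / "de_table.csv", index=False)
            tio.write_json(overlap.to_dict(), out / "overlap.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # conservation check: maintained can never exceed either generation's DMCs
    assert summary["methylome"]["n_maintained"] <= min(
        summary["methylome"]["n_dmc_f0"], summary["methylome"]["n_dmc_f1"]
    )
    if out:
        tio.write_json(summary, out / "summary.json")
    return summary
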