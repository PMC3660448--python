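"""End-to-end orchestration: simulate -> select -> scan -> burden -> LD/tags.

One :func:`run_pipeline` call produces, under an output directory, the
simulated dataset (VCF + annotation + phenotype tables), the selection
table, per-variant association tables split by functional class, a signed
-log10(p) table, a burden-test grid, LD/tag reports for the designated
exonic set, a descriptive count summary, and a JSON manifest from which
every reported number is recomputable.  Strata are analyzed independently
and never pooled.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import extremevar
from extremevar import design
from extremevar.burden_tests import burden_suite
from extremevar.ld_tags import greedy_tags, ld_matrix
from extremevar.single_tests import (
    bonferroni_threshold,
    display_threshold,
    scan_to_frame,
    single_variant_scan,
)
from extremevar.syndata import STRATA, SimConfig, apply_missingness, generate_cohort, write_dataset
from extremevar.variant_io import (
    classify_rarity,
    maf_vector,
    write_results_table,
)

logger = logging.getLogger(__name__)


def summarize_counts(annotations: pd.DataFrame) -> pd.DataFrame:
    """Descriptive counts by functional class, novelty and (when per-stratum
    ``maf_<stratum>`` columns are present) per-stratum polymorphism and
    rarity."""
    rows = []
    maf_cols = [c for c in annotations.columns if c.startswith("maf_")]
    for func, grp in annotations.groupby("func_class", sort=True):
        row = {"func_class": func, "n": len(grp), "n_novel": int(grp["novel"].sum())}
        for c in maf_cols:
            stratum = c[len("maf_"):]
            maf = grp[c].to_numpy(dtype=float)
            poly = np.isfinite(maf) & (maf > 0)
            row[f"n_poly_{stratum}"] = int(poly.sum())
            row[f"n_rare_{stratum}"] = int((poly & (maf < 0.05)).sum())
        rows.append(row)
    out = pd.DataFrame(rows)
    total = {"func_class": "total", "n": int(out["n"].sum()),
             "n_novel": int(out["n_novel"].sum())}
    for c in out.columns:
        if c.startswith("n_poly_") or c.startswith("n_rare_"):
            total[c] = int(out[c].sum())
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: SimConfig,
    outdir,
    n_permutations: int = 2000,
    maf_threshold: float = 0.05,
    r2_threshold: float = 0.7,
) -> dict:
    """Run the full extreme-phenotype association pipeline on a simulated
    cohort; returns the manifest dictionary (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    stage_counts: dict = {}

    logger.info("stage simulate: generating base cohort")
    sim = generate_cohort(config)
    stage_counts["base_cohort_subjects"] = int(sim.genotypes.n_subjects)
    stage_counts["panel_variants"] = int(sim.genotypes.n_variants)

    logger.info("stage select: covariate adjustment and extreme selection")
    adjusted = design.adjust_cohort(sim.cohort)
    adjusted["group"] = design.select_extremes(adjusted)
    selected = adjusted["group"].isin(["hyper", "hypo"]).to_numpy()
    sel_cohort = adjusted.loc[selected]
    stage_counts["selected_subjects"] = int(selected.sum())
    stage_counts["hyper"] = int((sel_cohort["group"] == "hyper").sum())
    stage_counts["hypo"] = int((sel_cohort["group"] == "hypo").sum())

    keep = pd.Index(sim.genotypes.subject_ids).isin(sel_cohort["subject_id"])
    gm = sim.genotypes.subset_subjects(np.asarray(keep))
    gm = apply_missingness(gm, config.missing_rate, seed)
    stage_counts["mean_missing_rate"] = float(gm.missing.mean())

    paths = write_dataset(sim, outdir, gm=gm)
    design.write_selection(adjusted, outdir / "selection.tsv")
    paths["selection"] = outdir / "selection.tsv"

    ann = sim.annotations.copy()
    group_of = sel_cohort.set_index("subject_id")["group"]
    bonf = bonferroni_threshold(0.05, gm.n_variants)
    results_summary: dict = {}
    for stratum in STRATA:
        view = gm.stratum_view(stratum)
        hyper = group_of.loc[list(view.subject_ids)].to_numpy() == "hyper"
        mafs = maf_vector(view)
        ann[f"maf_{stratum}"] = mafs

        logger.info("stage scan[%s]: %d variants, %d hyper / %d hypo",
                    stratum, view.n_variants, hyper.sum(), (~hyper).sum())
        scan = scan_to_frame(single_variant_scan(view, hyper, stratum, maf_threshold))
        scan = scan.merge(
            ann[["variant_id", "pos", "rsid", "ref", "alt", "func_class", "novel"]],
            on="variant_id", how="left")
        write_results_table(scan, outdir / f"scan_{stratum}.tsv")
        for cls in ("missense", "synonymous"):
            sub = scan[scan["func_class"] == cls]
            write_results_table(sub, outdir / f"table_{cls}_{stratum}.tsv")
        write_results_table(
            scan[["variant_id", "pos", "func_class", "p_value", "direction",
                  "signed_neglog10_p"]],
            outdir / f"signed_neglog10_{stratum}.tsv")
        tested = scan["p_value"].notna()
        results_summary[stratum] = {
            "n_tested": int(tested.sum()),
            "min_p": float(scan.loc[tested, "p_value"].min()) if tested.any() else None,
            "n_below_bonferroni": int((scan.loc[tested, "p_value"] < bonf).sum()),
        }

        logger.info("stage burden[%s]", stratum)
        grid = burden_suite(view, ann, hyper, stratum=stratum,
                            maf_threshold=maf_threshold,
                            n_permutations=n_permutations,
                            rng_seed=seed + 7 * (STRATA.index(stratum) + 1),
                            include_calpha=True)
        write_results_table(grid, outdir / f"burden_{stratum}.tsv")

        logger.info("stage ld[%s]", stratum)
        ld_ids = [v for v in (sim.panel.burden_set + [sim.panel.index_variant])]
        in_set = np.isin(view.variant_ids, ld_ids)
        poly = np.isfinite(mafs) & (mafs > 0)
        ld_gm = view.subset_variants(in_set & poly)
        if ld_gm.n_variants >= 2:
            r2, dprime = ld_matrix(ld_gm)
            r2.to_csv(outdir / f"ld_r2_{stratum}.tsv", sep="\t", float_format="%.4f")
            dprime.to_csv(outdir / f"ld_dprime_{stratum}.tsv", sep="\t",
                          float_format="%.4f")
            sub_ann = ann.set_index("variant_id").loc[list(ld_gm.variant_ids)]
            tags = greedy_tags(r2, r2_threshold,
                               maf=maf_vector(ld_gm), pos=sub_ann["pos"].to_numpy())
            pd.DataFrame(
                {"variant_id": list(tags.coverage_map.keys()),
                 "tag": list(tags.coverage_map.values())}
            ).sort_values("variant_id").to_csv(outdir / f"tags_{stratum}.tsv",
                                               sep="\t", index=False)
            results_summary[stratum]["n_ld_variants"] = int(ld_gm.n_variants)
            results_summary[stratum]["n_tags"] = len(tags.tags)

    counts = summarize_counts(ann)
    counts.to_csv(outdir / "counts.tsv", sep="\t", index=False)

    manifest = {
        "package_version": extremevar.__version__,
        "seed": seed,
        "config": dataclasses.asdict(config),
        "n_permutations": n_permutations,
        "maf_threshold": maf_threshold,
        "r2_threshold": r2_threshold,
        "bonferroni_threshold": bonf,
        "bonferroni_display": display_threshold(bonf),
        "stage_counts": stage_counts,
        "results": results_summary,
        "outputs": {},
    }
    for p in sorted(outdir.glob("*.tsv")) + [paths["vcf"]]:
        manifest["outputs"][p.name] = _sha256(Path(p))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
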