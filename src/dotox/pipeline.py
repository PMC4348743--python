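"""End-to-end orchestration: simulate -> QC -> reconstruct -> scan ->
heritability / dominance -> benchmark concentration -> report.

``run_all`` executes every stage from a single :class:`~dotox.config.RunConfig`
and a seed, writes the stage artifacts into an output directory, and returns a
summary dictionary.  Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bmc as bmc_mod
from . import hmm, io, phenostats, quantgen, scan, synthetic
from .config import RunConfig
from .containers import TrueQtlSpec, dumps_json

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is carried in the message."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with context
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_all(config: RunConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    summary: dict = {"seed": config.seed}

    # --- simulate ---------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        founders = synthetic.simulate_founder_genomes(
            n_chromosomes=config.n_chromosomes,
            markers_per_chromosome=config.markers_per_chromosome,
            private_interval=tuple(config.private_interval),
            chromosome_length_mb=config.chromosome_length_mb,
            seed=config.seed,
        )
        mosaics = synthetic.simulate_do_population(
            founders, config.n_mice, generation=config.generation, seed=config.seed + 1
        )
        qtl = None
        if config.qtl_on:
            qtl = TrueQtlSpec(
                chromosome=config.qtl_chromosome,
                position_mb=config.qtl_position_mb,
                focal_founder=config.qtl_founder,
                mode=config.qtl_mode,
                var_frac=config.qtl_var_frac,
            )
        exposure = synthetic.assign_exposures(
            [m.mouse_id for m in mosaics], doses=config.doses, seed=config.seed + 2
        )
        pheno = synthetic.simulate_phenotypes(
            mosaics,
            founders,
            qtl,
            exposure,
            exp_params=(config.exp_a, config.exp_b, config.exp_c),
            h2_target=config.h2_target,
            sigma_log=config.sigma_log,
            seed=config.seed + 3,
        )
        genos = synthetic.genotype_from_mosaic(
            mosaics,
            founders,
            error_rate=config.genotype_error_rate,
            missing_rate=config.genotype_missing_rate,
            missing_rate_sd=config.genotype_missing_rate_sd,
            seed=config.seed + 4,
        )
        io.write_phenotypes(pheno, outdir / "phenotypes.csv")
        io.write_genotypes(genos, outdir / "genotypes.csv")
        io.write_marker_map(founders.marker_map, outdir / "marker_map.csv")
        io.write_founders(
            founders, outdir / "founders.csv", outdir / "founders_meta.json"
        )
        io.write_truth(pheno.attrs["truth"], outdir / "truth.json")
        return founders, mosaics, pheno, genos

    founders, mosaics, pheno, genos = _simulate()

    # --- QC ---------------------------------------------------------------
    @_stage("qc")
    def _qc():
        kept, report = io.qc_filter(genos, config.qc_call_rate_threshold)
        report.to_csv(outdir / "qc_report.csv", index=False)
        return kept, report

    genos_qc, qc_report = _qc()
    summary["n_qc_removed"] = int(qc_report["removed"].sum())

    # --- reconstruct ------------------------------------------------------
    @_stage("reconstruct")
    def _reconstruct():
        dosages = hmm.reconstruct(
            genos_qc,
            founders,
            generation=config.generation,
            error_rate=config.hmm_error_rate,
        )
        io.write_dosages(dosages, cache_path=outdir / "dosages.npz")
        return dosages

    dosages = _reconstruct()
    kept_mice = list(genos_qc.columns)
    pheno_qc = pheno.set_index("mouse_id").loc[kept_mice].reset_index()

    # --- phenotype statistics --------------------------------------------
    @_stage("report")
    def _phenostats():
        gs = phenostats.group_summaries(
            pheno_qc["post_bm_mnret"], pheno_qc["exposure_ppm"]
        )
        gs.to_csv(outdir / "group_summaries.csv", index=False)
        anova = phenostats.two_way_anova_log(
            pheno_qc["post_bm_mnret"], pheno_qc["cohort"], pheno_qc["exposure_ppm"]
        )
        tukey = phenostats.tukey_hsd(
            np.log(pheno_qc["post_bm_mnret"].to_numpy()), pheno_qc["exposure_ppm"]
        )
        tukey.to_csv(outdir / "tukey.csv", index=False)
        corr = phenostats.correlate_pre_post(
            pheno_qc["pre_pb_mnret"], pheno_qc["post_pb_mnret"], pheno_qc["exposure_ppm"]
        )
        corr.to_csv(outdir / "pre_post_correlation.csv", index=False)
        return gs, anova, corr

    group_summ, anova_p, prepost = _phenostats()
    summary["anova"] = anova_p
    control = group_summ[group_summ["group"] == min(config.doses)].iloc[0]
    summary["control_gm_mnret"] = float(control["geometric_mean"])

    # --- kinship + heritability ------------------------------------------
    @_stage("herit")
    def _herit():
        K = scan.kinship_from_dosages(dosages)
        vc = quantgen.estimate_heritability(
            np.log(pheno_qc["pre_pb_mnret"].to_numpy()), K
        )
        return K, vc

    K, vc_pre = _herit()
    summary["heritability_preexposure"] = float(vc_pre.h2)

    # --- genome scan at the top concentration -----------------------------
    @_stage("scan")
    def _scan():
        top = max(config.doses)
        sel = pheno_qc["exposure_ppm"] == top
        mice_top = pheno_qc.loc[sel, "mouse_id"].tolist()
        y = np.log(pheno_qc.loc[sel, "post_bm_mnret"].to_numpy())
        d_top = dosages.subset_mice(mice_top)
        K_top = scan.kinship_from_dosages(d_top)
        covar = (
            pd.get_dummies(pheno_qc.loc[sel, "cohort"], drop_first=True)
            .to_numpy(float)
            if config.scan_covariate_cohort
            else None
        )
        result = scan.linkage_scan(y, d_top, K=K_top, covariates=covar)
        thr = scan.permutation_threshold(
            y,
            d_top,
            K=K_top,
            covariates=covar,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.seed + 5,
            varcomp=result.varcomp,
        )
        result.threshold, result.alpha = thr, config.alpha
        result.table.to_csv(outdir / "scan.csv", index=False)
        (outdir / "peak.json").write_text(
            dumps_json(
                {
                    "peak": result.peak,
                    "threshold": thr,
                    "alpha": config.alpha,
                    "support_interval": result.support_interval,
                    "variance_explained": result.variance_explained,
                    "variance_explained_raw": result.variance_explained_raw,
                    "n_used": result.n_used,
                }
            )
        )
        return result, d_top, y, mice_top

    scan_result, d_top, y_top, mice_top = _scan()
    summary["scan"] = {
        "peak": scan_result.peak,
        "threshold": scan_result.threshold,
        "significant": bool(scan_result.max_lod > scan_result.threshold),
        "variance_explained": scan_result.variance_explained,
        "variance_explained_raw": scan_result.variance_explained_raw,
        "support_interval": scan_result.support_interval,
        "n_used": scan_result.n_used,
    }

    # --- dominance test at the planted locus ------------------------------
    @_stage("domtest")
    def _domtest():
        locus_chr = config.qtl_chromosome if config.qtl_on else scan_result.peak["chr"]
        locus_pos = (
            config.qtl_position_mb if config.qtl_on else scan_result.peak["pos_Mb"]
        )
        d_focal = d_top.founder_dosage_at(locus_chr, locus_pos, config.qtl_founder)
        coding = quantgen.coding_from_dosage(d_focal)
        return quantgen.dominance_lrt(y_top, coding)

    try:
        dom = _domtest()
        verdict = (
            "dominant"
            if dom["p_general_vs_additive"] < 0.05 <= dom["p_general_vs_dominant"]
            else "additive"
            if dom["p_general_vs_dominant"] < 0.05 <= dom["p_general_vs_additive"]
            else "indeterminate"
        )
        summary["dominance"] = {
            "p_general_vs_additive": dom["p_general_vs_additive"],
            "p_general_vs_dominant": dom["p_general_vs_dominant"],
            "verdict": verdict,
        }
    except StageError as exc:
        logger.warning("dominance test skipped: %s", exc)
        summary["dominance"] = None

    # --- benchmark concentration ------------------------------------------
    @_stage("bmc")
    def _bmc():
        data = bmc_mod.DoseResponseData.from_individual(
            pheno_qc["exposure_ppm"].to_numpy(float),
            pheno_qc["post_bm_mnret"].to_numpy(float),
            distribution=config.bmc_distribution,
        )
        out = {}
        fit_all = bmc_mod.fit_exponential(data)
        out["all_doses"] = {
            "aic": fit_all.aic,
            "lack_of_fit_p": bmc_mod.lack_of_fit_test(fit_all, data),
            "bmcl_rel10": bmc_mod.bmcl_profile(
                fit_all, data, "rel10", level=config.bmc_level
            ),
            "bmcl_one_sd": bmc_mod.bmcl_profile(
                fit_all, data, "one_sd", level=config.bmc_level
            ),
        }
        if config.bmc_drop_high_dose and data.n_groups > 3:
            low = bmc_mod.drop_high_dose(data)
            fit_low = bmc_mod.fit_exponential(low)
            out["low_doses"] = {
                "aic": fit_low.aic,
                "bmcl_rel10": bmc_mod.bmcl_profile(
                    fit_low, low, "rel10", level=config.bmc_level
                ),
                "bmcl_one_sd": bmc_mod.bmcl_profile(
                    fit_low, low, "one_sd", level=config.bmc_level
                ),
            }
        return out

    bmc_out = _bmc()
    bmc_rows = []
    for subset, entry in bmc_out.items():
        for key in ("bmcl_rel10", "bmcl_one_sd"):
            est = entry[key]
            bmc_rows.append(
                {
                    "doses": subset,
                    "aic": entry["aic"],
                    "bmr": est.bmr_type,
                    "bmc": est.bmc,
                    "bmcl": est.bmcl,
                    "status": est.status,
                }
            )
    bmc_table = pd.DataFrame(bmc_rows)
    bmc_table.to_csv(outdir / "bmc_table.csv", index=False)
    summary["bmc"] = {
        row["doses"] + "_" + row["bmr"]: {
            "bmc": row["bmc"],
            "bmcl": row["bmcl"],
            "status": row["status"],
        }
        for row in bmc_rows
    }
    if "all_doses" in bmc_out:
        summary["bmc"]["all_doses_lack_of_fit_p"] = bmc_out["all_doses"][
            "lack_of_fit_p"
        ]

    (outdir / "summary.json").write_text(dumps_json(summary))
    return summary
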