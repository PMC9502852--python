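"""End-to-end analysis pipeline: simulate -> QC -> screens -> MR -> sensitivity.

Each stage writes its tables under the output directory and records itself
in a run manifest (seeds, thresholds, stage status); a stage failure is
captured in the manifest and downstream stages are skipped.  Outputs are a
pure function of (inputs, config, master seed).
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assoc_screen import interaction_scan, outcome_summary_stats, scan_linear
from .genetics_io import apply_qc, genomic_lambda, read_summary_stats, write_summary_stats
from .instruments import SelectionPolicy, harmonize_all, select_instruments
from .mr_core import run_all_methods, scatter_data
from .sensitivity import drop_and_refit, forest_data, leave_one_out
from .synthetic_data import CohortConfig, InstrumentConfig, simulate_two_sample

__all__ = ["run_pipeline", "load_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _log(msg: str) -> None:
    print(f"[{time.strftime('%H:%M:%S')}] {msg}", file=sys.stderr)


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int | None = None) -> dict:
    """Run the full chain and return the manifest (also written as JSON).

    ``config`` keys (all optional):

    - ``simulate``: ``{"cohort": {...CohortConfig}, "instruments": {...InstrumentConfig}}``
    - ``exposure_stats``: path to a summary TSV (alternative to simulation)
    - ``selection``: SelectionPolicy overrides
    - ``outcome_covariates``: covariate list for the outcome regressions
    - ``n_boot``: bootstrap draws for median SEs
    - ``drop``: instrument ids to exclude in the final refit (defaults to
      the leave-one-out influential SNP, if any)
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", seed if seed is not None else 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "exposure_stats_frame"},
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            def runner(*a, **kw):
                t0 = time.time()
                _log(f"stage {name} started")
                try:
                    out = fn(*a, **kw)
                    manifest["stages"][name] = {"status": "ok", "seconds": round(time.time() - t0, 3)}
                    return out
                except Exception as err:
                    manifest["stages"][name] = {"status": "failed", "error": str(err)}
                    raise

            return runner

        return deco

    try:
        # --- inputs -------------------------------------------------------
        sim_cfg = config.get("simulate", {})
        cohort_cfg = CohortConfig(**sim_cfg.get("cohort", {}))
        inst_cfg = InstrumentConfig(**sim_cfg.get("instruments", {}))

        @stage("simulate")
        def _simulate():
            exposure, cohort, truth = simulate_two_sample(inst_cfg, cohort_cfg, seed=seed)
            write_summary_stats(exposure, outdir / "exposure_stats.tsv")
            cohort.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t")
            cohort.genotypes.dosages.to_csv(outdir / "dosages.tsv", sep="\t", na_rep=".")
            truth.to_json(outdir / "ground_truth.json")
            return exposure, cohort

        if "exposure_stats" in config:
            exposure = read_summary_stats(config["exposure_stats"])
            _, cohort = _simulate()  # cohort still simulated; real-cohort input TBD
        else:
            exposure, cohort = _simulate()

        # --- QC -----------------------------------------------------------
        @stage("qc")
        def _qc():
            geno, report = apply_qc(cohort.genotypes)
            report.to_tsv(outdir / "qc_report.tsv")
            report.to_json(outdir / "qc_report.json")
            cohort.genotypes = geno
            return report

        _qc()

        # --- association screens -----------------------------------------
        @stage("assoc")
        def _assoc():
            glucose_scan = scan_linear(cohort, "model5", qvalues=True)
            glucose_scan.to_csv(outdir / "assoc_glucose.tsv", sep="\t", index=False)
            lam = genomic_lambda(pvalues=glucose_scan["pvalue"])
            diet = interaction_scan(cohort, "diet_high")
            diet.to_csv(outdir / "interaction_diet.tsv", sep="\t", index=False)
            sexint = interaction_scan(cohort, "sex")
            sexint.to_csv(outdir / "interaction_sex.tsv", sep="\t", index=False)
            manifest["genomic_lambda"] = lam
            return glucose_scan

        _assoc()

        # --- instrument selection + harmonization -------------------------
        policy = SelectionPolicy(**config.get("selection", {}))

        @stage("select")
        def _select():
            mafs = {
                snp: float(pd.Series(cohort.genotypes.dosages[snp]).mean() / 2.0)
                for snp in cohort.genotypes.snp_ids
            }
            selected, audit = select_instruments(exposure, policy, outcome_mafs=mafs)
            with open(outdir / "selection_audit.jsonl", "w") as fh:
                for rec in audit:
                    fh.write(json.dumps(rec) + "\n")
            return selected

        selected = _select()

        @stage("harmonize")
        def _harmonize():
            outcome = outcome_summary_stats(
                cohort, selected["snp_id"], config.get("outcome_covariates", ())
            )
            write_summary_stats(outcome, outdir / "outcome_stats.tsv")
            insts, audit = harmonize_all(selected, outcome, policy)
            with open(outdir / "harmonization_audit.jsonl", "w") as fh:
                for rec in audit:
                    fh.write(json.dumps(rec) + "\n")
            if insts.empty:
                raise ValueError("no instruments survived harmonization")
            insts.to_csv(outdir / "harmonized_instruments.tsv", sep="\t", index=False)
            return insts

        insts = _harmonize()

        # --- MR battery + sensitivity -------------------------------------
        n_boot = int(config.get("n_boot", 5000))

        @stage("mr")
        def _mr():
            table = run_all_methods(insts, seed=seed, n_boot=n_boot)
            table.to_csv(outdir / "mr_estimates.tsv", sep="\t", index=False)
            scatter_data(insts).to_csv(outdir / "scatter_data.tsv", sep="\t", index=False)
            return table

        _mr()

        @stage("loo")
        def _loo():
            loo = leave_one_out(insts, seed=seed)
            loo.to_csv(outdir / "leave_one_out.tsv", sep="\t", index=False)
            return loo

        loo = _loo()

        @stage("refit")
        def _refit():
            drop = config.get("drop")
            if drop is None:
                drop = list(loo.loc[loo["influential"], "excluded_snp_id"])
            if not drop:
                manifest["stages"]["refit"] = {"status": "skipped", "reason": "no outlier"}
                return None
            result = drop_and_refit(insts, drop, seed=seed, n_boot=n_boot)
            result["after"].to_csv(outdir / "mr_estimates_refit.tsv", sep="\t", index=False)
            forest_data(insts[~insts["snp_id"].isin(drop)]).to_csv(
                outdir / "forest_data.tsv", sep="\t", index=False
            )
            manifest["dropped_instruments"] = drop
            return result

        _refit()
    finally:
        manifest["thresholds"] = asdict(policy) if "policy" in locals() else {}
        if "exclusion_list" in manifest["thresholds"]:
            manifest["thresholds"]["exclusion_list"] = sorted(
                manifest["thresholds"]["exclusion_list"]
            )
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    _log("pipeline complete")
    return manifest
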