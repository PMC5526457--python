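"""End-to-end orchestration of the four analysis components.

From a single config (YAML file or dict) the pipeline runs:

1. variant screen — QQ chi-square statistics of the outcome associations and
   significance counts at the genome-wide and Bonferroni thresholds;
2. per-variant lookup — outcome associations of every variant with
   Bonferroni flags;
3. univariable MR — for each exposure, instrument selection at the
   genome-wide threshold, then IVW / MR-Egger / weighted median with
   Cochran's Q, a Cook's-distance screen and an optional
   leave-subset-out stability analysis;
4. multivariable MR — all variants, joint weighted regression, fitted vs
   observed export and R^2.

An optional gene-region stage runs the correlated-variant score when an LD
matrix is supplied.  Every stage is also callable on its own; the pipeline
only composes them and records a machine-readable run log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diagnostics, gene_region, multivariable, univariable
from .summary_data import (
    AssociationTable,
    HarmonizedSet,
    harmonize,
    read_association_table,
    select_instruments,
)

__all__ = ["DEFAULT_THRESHOLDS", "run_full", "PipelineResult"]

DEFAULT_THRESHOLDS = {
    "genome_wide": 5e-8,
    "family_alpha": 0.05,
    "cooks": 0.15,
    "leave_out_fraction": 0.30,
    "leave_out_iterations": 10_000,
    "n_boot": 1000,
}


@dataclass
class PipelineResult:
    """Bundle of stage outputs plus the run log."""

    qq: pd.DataFrame
    counts: dict
    lookup: pd.DataFrame
    univariable: pd.DataFrame
    heterogeneity: dict
    cooks: dict
    leave_out: dict
    multivariable: pd.DataFrame
    fitted_observed: pd.DataFrame
    r2_percent: float
    region: pd.DataFrame | None
    log: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.qq.to_csv(out / "qq_statistics.tsv", sep="\t", index=False)
        self.lookup.to_csv(out / "variant_lookup.tsv", sep="\t", index=False)
        self.univariable.to_csv(out / "univariable_mr.tsv", sep="\t", index=False)
        self.multivariable.to_csv(out / "multivariable_mr.tsv", sep="\t", index=False)
        self.fitted_observed.to_csv(
            out / "fitted_vs_observed.tsv", sep="\t", index=False
        )
        if self.region is not None:
            self.region.to_csv(out / "gene_region_mr.tsv", sep="\t", index=False)
        extras = {
            "counts": self.counts,
            "heterogeneity": self.heterogeneity,
            "cooks_flagged": self.cooks,
            "leave_out": self.leave_out,
            "r2_percent": self.r2_percent,
        }
        (out / "summary.json").write_text(json.dumps(extras, indent=2, default=str))
        (out / "run_log.json").write_text(json.dumps(self.log, indent=2, default=str))


def _subset_table(table: AssociationTable, ids: list[str]) -> AssociationTable:
    wanted = set(ids)
    return AssociationTable(
        table.trait_name,
        table.trait_scale,
        [r for r in table.records if r.variant_id in wanted],
    )


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_full(
    config,
    exposures: list[AssociationTable] | None = None,
    outcome: AssociationTable | None = None,
) -> PipelineResult:
    """Run the full analysis; tables may be passed directly or via paths.

    Config keys: ``exposures`` (list of {name, path}), ``outcome`` ({path}),
    ``thresholds`` (overrides of :data:`DEFAULT_THRESHOLDS`), ``seed``,
    ``leave_out`` (bool), ``region`` ({ld_path, variants, exposure}).
    """
    cfg = _load_config(config)
    thr = dict(DEFAULT_THRESHOLDS)
    thr.update(cfg.get("thresholds", {}))
    seed = int(cfg.get("seed", 0))
    log: dict = {
        "package": "lipidmr",
        "version": __version__,
        "seed": seed,
        "thresholds": thr,
        "stages": [],
        "notices": [],
    }

    if exposures is None:
        exposures = []
        for spec in cfg["exposures"]:
            tab, rejected = read_association_table(
                spec["path"], trait_name=spec.get("name", Path(spec["path"]).stem)
            )
            exposures.append(tab)
            if rejected:
                log["notices"].append({"table": tab.trait_name, "rejected": rejected})
    if outcome is None:
        outcome, rejected = read_association_table(
            cfg["outcome"]["path"], trait_name="outcome", trait_scale="log-odds"
        )
        if rejected:
            log["notices"].append({"table": "outcome", "rejected": rejected})

    # ---- stage 1+2: screen all variants against the outcome -----------------
    full = harmonize(exposures, outcome)
    n_tests = full.n_variants
    bonf = diagnostics.bonferroni_threshold(thr["family_alpha"], n_tests)
    qq = diagnostics.qq_statistics(full.outcome_log10_p)
    counts = {
        "n_variants": n_tests,
        "bonferroni_threshold": bonf,
        **{
            str(k): v
            for k, v in diagnostics.count_significant(
                full.outcome_log10_p, [bonf, thr["genome_wide"]]
            ).items()
        },
    }
    lookup = pd.DataFrame(
        {
            "variant_id": full.variant_ids,
            "outcome_beta": full.by,
            "outcome_se": full.sy,
            "outcome_log10_p": full.outcome_log10_p,
            "bonferroni_significant": full.outcome_log10_p < np.log10(bonf),
            "genome_wide_significant": full.outcome_log10_p
            < np.log10(thr["genome_wide"]),
        }
    )
    log["stages"].append({"stage": "screen", "n_variants": n_tests, "dropped": full.dropped})

    # ---- stage 3: univariable MR per exposure -------------------------------
    uni_rows = []
    het: dict = {}
    cooks_flagged: dict = {}
    leave_out: dict = {}
    for k, exp in enumerate(exposures):
        instruments = select_instruments(exp, thr["genome_wide"])
        if len(instruments) < 3:
            log["notices"].append(
                {"stage": "univariable", "exposure": exp.trait_name,
                 "skipped": f"only {len(instruments)} instruments"}
            )
            continue
        hs = harmonize([_subset_table(exp, instruments)], outcome)
        estimates = [
            univariable.ivw(hs, effects="random"),
            univariable.egger(hs),
            univariable.weighted_median(hs, n_boot=thr["n_boot"], seed=seed + k),
        ]
        for est in estimates:
            uni_rows.append({"exposure": exp.trait_name, **est.to_dict()})
        q, dfq, pq = diagnostics.cochran_q(hs, estimates[0].theta)
        het[exp.trait_name] = {"Q": q, "df": dfq, "p": pq}
        d, flagged = diagnostics.cooks_distances(hs, "ivw", threshold=thr["cooks"])
        cooks_flagged[exp.trait_name] = [hs.variant_ids[i] for i in flagged]
        if cfg.get("leave_out", False):
            res = diagnostics.leave_subset_out(
                hs,
                fraction=thr["leave_out_fraction"],
                n_iterations=thr["leave_out_iterations"],
                seed=seed + 1000 + k,
            )
            leave_out[exp.trait_name] = res.summary
    log["stages"].append({"stage": "univariable", "n_exposures": len(exposures)})

    # ---- stage 4: multivariable MR ------------------------------------------
    estimates, fitted = multivariable.mvmr_fit(full)
    mv = pd.DataFrame(
        [{"exposure": name, **est.to_dict()}
         for name, est in zip(full.exposure_names, estimates)]
    )
    r2 = multivariable.fitted_observed_r2(full.by, fitted)
    r2_weighted = multivariable.fitted_observed_r2(full.by, fitted, weights=full.sy ** -2)
    fo = pd.DataFrame(
        {"variant_id": full.variant_ids, "expected": fitted, "observed": full.by}
    )
    log["stages"].append(
        {"stage": "multivariable", "r2_percent": r2, "r2_weighted_percent": r2_weighted}
    )

    # ---- optional stage: gene region ----------------------------------------
    region_df = None
    if "region" in cfg and cfg["region"]:
        rcfg = cfg["region"]
        ld = gene_region.read_ld_matrix(rcfg["ld_path"])
        exp_idx = int(rcfg.get("exposure_index", 0))
        kept = gene_region.screen_correlated(
            rcfg.get("variants", ld.variant_ids), ld, rcfg.get("r2_max", 0.2)
        )
        hs = harmonize([_subset_table(exposures[exp_idx], kept)], outcome)
        est = gene_region.correlated_ivw(hs, ld.subset(hs.variant_ids))
        region_df = pd.DataFrame(
            [{"exposure": exposures[exp_idx].trait_name, "variants": ",".join(kept),
              **est.to_dict()}]
        )
        log["stages"].append({"stage": "region", "kept": kept})
    else:
        log["notices"].append({"stage": "region", "skipped": "no LD inputs supplied"})

    result = PipelineResult(
        qq=qq,
        counts=counts,
        lookup=lookup,
        univariable=pd.DataFrame(uni_rows),
        heterogeneity=het,
        cooks=cooks_flagged,
        leave_out=leave_out,
        multivariable=mv,
        fitted_observed=fo,
        r2_percent=r2,
        region=region_df,
        log=log,
    )
    if cfg.get("outdir"):
        result.write(cfg["outdir"])
    return result
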