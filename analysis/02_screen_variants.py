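#!/usr/bin/env python
"""Screen all candidate variants against the outcome.

Two parts:
1. the published association tables — reproduce the significance counts and
   the genome-wide instrument counts from the printed per-variant p-values;
2. the synthetic study from 01 — QQ chi-square statistics of the outcome
   associations and counts at the Bonferroni and genome-wide thresholds.

Writes results/screen/{qq_statistics.tsv,counts.json}.
"""

import json
from pathlib import Path

from lipidmr import datasets
from lipidmr.diagnostics import bonferroni_threshold, count_significant, qq_statistics
from lipidmr.summary_data import harmonize, read_association_table, select_instruments

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "screen"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    # -- published tables ----------------------------------------------------
    t1 = datasets.table1()
    amd = t1[t1["trait"] == "amd"]["log10_p"].tolist()
    bonf = bonferroni_threshold(0.05, 182)
    printed = count_significant(amd, [bonf, 5e-8])
    hdl = datasets.association_table(t1, "hdl")
    hdl_instruments = select_instruments(hdl, 5e-8)
    print(f"printed table: {printed[bonf]} variants below Bonferroni "
          f"({bonf:.2g}), {printed[5e-8]} genome-wide significant")
    print(f"printed HDL column: {len(hdl_instruments)} genome-wide instruments")

    # -- synthetic study -----------------------------------------------------
    exposures = [
        read_association_table(DATA / f"exposure_{k}.tsv",
                               trait_name=f"exposure_{k}")[0]
        for k in (1, 2, 3)
    ]
    outcome = read_association_table(DATA / "outcome.tsv", trait_name="outcome",
                                     trait_scale="log-odds")[0]
    full = harmonize(exposures, outcome)
    bonf_syn = bonferroni_threshold(0.05, full.n_variants)
    counts = count_significant(full.outcome_log10_p, [bonf_syn, 5e-8])
    qq = qq_statistics(full.outcome_log10_p)
    qq.to_csv(OUT / "qq_statistics.tsv", sep="\t", index=False)
    print(f"synthetic study: {full.n_variants} variants harmonized, "
          f"{counts[bonf_syn]} below Bonferroni, {counts[5e-8]} genome-wide; "
          f"top QQ point chi2 = {qq['observed'].iloc[-1]:.1f}")

    (OUT / "counts.json").write_text(json.dumps({
        "printed_bonferroni_count": printed[bonf],
        "printed_genome_wide_count": printed[5e-8],
        "printed_hdl_instruments": hdl_instruments,
        "synthetic_n_variants": full.n_variants,
        "synthetic_bonferroni_count": counts[bonf_syn],
        "synthetic_genome_wide_count": counts[5e-8],
    }, indent=2))


if __name__ == "__main__":
    main()
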