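#!/usr/bin/env python
"""Univariable Mendelian randomization for each synthetic exposure.

For each exposure: select genome-wide significant instruments, harmonize
with the outcome, and estimate the causal effect by IVW (multiplicative
random effects), MR-Egger and the weighted median; attach Cochran's Q, a
Cook's-distance influence screen (threshold 0.15) and a leave-30%-out
stability analysis (10,000 iterations).

Writes results/univariable/{estimates.tsv,diagnostics.json}.
"""

import json
from pathlib import Path

import pandas as pd

from lipidmr.diagnostics import cochran_q, cooks_distances, leave_subset_out
from lipidmr.summary_data import (
    AssociationTable,
    harmonize,
    read_association_table,
    select_instruments,
)
from lipidmr.univariable import egger, ivw, weighted_median

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "univariable"
SEED = 42


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    truth = json.loads((DATA / "truth.json").read_text())
    outcome = read_association_table(DATA / "outcome.tsv", trait_name="outcome",
                                     trait_scale="log-odds")[0]
    rows, diag = [], {}
    for k in (1, 2, 3):
        name = f"exposure_{k}"
        exp = read_association_table(DATA / f"{name}.tsv", trait_name=name)[0]
        ids = select_instruments(exp, 5e-8)
        sub = AssociationTable(name, "sd-units", [exp.get(v) for v in ids])
        hs = harmonize([sub], outcome)
        fits = [
            ivw(hs),
            egger(hs),
            weighted_median(hs, n_boot=1000, seed=SEED + k),
        ]
        for f in fits:
            rows.append({"exposure": name, **f.to_dict()})
        q, df, p = cochran_q(hs, fits[0].theta)
        d, flagged = cooks_distances(hs, "ivw", threshold=0.15)
        lso = leave_subset_out(hs, fraction=0.30, n_iterations=10_000,
                               seed=SEED + 10 + k)
        diag[name] = {
            "n_instruments": hs.n_variants,
            "cochran_q": q, "df": df, "p": p,
            "cooks_flagged": [hs.variant_ids[i] for i in flagged],
            "leave30_positive_share": lso.proportion_positive,
        }
        orr, lo, hi = fits[0].odds_ratio
        print(f"{name} (true theta {truth['theta'][k-1]}): "
              f"IVW OR {orr:.2f} ({lo:.2f}-{hi:.2f}), "
              f"Q/df {q/df:.2f}, {len(flagged)} influential, "
              f"{100*lso.proportion_positive:.1f}% positive after 30% removal")
    pd.DataFrame(rows).to_csv(OUT / "estimates.tsv", sep="\t", index=False)
    (OUT / "diagnostics.json").write_text(json.dumps(diag, indent=2))


if __name__ == "__main__":
    main()
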