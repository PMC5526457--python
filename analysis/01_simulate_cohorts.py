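#!/usr/bin/env python
"""Generate the synthetic two-sample study the downstream analyses consume.

Emulates the design of a lipid-fraction -> disease investigation: three
correlated exposures (LDL-like, HDL-like, triglyceride-like, in SD units)
measured in a large quantitative-trait consortium (n = 188,577) and a binary
outcome (log-odds scale) from a smaller case-control consortium
(n = 33,526), with 185 candidate variants.  Only the second exposure has a
true causal effect (0.2 log odds per SD); balanced per-variant pleiotropy
adds the heterogeneity real lipid instruments show.  A fraction of outcome
records is written allele-flipped to exercise harmonization.

Writes results/data/{exposure_*,outcome}.tsv plus truth.json.
"""

import json
from pathlib import Path

from lipidmr.summary_data import write_association_table
from lipidmr.synthetic import PleiotropyLaw, SyntheticTruth, generate_two_sample

SEED = 20170801
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main():
    truth = SyntheticTruth(
        theta=(0.0, 0.2, 0.0),
        pleiotropy=PleiotropyLaw.balanced(sd=0.01),
        J=185,
        gamma_corr=0.3,
        flip_fraction=0.25,
        seed=SEED,
    )
    exposures, outcome, truth = generate_two_sample(truth)
    OUT.mkdir(parents=True, exist_ok=True)
    for tab in exposures:
        write_association_table(tab, OUT / f"{tab.trait_name}.tsv")
    write_association_table(outcome, OUT / "outcome.tsv")
    (OUT / "truth.json").write_text(json.dumps({
        "theta": list(truth.theta),
        "pleiotropy": {"kind": truth.pleiotropy.kind, "sd": truth.pleiotropy.sd},
        "J": truth.J,
        "gamma_corr": truth.gamma_corr,
        "n_exposure": truth.n_exposure,
        "n_outcome": truth.n_outcome,
        "flip_fraction": truth.flip_fraction,
        "seed": truth.seed,
    }, indent=2))
    print(f"wrote {len(exposures)} exposure tables + outcome ({truth.J} variants) "
          f"to {OUT}")
    print("true direct effects:", truth.theta)


if __name__ == "__main__":
    main()
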