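"""Published per-variant association tables used as worked-example inputs.

Two small lookup tables of printed summary statistics from a large
lipid-fraction / age-related macular degeneration (AMD) investigation:

* ``table1`` — the 9 lipid-related variants associated with AMD risk at a
  Bonferroni-corrected level of significance, with their printed
  beta-coefficients and p-values for LDL-cholesterol, HDL-cholesterol,
  triglycerides (SD units) and AMD risk (log odds).  All variants are
  oriented to the AMD risk-increasing allele.
* ``table2`` — the 12 lead variants in drug-target gene regions (PCSK9,
  HMGCR, LPA, NPC1L1, APOC3, CETP, APOE) with associations for the three
  lipid fractions plus AMD, coronary artery disease (CAD) and Alzheimer's
  disease (ALZ).

P-values are stored as printed strings (some are far below double
underflow); standard errors are not printed and are recovered as
|beta| / |z(p)| when an :class:`AssociationTable` is requested.
"""

from __future__ import annotations

import pandas as pd

from . import pvalues
from .summary_data import AssociationTable, VariantAssociation

__all__ = ["table1", "table2", "association_table"]

_T1_COLUMNS = ["variant_id", "effect_allele", "gene", "trait", "beta", "p"]

_TABLE1 = [
    # variant, effect allele, gene, {trait: (beta, p)}
    ("rs1883025", "C", "ABCA1",
     {"ldl": (0.030, "1e-11"), "hdl": (0.070, "6e-66"),
      "tg": (0.022, "3e-8"), "amd": (0.104, "2e-7")}),
    ("rs653178", "C", "ATXN2",
     {"ldl": (-0.023, "2e-9"), "hdl": (-0.026, "1e-13"),
      "tg": (0.010, "0.004"), "amd": (0.064, "0.0002")}),
    ("rs1532085", "G", "LIPC",
     {"ldl": (-0.003, "0.48"), "hdl": (-0.107, "2e-209"),
      "tg": (-0.031, "5e-20"), "amd": (0.123, "3e-12")}),
    ("rs261342", "C", "LIPC",
     {"ldl": (0.003, "0.69"), "hdl": (-0.107, "6e-71"),
      "tg": (-0.045, "4e-14"), "amd": (0.117, "1e-9")}),
    ("rs9989419", "G", "CETP",
     {"ldl": (-0.028, "8e-13"), "hdl": (0.147, "8e-373"),
      "tg": (-0.024, "3e-12"), "amd": (0.109, "3e-10")}),
    ("rs5880", "G", "CETP",
     {"ldl": (-0.047, "9e-7"), "hdl": (0.307, "4e-257"),
      "tg": (-0.048, "3e-8"), "amd": (0.144, "6e-5")}),
    ("rs6859", "G", "PVRL2",
     {"ldl": (-0.084, "1e-101"), "hdl": (0.018, "1e-6"),
      "tg": (-0.014, "6e-5"), "amd": (0.077, "8e-6")}),
    ("rs103294", "T", "LILRB2/LILRA5",
     {"ldl": (0.007, "0.12"), "hdl": (0.052, "4e-33"),
      "tg": (-0.002, "0.61"), "amd": (0.087, "6e-5")}),
    ("rs4465830", "A", "ZNF335",
     {"ldl": (-0.009, "0.06"), "hdl": (0.060, "4e-42"),
      "tg": (-0.053, "5e-36"), "amd": (0.087, "4e-5")}),
]

_TABLE2 = [
    ("rs12067569", "G", "PCSK9",
     {"ldl": (-0.089, "9e-11"), "hdl": (0.007, "0.33"), "tg": (0.005, "0.52"),
      "amd": (0.020, "0.61"), "cad": (-0.048, "0.04"), "alz": (-0.048, "0.25")}),
    ("rs7703051", "C", "HMGCR",
     {"ldl": (-0.073, "5e-85"), "hdl": (-0.002, "0.56"), "tg": (-0.006, "0.09"),
      "amd": (0.044, "0.010"), "cad": (-0.030, "0.002"), "alz": (-0.015, "0.37")}),
    ("rs2297374", "T", "LPA",
     {"ldl": (-0.032, "6e-18"), "hdl": (0.006, "0.11"), "tg": (-0.009, "0.008"),
      "amd": (0.026, "0.14"), "cad": (-0.038, "8e-5"), "alz": (-0.014, "0.40")}),
    ("rs1564348", "T", "LPA",
     {"ldl": (-0.048, "3e-22"), "hdl": (0.008, "0.10"), "tg": (-0.016, "0.0003"),
      "amd": (0.026, "0.28"), "cad": (-0.030, "0.022"), "alz": (-0.007, "0.74")}),
    ("rs2073547", "A", "NPC1L1",
     {"ldl": (-0.048, "5e-23"), "hdl": (0.005, "0.28"), "tg": (-0.015, "0.0009"),
      "amd": (0.021, "0.32"), "cad": (-0.021, "0.08"), "alz": (0.025, "0.24")}),
    ("rs217386", "A", "NPC1L1",
     {"ldl": (-0.036, "8e-22"), "hdl": (0.001, "0.71"), "tg": (-0.010, "0.003"),
      "amd": (0.031, "0.08"), "cad": (-0.022, "0.029"), "alz": (0.005, "0.77")}),
    ("rs10790162", "A", "APOC3",
     {"ldl": (0.076, "3e-26"), "hdl": (-0.095, "3e-46"), "tg": (0.230, "1e-276"),
      "amd": (0.042, "0.16"), "cad": (0.043, "0.004"), "alz": (0.046, "0.13")}),
    ("rs603446", "C", "APOC3",
     {"ldl": (0.009, "0.013"), "hdl": (-0.002, "0.60"), "tg": (0.050, "2e-50"),
      "amd": (0.006, "0.73"), "cad": (0.015, "0.12"), "alz": (0.032, "0.05")}),
    ("rs9989419", "G", "CETP",
     {"ldl": (-0.028, "8e-13"), "hdl": (0.147, "8e-373"), "tg": (-0.024, "3e-12"),
      "amd": (0.109, "3e-10"), "cad": (-0.009, "0.36"), "alz": (0.008, "0.63")}),
    ("rs5880", "G", "CETP",
     {"ldl": (-0.047, "9e-7"), "hdl": (0.307, "4e-257"), "tg": (-0.048, "3e-8"),
      "amd": (0.144, "6e-5"), "cad": (-0.007, "0.75"), "alz": (0.027, "0.52")}),
    ("rs6859", "G", "APOE",
     {"ldl": (-0.084, "1e-101"), "hdl": (0.018, "1e-6"), "tg": (-0.014, "6e-5"),
      "amd": (0.077, "8e-6"), "cad": (-0.026, "0.010"), "alz": (-0.334, "9e-97")}),
    ("rs7254892", "A", "APOE",
     {"ldl": (-0.485, "8e-365"), "hdl": (0.053, "3e-6"), "tg": (0.124, "4e-31"),
      "amd": (0.063, "0.19"), "cad": (-0.078, "0.009"), "alz": (-0.250, "1e-5")}),
]


def _to_frame(raw) -> pd.DataFrame:
    rows = []
    for vid, ea, gene, traits in raw:
        for trait, (beta, p) in traits.items():
            rows.append(
                dict(
                    variant_id=vid,
                    effect_allele=ea,
                    gene=gene,
                    trait=trait,
                    beta=beta,
                    p=p,
                    log10_p=pvalues.log10_from_string(p),
                )
            )
    return pd.DataFrame(rows)


def table1() -> pd.DataFrame:
    """Long-format frame of the Bonferroni-significant AMD variants."""
    return _to_frame(_TABLE1)


def table2() -> pd.DataFrame:
    """Long-format frame of the drug-target proxy variants."""
    return _to_frame(_TABLE2)


def association_table(frame: pd.DataFrame, trait: str) -> AssociationTable:
    """Build an :class:`AssociationTable` for one trait from a printed table.

    Standard errors are not printed; each is recovered as |beta| / |z(p)|,
    which inverts the consortium's own Wald test.  The other allele is not
    printed either and is stored as the placeholder ``"N"``.
    """
    sub = frame[frame["trait"] == trait]
    scale = "log-odds" if trait in {"amd", "cad", "alz"} else "sd-units"
    records = []
    for _, row in sub.iterrows():
        z = abs(pvalues.z_from_log10p(row["log10_p"]))
        if z == 0 or row["beta"] == 0:
            raise ValueError(f"cannot recover se for {row['variant_id']} ({trait})")
        records.append(
            VariantAssociation(
                variant_id=row["variant_id"],
                effect_allele=row["effect_allele"],
                other_allele="N",
                beta=float(row["beta"]),
                se=float(abs(row["beta"]) / z),
                log10_p=float(row["log10_p"]),
            )
        )
    return AssociationTable(trait, scale, records)
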