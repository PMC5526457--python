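"""Read, validate, harmonize and subset per-variant summary-association tables.

The two-sample Mendelian randomization design consumes nothing but per-variant
summary statistics: for each variant, its association beta, standard error and
p-value with an exposure (SD units for quantitative traits) and with an
outcome (log odds for disease traits), each estimated in a separate study.
Because the studies may report different effect alleles for the same variant,
the tables have to be harmonized to a common allele orientation before any
estimator sees them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import pvalues

__all__ = [
    "VariantAssociation",
    "AssociationTable",
    "HarmonizedSet",
    "read_association_table",
    "write_association_table",
    "harmonize",
    "select_instruments",
    "DEFAULT_COLUMN_MAP",
]

DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "variant_id": "SNP",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "p": "pval",
    "n": "n",
}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is per effect-allele copy (SD units or log odds); ``log10_p``
    holds the two-sided p-value on the log10 scale so values such as 8e-373
    survive double underflow.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    log10_p: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if self.eaf is not None and not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.variant_id}: eaf must be in (0,1), got {self.eaf}")

    @property
    def p(self) -> float:
        return pvalues.p_from_log10(self.log10_p)

    @property
    def maf(self) -> float | None:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def flipped(self) -> "VariantAssociation":
        """The same association reported for the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class AssociationTable:
    """A named collection of :class:`VariantAssociation`, unique by variant."""

    trait_name: str
    trait_scale: str  # "sd-units" or "log-odds"
    records: list[VariantAssociation] = field(default_factory=list)

    def __post_init__(self):
        self._index = {}
        for rec in self.records:
            if rec.variant_id in self._index:
                raise ValueError(f"duplicate variant_id {rec.variant_id!r} in {self.trait_name}")
            self._index[rec.variant_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def get(self, variant_id: str) -> VariantAssociation:
        return self._index[variant_id]

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                dict(
                    variant_id=r.variant_id,
                    effect_allele=r.effect_allele,
                    other_allele=r.other_allele,
                    eaf=np.nan if r.eaf is None else r.eaf,
                    beta=r.beta,
                    se=r.se,
                    log10_p=r.log10_p,
                    n=np.nan if r.n is None else r.n,
                )
            )
        return pd.DataFrame(rows)


def read_association_table(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "trait",
    trait_scale: str = "sd-units",
) -> tuple[AssociationTable, list[tuple[str, str]]]:
    """Read a tab-delimited summary-statistics file.

    Returns the table plus a list of ``(variant_id, reason)`` for rows
    rejected during validation (e.g. non-positive SE).  P-values are parsed
    from their decimal string representation so sub-underflow values survive.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["variant_id", "effect_allele", "other_allele", "beta", "se", "p"]
    for key in required:
        if cmap[key] not in df.columns:
            raise ValueError(f"missing mapped column {cmap[key]!r} for field {key!r}")

    records: list[VariantAssociation] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        vid = str(row[cmap["variant_id"]])
        if vid in seen:
            raise ValueError(f"duplicate variant_id {vid!r}")
        seen.add(vid)
        se = float(row[cmap["se"]])
        if se <= 0:
            rejected.append((vid, "nonpositive SE"))
            continue
        try:
            log10p = pvalues.log10_from_string(str(row[cmap["p"]]))
        except ValueError:
            rejected.append((vid, "unparseable p-value"))
            continue
        eaf_col = cmap.get("eaf")
        eaf = None
        if eaf_col in df.columns and not pd.isna(row[eaf_col]):
            eaf = float(row[eaf_col])
        n_col = cmap.get("n")
        n = None
        if n_col in df.columns and not pd.isna(row[n_col]):
            n = float(row[n_col])
        records.append(
            VariantAssociation(
                variant_id=vid,
                effect_allele=str(row[cmap["effect_allele"]]).upper(),
                other_allele=str(row[cmap["other_allele"]]).upper(),
                beta=float(row[cmap["beta"]]),
                se=se,
                log10_p=log10p,
                eaf=eaf,
                n=n,
            )
        )
    return AssociationTable(trait_name, trait_scale, records), rejected


def write_association_table(table: AssociationTable, path) -> None:
    """Write the dialect :func:`read_association_table` consumes."""
    df = table.to_dataframe()
    # render p back to a decimal string that survives round-trip
    def _fmt_p(log10p: float) -> str:
        if log10p == 0.0:
            return "1"
        exp = math.floor(log10p)
        mant = 10.0 ** (log10p - exp)
        return f"{mant:.6f}e{exp:d}"

    out = pd.DataFrame(
        {
            "SNP": df["variant_id"],
            "effect_allele": df["effect_allele"],
            "other_allele": df["other_allele"],
            "eaf": df["eaf"],
            "beta": df["beta"],
            "se": df["se"],
            "pval": [_fmt_p(v) for v in df["log10_p"]],
            "n": df["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


@dataclass
class HarmonizedSet:
    """Exposure and outcome associations aligned to a common effect allele.

    ``bx``/``sx`` are (J variants x K exposures); ``by``/``sy`` are length J.
    ``orientation_flags[j]`` is True when variant j's outcome record (and any
    non-reference exposure record) was allele-flipped during harmonization.
    """

    variant_ids: list[str]
    exposure_names: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    orientation_flags: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)
    outcome_log10_p: np.ndarray | None = None

    def __post_init__(self):
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        if self.bx.shape[0] == 1 and len(self.variant_ids) != 1:
            self.bx = self.bx.T
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        if self.sx.shape[0] == 1 and len(self.variant_ids) != 1:
            self.sx = self.sx.T
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        self.orientation_flags = np.asarray(self.orientation_flags, dtype=bool)
        J = len(self.variant_ids)
        assert self.bx.shape[0] == J and self.by.shape == (J,) and self.sy.shape == (J,)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_exposures(self) -> int:
        return self.bx.shape[1]

    def single(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(bx, sx, by, sy) vectors for a single-exposure set."""
        if self.n_exposures != 1:
            raise ValueError("set has more than one exposure")
        return self.bx[:, 0], self.sx[:, 0], self.by, self.sy

    def subset(self, index) -> "HarmonizedSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HarmonizedSet(
            variant_ids=[self.variant_ids[i] for i in index],
            exposure_names=self.exposure_names,
            bx=self.bx[index],
            sx=self.sx[index],
            by=self.by[index],
            sy=self.sy[index],
            orientation_flags=self.orientation_flags[index],
            dropped=list(self.dropped),
            outcome_log10_p=None
            if self.outcome_log10_p is None
            else self.outcome_log10_p[index],
        )


def _reconcile(ref: VariantAssociation, rec: VariantAssociation):
    """Align ``rec`` to ``ref``'s effect allele; returns (record, flipped) or None."""
    if (rec.effect_allele, rec.other_allele) == (ref.effect_allele, ref.other_allele):
        return rec, False
    if (rec.other_allele, rec.effect_allele) == (ref.effect_allele, ref.other_allele):
        return rec.flipped(), True
    return None


def harmonize(
    exposures: Sequence[AssociationTable],
    outcome: AssociationTable,
    palindromic_policy: str = "frequency",
    palindromic_maf_max: float = 0.42,
) -> HarmonizedSet:
    """Align exposure and outcome tables to the first exposure's effect allele.

    Variants missing from any table are dropped with reason
    ``"missing in <trait>"``; irreconcilable allele pairs are dropped, never
    silently kept.  Palindromic variants (A/T, C/G) are handled per policy:
    ``"drop"`` removes them, ``"keep"`` trusts the reported alleles, and the
    default ``"frequency"`` drops those with maf > ``palindromic_maf_max``
    and aligns the remainder by effect-allele frequency agreement.
    """
    if not exposures:
        raise ValueError("at least one exposure table required")
    if palindromic_policy not in {"drop", "keep", "frequency"}:
        raise ValueError(f"unknown palindromic policy {palindromic_policy!r}")

    ref_table = exposures[0]
    others = list(exposures[1:]) + [outcome]
    all_tables = list(exposures) + [outcome]

    dropped: list[tuple[str, str]] = []
    ids: list[str] = []
    bx_rows, sx_rows, by_rows, sy_rows, flags, out_logp = [], [], [], [], [], []

    intersection = [
        vid for vid in ref_table.variant_ids if all(vid in t for t in others)
    ]
    # record the variants excluded for absence from some table
    for vid in ref_table.variant_ids:
        for t in others:
            if vid not in t:
                dropped.append((vid, f"missing in {t.trait_name}"))
                break
    if not intersection and not dropped:
        raise ValueError("empty variant intersection between tables")
    if not intersection:
        raise ValueError(
            "empty variant intersection between tables "
            f"({len(dropped)} variants missing from some table)"
        )

    for vid in intersection:
        ref = ref_table.get(vid)
        palindromic = _is_palindromic(ref.effect_allele, ref.other_allele)
        if palindromic and palindromic_policy == "drop":
            dropped.append((vid, "palindromic"))
            continue
        if palindromic and palindromic_policy == "frequency":
            mafs = [t.get(vid).maf for t in all_tables]
            if any(m is None for m in mafs):
                dropped.append((vid, "palindromic, eaf missing"))
                continue
            if max(m for m in mafs if m is not None) > palindromic_maf_max:
                dropped.append((vid, f"palindromic, maf > {palindromic_maf_max}"))
                continue

        aligned = []
        flip_any = False
        ok = True
        for t in others:
            res = _reconcile(ref, t.get(vid))
            if res is None:
                dropped.append((vid, f"allele mismatch in {t.trait_name}"))
                ok = False
                break
            rec, flipped = res
            if palindromic and palindromic_policy == "frequency":
                # palindromic alleles match both ways; trust frequency side
                if rec.eaf is None or ref.eaf is None:
                    dropped.append((vid, "palindromic, eaf missing"))
                    ok = False
                    break
                if (rec.eaf < 0.5) != (ref.eaf < 0.5):
                    rec = rec.flipped()
                    flipped = not flipped
                    # after a frequency flip alleles read as complement strand
            aligned.append(rec)
            flip_any = flip_any or flipped
        if not ok:
            continue

        exp_recs = [ref] + aligned[: len(exposures) - 1]
        out_rec = aligned[-1]
        ids.append(vid)
        bx_rows.append([r.beta for r in exp_recs])
        sx_rows.append([r.se for r in exp_recs])
        by_rows.append(out_rec.beta)
        sy_rows.append(out_rec.se)
        out_logp.append(out_rec.log10_p)
        flags.append(flip_any)

    if not ids:
        raise ValueError("no variants survived harmonization")
    return HarmonizedSet(
        variant_ids=ids,
        exposure_names=[t.trait_name for t in exposures],
        bx=np.array(bx_rows, dtype=float),
        sx=np.array(sx_rows, dtype=float),
        by=np.array(by_rows, dtype=float),
        sy=np.array(sy_rows, dtype=float),
        orientation_flags=np.array(flags, dtype=bool),
        dropped=dropped,
        outcome_log10_p=np.array(out_logp, dtype=float),
    )


def select_instruments(table: AssociationTable, threshold: float) -> list[str]:
    """Variant IDs with p strictly below ``threshold``, in input order.

    The comparison runs on the log10 representation, so genome-wide screens
    behave correctly for p-values below double underflow.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    log10_thr = math.log10(threshold)
    return [r.variant_id for r in table.records if r.log10_p < log10_thr]
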