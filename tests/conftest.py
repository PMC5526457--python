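import numpy as np
import pytest

from lipidmr import pvalues
from lipidmr.summary_data import AssociationTable, VariantAssociation


def make_table(
    name,
    betas,
    ses,
    alleles=None,
    eafs=None,
    ids=None,
    scale="sd-units",
    log10_ps=None,
):
    """Build an AssociationTable from parallel arrays (test helper)."""
    J = len(betas)
    ids = ids or [f"rs{j+1}" for j in range(J)]
    alleles = alleles or [("A", "G")] * J
    records = []
    for j in range(J):
        lp = (
            log10_ps[j]
            if log10_ps is not None
            else pvalues.log10p_from_z(betas[j] / ses[j])
        )
        records.append(
            VariantAssociation(
                variant_id=ids[j],
                effect_allele=alleles[j][0],
                other_allele=alleles[j][1],
                beta=float(betas[j]),
                se=float(ses[j]),
                log10_p=lp,
                eaf=None if eafs is None else float(eafs[j]),
            )
        )
    return AssociationTable(name, scale, records)


@pytest.fixture
def ivw_toy():
    """Three-variant toy with known hand-computed IVW solution."""
    bx = np.array([0.1, 0.2, 0.3])
    by = np.array([0.05, 0.08, 0.18])
    sy = np.full(3, 0.02)
    sx = np.full(3, 0.01)
    return bx, sx, by, sy


@pytest.fixture
def random_toys():
    """100 random (bx, sx, by, sy) toys for oracle-equivalence checks."""
    rng = np.random.default_rng(2024)
    toys = []
    for _ in range(100):
        J = rng.integers(4, 30)
        bx = rng.normal(0.1, 0.05, J)
        bx[bx == 0] = 0.01
        sx = rng.uniform(0.005, 0.02, J)
        by = rng.normal(0.05, 0.03, J)
        sy = rng.uniform(0.005, 0.05, J)
        toys.append((bx, sx, by, sy))
    return toys
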