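import numpy as np
import pandas as pd
import pytest

from qcdrift import DriftSimConfig, FeatureTable, dedup_boundary_qcs, simulate_dataset


def make_table(roles, values, batches=None, orders=None, ids=None, metabolites=None):
    """Build a small FeatureTable from plain lists/arrays."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = ids or [f"s{i}" for i in range(n)]
    orders = list(orders) if orders is not None else list(range(1, n + 1))
    batches = list(batches) if batches is not None else ["b1"] * n
    metabolites = metabolites or [f"met{j}" for j in range(m)]
    samples = pd.DataFrame(
        {"injection_order": orders, "batch": batches, "role": list(roles)},
        index=pd.Index(ids, name="sample_id"),
    )
    inten = pd.DataFrame(values, index=samples.index, columns=metabolites)
    return FeatureTable(inten, samples)


@pytest.fixture
def small_sim():
    """Scaled-down simulated run: 2 batches, 6 QCs/batch after dedup."""
    def build(seed=0, **overrides):
        cfg = DriftSimConfig(
            n_batches=2, n_bio_per_batch=25, qc_every=5,
            n_metabolites=12, n_blocks=3, seed=seed, **overrides,
        )
        table, truth = simulate_dataset(cfg)
        return dedup_boundary_qcs(table), truth
    return build


def qc_rsds(table):
    """Per-metabolite QC RSD, NaN where undefined."""
    from qcdrift.metrics import _safe, rsd

    qc = table.qc_intensities()
    return np.array([_safe(rsd, qc[c]) for c in table.metabolite_ids])
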