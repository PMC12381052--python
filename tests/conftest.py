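"""Shared fixtures: one synthetic cohort, prepared once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import periomics as po


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (seed 1) with all planted signal."""
    cfg = po.SimulationConfig(seed=1)
    dna, rna, ann, tensor, pathways, meta, truth = po.simulate_cohort(cfg)
    return {"cfg": cfg, "dna": dna, "rna": rna, "ann": ann, "tensor": tensor,
            "pathways": pathways, "meta": meta, "truth": truth}


def prep(table, min_rel=0.001):
    """filter -> relative -> log1p -> Bray-Curtis."""
    filt, _ = po.prevalence_filter(table, min_rel=min_rel)
    logged = po.log1p_transform(po.to_relative(filt))
    return logged, po.bray_curtis(logged)


@pytest.fixture(scope="session")
def species_block(cohort):
    logged, dm = prep(cohort["dna"])
    model = po.cap_fit(dm, cohort["meta"].diagnosis(logged.sample_ids))
    return logged, dm, model


@pytest.fixture(scope="session")
def ec_block(cohort):
    ec4 = po.aggregate_to_ec(cohort["rna"], cohort["ann"], level=4)
    logged, dm = prep(ec4)
    model = po.cap_fit(dm, cohort["meta"].diagnosis(logged.sample_ids))
    return logged, dm, model


def toy_table(values, sample_ids=None, feature_ids=None, scale="counts",
              feature_meta=None):
    values = np.asarray(values, dtype=float)
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(values.shape[0])]
    feature_ids = feature_ids or [f"f{j + 1}" for j in range(values.shape[1])]
    return po.FeatureTable(pd.DataFrame(values, index=sample_ids,
                                        columns=feature_ids),
                           scale=scale, feature_meta=feature_meta)
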