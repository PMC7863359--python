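"""Shared fixtures: small synthetic cohorts and pre-trained models.

Everything is generated programmatically at test time; session scope keeps
the slower fixtures (assembled cohorts, trained networks) to one build each.
"""

from __future__ import annotations

import pandas as pd
import pytest

import sigsurvnet as ssn


def clinical_table(ds):
    """Processed clinical frame for an in-memory generated dataset."""
    clin = ds.clinical.set_index("sample_id")
    out = pd.DataFrame(index=clin.index)
    out["age"] = clin["age"].astype(float)
    out["gender_code"] = (clin["gender"] == "male").astype(int)
    out["stage_ordinal"] = clin["stage"].str.extract(r"Stage (\w+)")[0].map(
        {"I": 1, "II": 2, "III": 3, "IV": 4}).astype(float)
    out["stage_unknown"] = False
    out["vital_status"] = (clin["vital_status"] == "deceased").astype(int)
    out["survival_days"] = clin["survival_days"].astype(int)
    return out


def assemble_in_memory(ds):
    """Assemble a generated dataset without touching the filesystem."""
    return ssn.assemble_dataset(ds.expression, ds.copy_number,
                                clinical_table(ds), ds.pathways)


def assemble_generated(ds):
    """Run a generated in-memory dataset through the file loaders."""
    return ssn.assemble_dataset(
        ssn.load_matrix(ds.paths["expression"], "continuous"),
        ssn.load_matrix(ds.paths["copy_number"], "integer"),
        ssn.load_clinical(ds.paths["clinical"]),
        ssn.load_pathways(ds.paths["pathways"]),
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A compact cohort (160 samples, 10 pathways) with strong signal."""
    spec = ssn.SyntheticSpec(
        n_samples=160, n_pathways=10, genes_per_pathway=12,
        causal_pathways=(1, 4, 7), effect_sizes=(300.0, -300.0, 300.0),
        seed=11,
    )
    out = tmp_path_factory.mktemp("small_cohort")
    ds = ssn.generate(spec, out_dir=out)
    data, mask = assemble_generated(ds)
    return {"spec": spec, "generated": ds, "data": data, "mask": mask}


@pytest.fixture(scope="session")
def small_split(small_cohort):
    n = small_cohort["data"].n_samples
    return ssn.split_samples(n, 0.8, seed=5)


@pytest.fixture(scope="session")
def trained_small(small_cohort, small_split):
    """A quickly trained network on the small cohort (shared, read-only)."""
    est = ssn.DeepSigSurvNet(mask=small_cohort["mask"], epochs=8, random_state=5)
    ssn.train(est, small_cohort["data"], small_split)
    return est


@pytest.fixture(scope="session")
def strong_cohort(tmp_path_factory):
    """The default-scale cohort (400 samples, 46 pathways, 5 causal)."""
    out = tmp_path_factory.mktemp("strong_cohort")
    ds = ssn.generate(ssn.SyntheticSpec(seed=23), out_dir=out)
    data, mask = assemble_generated(ds)
    return {"generated": ds, "data": data, "mask": mask}
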