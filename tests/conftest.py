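from __future__ import annotations

import numpy as np
import pytest

from nsrscan.model import GeneModel
from nsrscan.pipeline import PipelineConfig, run_pipeline
from nsrscan.simulate import SimConfig, emit_dataset, simulate


def make_gene(gene_id, start, end, scaffold="scf0", strand="+", **kw):
    return GeneModel(gene_id, scaffold, start, end, strand, **kw)


@pytest.fixture(scope="session")
def rng():
    return np.random.Generator(np.random.PCG64(1234))


# configuration used for the parameter-recovery acceptance tests: three
# interior hotspot tracts that end up >= 600 kb after recurrent events
B2_CONFIG = SimConfig(
    seed=11,
    genes_per_scaffold=2000,
    n_nahr_events=75,
    te_insertions=400,
    hotspot_fraction=0.40,
    n_hotspots=3,
    nahr_hotspot_bias=200.0,
    dup_ks=0.5,
    dup_ka=0.15,
)


@pytest.fixture(scope="session")
def b2_run(tmp_path_factory):
    """Simulate the recovery-scale dataset once and run the full pipeline."""
    data_dir = tmp_path_factory.mktemp("b2_data")
    out_dir = tmp_path_factory.mktemp("b2_out")
    result = simulate(B2_CONFIG)
    emit_dataset(result, data_dir)
    pipeline_out = run_pipeline(
        PipelineConfig(data_dir=str(data_dir), out_dir=str(out_dir))
    )
    return {
        "sim": result,
        "pipeline": pipeline_out,
        "data_dir": data_dir,
        "out_dir": out_dir,
    }


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A quick, small simulated dataset for io/pipeline smoke tests."""
    data_dir = tmp_path_factory.mktemp("small_data")
    cfg = SimConfig(
        seed=5, genes_per_scaffold=120, n_nahr_events=5, te_insertions=40,
        hotspot_fraction=0.2, n_hotspots=1,
    )
    result = simulate(cfg)
    paths = emit_dataset(result, data_dir)
    return {"sim": result, "paths": paths, "data_dir": data_dir, "config": cfg}
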