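import pandas as pd
import pytest

from apaswitch import pas_calling, pipeline, simdata


def events_frame(samples: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Stack per-sample read tables into one event table."""
    return pd.concat(
        [df.assign(sample=sid) for sid, df in samples.items()], ignore_index=True
    )[pas_calling.EVENT_COLUMNS]


@pytest.fixture(scope="session")
def default_sim():
    """Generator defaults: 200 genes, 1-3 PASs each, no planted effects."""
    cfg = simdata.SimConfig(seed=42)
    genome, ann, truth, samples, sheet = simdata.simulate_dataset(cfg)
    return {
        "cfg": cfg,
        "genome": genome,
        "annotation": ann,
        "truth": truth,
        "samples": samples,
        "sheet": sheet,
        "events": events_frame(samples),
    }


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Full pipeline stages on the default synthetic dataset."""
    d = default_sim
    return pipeline.analyze_dataset(d["genome"], d["annotation"], d["events"], d["sheet"])


@pytest.fixture(scope="session")
def switch_sim():
    """50 planted class-I and 50 class-II switch genes plus 100 null APA
    genes (usage shift 0.3, gene mean 200 reads/sample, 3 replicates)."""
    cfg = simdata.SimConfig(
        n_genes=200,
        pas_per_gene_range=(2, 3),
        switch_fraction=0.5,
        switch_delta=0.3,
        gene_mean=200.0,
        seed=5,
    )
    genome, ann, truth, samples, sheet = simdata.simulate_dataset(cfg)
    return {
        "cfg": cfg,
        "genome": genome,
        "annotation": ann,
        "truth": truth,
        "samples": samples,
        "sheet": sheet,
        "events": events_frame(samples),
    }


@pytest.fixture(scope="session")
def switch_analysis(switch_sim):
    d = switch_sim
    return pipeline.analyze_dataset(d["genome"], d["annotation"], d["events"], d["sheet"])
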