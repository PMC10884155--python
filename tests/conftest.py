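import numpy as np
import pandas as pd
import pytest

from epiprime import pipeline, synth


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 1), shared across tests."""
    return synth.simulate(synth.SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study (seed 1)."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = pipeline.PipelineConfig(seed=1)
    manifest = pipeline.run_pipeline(cfg, outdir)
    return outdir, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def match_truth_labels(calls: pd.DataFrame, truth_regions: pd.DataFrame):
    """Align openness calls with planted regions by exact interval.

    Decoy regions map to the 'unassigned' prediction target.  Returns
    (truth labels, predicted labels) for the matched peaks.
    """
    key = lambda df: list(zip(df["chrom"], df["start"], df["end"]))
    tmap = dict(zip(key(truth_regions), truth_regions["cls"]))
    truth, pred = [], []
    for k, lab in zip(key(calls), calls["label"]):
        cls = tmap.get(k)
        if cls is None:
            continue
        truth.append("unassigned" if cls == "decoy" else cls)
        pred.append(lab)
    return truth, pred
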