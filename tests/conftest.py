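import numpy as np
import pandas as pd
import pytest

from diseasome.datasets import ExpressionDataset


def make_dataset(values, n_case, disease_id="D", gene_ids=None):
    """Build an ExpressionDataset from an array; first n_case columns are cases."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = gene_ids or [f"G{i:04d}" for i in range(1, n_genes + 1)]
    samples = [f"s{i}" for i in range(1, n_samples + 1)]
    groups = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
    frame = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionDataset(disease_id, frame, groups)


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples (2 case / 2 control) on the log2 scale."""
    return make_dataset(
        [[5.0, 5.2, 3.0, 3.1], [2.0, 2.1, 2.0, 2.2], [1.0, 1.5, 4.0, 4.2]],
        n_case=2,
    )


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """The packaged demo study: fixtures on disk plus a completed pipeline run."""
    from diseasome.pipeline import PipelineConfig, run_pipeline
    from diseasome.simulate import write_fixtures

    root = tmp_path_factory.mktemp("demo")
    info = write_fixtures(root, seed=11)
    cfg = PipelineConfig.from_yaml(info["config"])
    manifest = run_pipeline(cfg)
    return {"info": info, "config": cfg, "manifest": manifest, "root": root}
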