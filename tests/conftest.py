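import numpy as np
import pytest

from rdikit import FeatureCountTable, RDIParameters, geometric_baseline


@pytest.fixture()
def airr_tsv(tmp_path):
    """A tiny rearrangement TSV: 2 repertoires, mixed call quality."""
    path = tmp_path / "rearrangements.tsv"
    rows = [
        ("sample", "v_call", "j_call"),
        ("donor1", "IGHV1-2*02", "IGHJ4*02"),
        ("donor1", "IGHV1-2*04", "IGHJ4*02"),
        ("donor1", "IGHV3-23*01", "IGHJ6*01"),
        ("donor1", "IGHV1-2*02,IGHV1-2*04", "IGHJ4*02"),
        ("donor2", "IGHV3-23*01", "IGHJ6*01"),
        ("donor2", "IGHV1-2*02,IGHV3-23*01", "IGHJ4*02"),
        ("donor2", "", "IGHJ4*02"),
    ]
    path.write_text("\n".join("\t".join(r) for r in rows) + "\n")
    return path


@pytest.fixture()
def one_hot_table():
    """Two repertoires concentrated on disjoint single features."""
    return FeatureCountTable(
        repertoire_ids=["a", "b"],
        feature_labels=["V1", "V2"],
        counts=np.array([[20, 0], [0, 20]]),
    )


@pytest.fixture()
def small_table():
    rng = np.random.default_rng(42)
    base = geometric_baseline(12)
    counts = np.vstack(
        [rng.multinomial(n, base.probs) for n in (400, 350, 520, 610)]
    )
    return FeatureCountTable(
        repertoire_ids=[f"r{i}" for i in range(4)],
        feature_labels=list(base.labels),
        counts=counts,
    )


@pytest.fixture(scope="session")
def fast_params():
    return RDIParameters(n_iterations=20, seed=7)
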