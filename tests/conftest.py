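import pytest

import hydsite as h


@pytest.fixture()
def write_fasta(tmp_path):
    """Write entries [(id, seq), ...] to a temp FASTA file and return its path."""

    def _write(entries, name="input.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in entries:
                fh.write(f">{rec_id}\n{seq}\n")
        return path

    return _write


@pytest.fixture(scope="session")
def bench_xi4():
    """Small strongly-coupled benchmark (xi=4, 40/40) shared across tests."""
    spec = h.GeneratorSpec(xi=4, seed=7, coupling_strength=1.0)
    return h.generate_benchmark(spec, 40, 40)


@pytest.fixture(scope="session")
def model_xi4(bench_xi4):
    return h.fit_model(bench_xi4)


@pytest.fixture(scope="session")
def clf_xi4(bench_xi4):
    windows = [s.window for s in bench_xi4.positives + bench_xi4.negatives]
    labels = [1] * len(bench_xi4.positives) + [0] * len(bench_xi4.negatives)
    clf = h.SequenceCoupledSiteClassifier(n_trees=50, random_state=0)
    return clf.fit(windows, labels)
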