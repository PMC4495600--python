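import numpy as np
import pytest

from sumovar import features, model, seqio, synthetic


@pytest.fixture(scope="session")
def synth_proteome():
    """A mid-sized synthetic proteome with planted consensus-motif sites."""
    cfg = synthetic.SynthConfig(n_proteins=60, n_positive_sites=150,
                                motif_fidelity=0.9, seed=11)
    records, sites, truth = synthetic.generate_proteome(cfg)
    return cfg, records, sites, truth


@pytest.fixture(scope="session")
def synth_matrix(synth_proteome):
    cfg, records, sites, _ = synth_proteome
    fragments = seqio.build_dataset(records, sites, flank=cfg.flank)
    encoder = features.EncoderConfig(families=("physchem", "cksaap"),
                                     k_set=(0, 1, 2))
    matrix = features.assemble(fragments, encoder)
    return encoder, fragments, matrix


@pytest.fixture(scope="session")
def small_ensemble(synth_matrix):
    """A 3-member ensemble trained on the session proteome (sequence-only)."""
    encoder, _, matrix = synth_matrix
    pos_X = matrix.X[matrix.y == 1].to_numpy()
    neg_X = matrix.X[matrix.y == -1].to_numpy()
    config = model.TrainConfig(seed=11, n_negative_sets=3, repeats=1)
    ensemble = model.train_ensemble(pos_X, neg_X, config,
                                    feature_names=list(matrix.X.columns))
    return encoder, ensemble


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
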