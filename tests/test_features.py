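import numpy as np
import pandas as pd
import pytest

from sumovar import features, seqio, synthetic
from sumovar.features import (EncoderConfig, FeatureMatrix, PropertyTable,
                              PSSMProfile, StructureAnnotation)
from sumovar.seqio import Fragment, ValidationError


def frag(residues, pos=None, pid="P"):
    center = len(residues) // 2 + 1
    return Fragment(pid, pos if pos is not None else center, residues)


class TestPhyschem:
    def test_all_x_is_zero(self):
        table = PropertyTable.default()
        v = features.encode_physchem(frag("X" * 21), table)
        assert not v.any()
        assert len(v) == 21 * len(table)

    def test_constant_fragment_single_property(self):
        table = PropertyTable({aa: [3.5 if aa == "A" else 0.0]
                               for aa in seqio.AMINO_ACIDS}, ["p"])
        v = features.encode_physchem(frag("A" * 21), table)
        assert np.allclose(v, 3.5)

    def test_lookup_oracle(self, rng):
        table = PropertyTable.default()
        s = "".join(rng.choice(list(seqio.AMINO_ACIDS), 21))
        v = features.encode_physchem(frag(s), table)
        expected = [table.vector(aa)[j] for aa in s for j in range(len(table))]
        assert np.allclose(v, expected)

    def test_default_table_is_standardized(self):
        table = PropertyTable.default()
        arr = np.array([table.vector(aa) for aa in seqio.AMINO_ACIDS])
        assert np.allclose(arr.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(arr.std(axis=0), 1, atol=1e-12)


def _brute_force_cksaap(s, k):
    counts = {}
    for i in range(len(s)):
        j = i + k + 1
        if j < len(s) and s[i] != "X" and s[j] != "X":
            counts[s[i] + s[j]] = counts.get(s[i] + s[j], 0) + 1
    return {p: c / (len(s) - k - 1) for p, c in counts.items()}


class TestCksaap:
    def test_poly_a_k0(self):
        v = features.encode_cksaap(frag("A" * 21), k_set=(0,))
        names = features.cksaap_feature_names((0,))
        assert v[names.index("cksaap|k0|AA")] == pytest.approx(1.0)
        assert v.sum() == pytest.approx(1.0)

    def test_single_residue_no_pairs(self):
        v = features.encode_cksaap(frag("X" * 10 + "K" + "X" * 10))
        assert not v.any()

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            features.encode_cksaap(frag("A" * 21), k_set=(20,))

    def test_matches_enumeration_oracle(self, rng):
        s = "".join(rng.choice(list(seqio.AMINO_ACIDS + "X"), 21))
        k_set = (0, 1, 2)
        v = features.encode_cksaap(frag(s), k_set=k_set)
        names = features.cksaap_feature_names(k_set)
        for k in k_set:
            expected = _brute_force_cksaap(s, k)
            for pair, val in expected.items():
                assert v[names.index(f"cksaap|k{k}|{pair}")] == pytest.approx(val)
            block = [x for n, x in zip(names, v) if n.startswith(f"cksaap|k{k}|")]
            assert sum(block) == pytest.approx(sum(expected.values()))


class TestStructureEncoders:
    def test_all_helix(self):
        ann = StructureAnnotation("P", np.zeros(40), "H" * 40)
        v = features.encode_ss(frag("A" * 21, pos=20), ann)
        names = features.ss_feature_names(10)
        h = [x for n, x in zip(names, v) if n.endswith("|H")]
        assert h == [1.0] * 21

    def test_constant_asa_mean(self):
        ann = StructureAnnotation("P", np.full(40, 7.25), "C" * 40)
        v = features.encode_aasa(frag("A" * 21, pos=20), ann)
        assert v[-1] == pytest.approx(7.25)

    def test_padding_positions_zero(self):
        ann = StructureAnnotation("P", np.full(15, 3.0), "H" * 15)
        v = features.encode_ss(frag("A" * 21, pos=3), ann)
        # offsets -10..-3 fall before the sequence start
        assert not v[: 3 * 8].any()

    def test_fabricated_round_trip(self, tmp_path, rng):
        rec = seqio.ProteinRecord("P1", "".join(rng.choice(list("ACDK"), 50)))
        profiles, structures = synthetic.fabricate_profiles([rec], tmp_path, seed=5)
        back = features.read_structure(tmp_path / "structure" / "P1.tsv", "P1")
        assert np.allclose(back.asa, structures["P1"].asa)
        assert back.ss == structures["P1"].ss


class TestPssm:
    def test_zero_profile(self):
        prof = PSSMProfile("P", np.zeros((40, 20)))
        assert not features.encode_pssm(frag("A" * 21, pos=20), prof).any()

    def test_interior_window_equals_slice(self, rng):
        scores = rng.normal(size=(60, 20))
        prof = PSSMProfile("P", scores)
        v = features.encode_pssm(frag("A" * 21, pos=30), prof)
        assert np.allclose(v, scores[19:40].ravel())

    def test_center_at_start_pads_left(self, rng):
        prof = PSSMProfile("P", rng.normal(size=(60, 20)))
        v = features.encode_pssm(frag("A" * 21, pos=1), prof)
        assert not v[:200].any()
        assert v[200:].any()

    def test_fabricated_round_trip(self, tmp_path, rng):
        rec = seqio.ProteinRecord("P1", "".join(rng.choice(list("ACDK"), 30)))
        profiles, _ = synthetic.fabricate_profiles([rec], tmp_path, seed=5)
        back = features.read_pssm(tmp_path / "pssm" / "P1.pssm", "P1")
        assert np.allclose(back.scores, profiles["P1"].scores)


def _fscore_reference(X, y):
    """Direct transliteration of the printed formula, as the oracle."""
    out = []
    pos = X[y == 1]
    neg = X[y == -1]
    for i in range(X.shape[1]):
        xb = np.mean(np.concatenate([pos[:, i], neg[:, i]]))
        xbp, xbn = pos[:, i].mean(), neg[:, i].mean()
        num = (xbp - xb) ** 2 + (xbn - xb) ** 2
        den = (np.sum((pos[:, i] - xbp) ** 2) / (len(pos) - 1)
               + np.sum((neg[:, i] - xbn) ** 2) / (len(neg) - 1))
        if den == 0:
            out.append(0.0 if num == 0 else np.inf)
        else:
            out.append(num / den)
    return np.array(out)


class TestFscore:
    def test_constant_feature_zero(self):
        X = np.ones((10, 1))
        y = np.array([1] * 5 + [-1] * 5)
        assert features.fscore(X, y)[0] == 0.0

    def test_perfect_separator_infinite(self):
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        y = np.array([1, 1, -1, -1])
        assert features.fscore(X, y)[0] == np.inf

    def test_matches_independent_formula(self, rng):
        X = np.vstack([rng.normal(1, 1, size=(40, 6)),
                       rng.normal(0, 2, size=(60, 6))])
        y = np.array([1] * 40 + [-1] * 60)
        assert np.allclose(features.fscore(X, y), _fscore_reference(X, y))

    def test_instance_order_invariance(self, rng):
        X = rng.normal(size=(50, 4))
        y = np.where(rng.random(50) < 0.5, 1, -1)
        y[:2] = [1, -1]  # ensure both classes twice over
        y[2:4] = [1, -1]
        perm = rng.permutation(50)
        assert np.allclose(features.fscore(X, y), features.fscore(X[perm], y[perm]))

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array([1] * 30 + [-1] * 30)
        scaled = 3.7 * X + 11.0
        assert np.allclose(features.fscore(X, y), features.fscore(scaled, y))

    def test_small_class_errors(self):
        with pytest.raises(ValidationError):
            features.fscore(np.ones((3, 1)), np.array([1, -1, -1]))

    def test_averaged_requires_matching_columns(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["a", "b"])
        y = np.array([1] * 5 + [-1] * 5)
        m1 = FeatureMatrix(X, y)
        m2 = FeatureMatrix(X.rename(columns={"b": "c"}), y)
        with pytest.raises(ValidationError):
            features.fscore_averaged([m1, m2])


class TestForwardSelect:
    @staticmethod
    def _trainer():
        from sklearn.svm import SVC
        return SVC(C=1.0, gamma=0.5, kernel="rbf")

    def _matrix(self, rng, n=120):
        informative = np.concatenate([rng.normal(1.5, 1, n // 2),
                                      rng.normal(-1.5, 1, n // 2)])
        noise = rng.normal(size=n)
        X = pd.DataFrame({"signal": informative, "noise": noise})
        y = np.array([1] * (n // 2) + [-1] * (n // 2))
        return FeatureMatrix(X, y)

    def test_keeps_signal_rejects_noise(self, rng):
        m = self._matrix(rng)
        res = features.forward_select(m, self._trainer, folds=5, seed=0)
        assert "signal" in res.retained
        assert "noise" not in res.retained

    def test_duplicate_features_keep_one(self, rng):
        m = self._matrix(rng)
        X = pd.DataFrame({"a": m.X["signal"], "b": m.X["signal"],
                          "c": m.X["signal"]})
        dup = FeatureMatrix(X, m.y)
        res = features.forward_select(dup, self._trainer, folds=5, seed=0)
        assert len(res.retained) == 1

    def test_shuffled_labels_select_nearly_nothing(self, rng):
        m = self._matrix(rng)
        y = m.y.copy()
        rng.shuffle(y)
        res = features.forward_select(FeatureMatrix(m.X, y), self._trainer,
                                      folds=5, seed=0)
        assert len(res.retained) <= 1

    def test_accuracy_trace_nondecreasing_at_accepted_steps(self, rng):
        m = self._matrix(rng)
        res = features.forward_select(m, self._trainer, folds=5, seed=0)
        trace = res.accuracy_trace
        assert trace == sorted(trace)

    def test_needs_two_features(self, rng):
        X = pd.DataFrame({"only": rng.normal(size=20)})
        y = np.array([1] * 10 + [-1] * 10)
        with pytest.raises(ValidationError):
            features.forward_select(FeatureMatrix(X, y), self._trainer)


class TestAssemble:
    def test_registry_order_and_provenance(self, rng):
        f = frag("A" * 21)
        enc = EncoderConfig(families=("cksaap", "physchem"), k_set=(0,))
        m = features.assemble([f], enc)
        cols = list(m.X.columns)
        # physchem precedes cksaap regardless of request order
        assert cols[0].startswith("pc|")
        assert cols[-1].startswith("cksaap|")
        assert len(set(cols)) == len(cols)

    def test_missing_profiles_degrade_gracefully(self, caplog):
        f = frag("A" * 21, pid="NOPE")
        enc = EncoderConfig(families=("physchem", "pssm"))
        m = features.assemble([f], enc)
        assert all(c.startswith("pc|") for c in m.X.columns)

    def test_strict_mode_raises(self):
        f = frag("A" * 21, pid="NOPE")
        enc = EncoderConfig(families=("pssm",), strict=True)
        with pytest.raises(ValidationError):
            features.assemble([f], enc)

    def test_top_fscore_features_hit_consensus_positions(self, synth_matrix):
        # on planted-motif data the strongest features involve -1 and +2
        _, _, matrix = synth_matrix
        scores = pd.Series(features.fscore(matrix.X, matrix.y),
                           index=matrix.X.columns)
        top = features.rank_features(scores).index[:12]
        hits = [c for c in top
                if ("|+2|" in c) or ("|-1|" in c) or c.startswith("cksaap")]
        assert len(hits) >= 6
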