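"""Directed MPNN: graph construction, forward oracle, training properties."""

import numpy as np
import pytest
from rdkit import Chem

from muorpred.dmpnn import (
    ATOM_DIM,
    BOND_DIM,
    DMPNNClassifier,
    DMPNNEnsemble,
    MoleculeFeatureNormalizer,
    _backward,
    _forward,
    _make_batch,
    add_molecule_features,
    init_params,
    smiles_to_graph,
)
from muorpred.ligands import InvalidSmilesError
from muorpred.metrics import auc


class TestGraphConstruction:
    @pytest.mark.parametrize(
        "smiles,n_atoms,n_edges",
        [
            ("CC", 2, 2),  # ethane: 1 bond, 2 directed edges
            ("c1ccccc1", 6, 12),
            ("C", 1, 0),  # bondless graph allowed
            ("CCO", 3, 4),
        ],
    )
    def test_counts(self, smiles, n_atoms, n_edges):
        g = smiles_to_graph(smiles)
        assert g.n_atoms == n_atoms and g.n_edges == n_edges

    def test_reverse_of_reverse_is_identity(self):
        g = smiles_to_graph("CC(O)CN")
        np.testing.assert_array_equal(g.rev_index[g.rev_index], np.arange(g.n_edges))
        np.testing.assert_array_equal(g.edge_src, g.edge_dst[g.rev_index])

    def test_benzene_aromatic_flags(self):
        g = smiles_to_graph("c1ccccc1")
        # aromatic atom flag lives after element(12)+degree(6)+charge(5)
        assert np.all(g.atom_features[:, 12 + 6 + 5] == 1.0)
        # aromatic bond type is the 4th bond one-hot slot
        assert np.all(g.bond_features[:, 3] == 1.0)

    def test_ethane_atom_feature_layout(self):
        """Hand-written one-hot layout for a CH3 carbon in ethane."""
        g = smiles_to_graph("CC")
        x = g.atom_features[0]
        expected = np.zeros(ATOM_DIM)
        expected[0] = 1  # element C
        expected[12 + 1] = 1  # degree 1
        expected[18 + 2] = 1  # formal charge 0
        expected[24 + 3] = 1  # three hydrogens
        expected[29 + 2] = 1  # sp3
        np.testing.assert_array_equal(x, expected)
        # single non-conjugated acyclic bond
        np.testing.assert_array_equal(g.bond_features[0], [1, 0, 0, 0, 0, 0])

    def test_invalid_smiles_rejected(self):
        with pytest.raises(InvalidSmilesError):
            smiles_to_graph("C(")


class TestForwardOracle:
    def _indicator_params(self, hidden=2):
        """W_i picks (element-C + single-bond) and (3-hydrogens); W_m = I."""
        params = init_params(hidden=hidden, seed=0)
        for k in params:
            params[k] = np.zeros_like(params[k])
        params["W_i"][0, 0] = 1.0  # x: element C
        params["W_i"][0, ATOM_DIM + 0] = 1.0  # e: single bond
        params["W_i"][1, 24 + 3] = 1.0  # x: three hydrogens
        params["W_m"][:] = np.eye(hidden)
        return params

    def test_ethane_edge_states_match_hand_enumeration(self):
        """Ethane, depth 1: both edge states are exactly relu(W_i [x||e]).

        With the indicator weights: channel 0 = 1 (C) + 1 (single bond) = 2,
        channel 1 = 1 (CH3).  No neighbors besides the reverse edge exist,
        so deeper message passing leaves the states unchanged.
        """
        batch = _make_batch([smiles_to_graph("CC")])
        params = self._indicator_params()
        for depth in (1, 3):
            cache = {}
            _forward(params, batch, depth=depth, cache=cache)
            np.testing.assert_allclose(cache["h0"], [[2, 1], [2, 1]])
            np.testing.assert_allclose(cache["h_last"], [[2, 1], [2, 1]])

    def test_propane_depth2_matches_hand_enumeration(self):
        """Propane edges (0->1, 1->0, 1->2, 2->1): h0 channel 1 is 1 only
        when the source is a CH3.  At t=1 the 1->0 and 1->2 messages pick
        up the single incoming edge from the opposite terminal CH3:
        h1 = [ [2,1], [4,1], [4,1], [2,1] ] by direct enumeration."""
        batch = _make_batch([smiles_to_graph("CCC")])
        params = self._indicator_params()
        cache = {}
        _forward(params, batch, depth=2, cache=cache)
        np.testing.assert_allclose(cache["h0"], [[2, 1], [2, 0], [2, 0], [2, 1]])
        np.testing.assert_allclose(cache["h_last"], [[2, 1], [4, 1], [4, 1], [2, 1]])

    def test_permutation_and_kekulization_invariance(self):
        pairs = [
            ("c1ccccc1CCO", "OCCc1ccccc1"),
            ("C1=CC=CC=C1", "c1ccccc1"),
            ("CC(N)C(=O)O", "OC(=O)C(C)N"),
        ]
        params = init_params(hidden=16, seed=3)
        for a, b in pairs:
            pa = _forward(params, _make_batch([smiles_to_graph(a)]), depth=3)
            pb = _forward(params, _make_batch([smiles_to_graph(b)]), depth=3)
            assert pa == pytest.approx(pb, abs=1e-12)

    def test_deterministic_without_dropout(self):
        params = init_params(hidden=8, seed=1)
        batch = _make_batch([smiles_to_graph("CCOc1ccccc1")])
        a = _forward(params, batch, depth=3)
        b = _forward(params, batch, depth=3)
        np.testing.assert_array_equal(a, b)

    def test_bondless_molecule_handled(self):
        params = init_params(hidden=8, seed=1)
        p = _forward(params, _make_batch([smiles_to_graph("C")]), depth=3)
        assert 0.0 < p[0] < 1.0

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        graphs = [smiles_to_graph(s) for s in ["CCO", "c1ccncc1", "C"]]
        batch = _make_batch(graphs)
        params = init_params(hidden=4, seed=1)
        y = np.array([1.0, 0.0, 1.0])

        def loss():
            p = _forward(params, batch, depth=3)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        cache = {}
        _forward(params, batch, depth=3, cache=cache)
        grads = _backward(params, batch, cache, y, depth=3)
        for key in ("W_i", "W_m", "W_a", "W_1"):
            flat = params[key].ravel()
            for idx in rng.choice(flat.size, size=5, replace=False):
                h = 1e-6
                old = flat[idx]
                flat[idx] = old + h
                lp = loss()
                flat[idx] = old - h
                lm = loss()
                flat[idx] = old
                num = (lp - lm) / (2 * h)
                assert grads[key].ravel()[idx] == pytest.approx(num, abs=1e-5)


def _contains_n_task(n_per_class=15):
    """Toy separable task: amines (positive) vs oxygen/alkane molecules."""
    neg = ["C" * k for k in range(2, 8)] + [f"{'C'*k}O" for k in range(1, 6)] + [
        "CC(C)C", "CCOCC", "CC(O)C", "c1ccccc1",
    ]
    pos = [f"{'C'*k}N" for k in range(1, 6)] + [
        "CCN(C)C", "CN(C)C", "C1CCNCC1", "NCCN", "CC(N)C", "CNC", "CCNC",
        "c1ccncc1", "CCCCN(C)C", "NCCO",
    ]
    smiles = neg[:n_per_class] + pos[:n_per_class]
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return smiles, y


class TestTraining:
    def test_loss_decreases_on_fixed_task(self):
        smiles, y = _contains_n_task()
        clf = DMPNNClassifier(
            hidden=16, depth=2, epochs=8, batch_size=10, val_fraction=0, patience=0, seed=0
        ).fit(smiles, y)
        assert clf.loss_history_[-1] < clf.loss_history_[0]

    def test_separable_task_learned(self):
        smiles, y = _contains_n_task()
        clf = DMPNNClassifier(
            hidden=32, depth=3, epochs=60, val_fraction=0, patience=0, seed=0
        ).fit(smiles, y)
        scores = clf.predict_proba(smiles)[:, 1]
        assert auc(scores, y) >= 0.95

    def test_ensemble_mean_equals_member_average(self):
        smiles, y = _contains_n_task()
        ens = DMPNNEnsemble(k=2, seed=0, hidden=16, depth=2, epochs=10).fit(smiles, y)
        probe = ["CCCO", "CCN(CC)CC", "c1ccccc1C"]
        mean_members = np.mean(
            [m.predict_proba(probe)[:, 1] for m in ens.models_], axis=0
        )
        np.testing.assert_allclose(ens.predict_proba(probe)[:, 1], mean_members)

    def test_k1_degenerates_to_single_model_with_carveout(self):
        smiles, y = _contains_n_task()
        ens = DMPNNEnsemble(k=1, seed=0, hidden=16, depth=2, epochs=10).fit(smiles, y)
        assert len(ens.models_) == 1
        assert 0.0 <= ens.threshold_ <= 1.0

    def test_reference_config_hyperparameters(self):
        clf = DMPNNClassifier.reference_config()
        assert (clf.depth, clf.hidden, clf.ffn_layers) == (6, 500, 2)
        assert (clf.dropout, clf.epochs, clf.batch_size) == (0.1, 100, 50)


class TestMoleculeFeatures:
    def test_mean_row_normalizes_to_zero(self):
        rng = np.random.default_rng(0)
        X = rng.random((20, 5))
        norm = MoleculeFeatureNormalizer().fit(X)
        np.testing.assert_allclose(norm.transform(X.mean(0, keepdims=True)), 0, atol=1e-12)

    def test_constant_feature_dropped(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        norm = MoleculeFeatureNormalizer().fit(X)
        assert norm.n_features_out == 1

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        X = rng.random((15, 4))
        norm = MoleculeFeatureNormalizer().fit(X)
        np.testing.assert_allclose(norm.inverse_transform(norm.transform(X)), X)

    def test_unfitted_rejected_and_concatenation(self):
        norm = MoleculeFeatureNormalizer()
        with pytest.raises(ValueError):
            norm.transform(np.ones((1, 3)))
        X = np.random.default_rng(0).random((10, 3))
        norm.fit(X)
        out = add_molecule_features(np.array([1.0, 2.0]), X[0], norm)
        assert out.shape == (2 + norm.n_features_out,)
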