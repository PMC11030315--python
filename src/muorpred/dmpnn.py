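"""A directed message passing neural network (D-MPNN) for molecules.

Hidden states live on *directed bonds* rather than atoms: each undirected
bond v-w yields two directed edges v->w and w->v.  With atom features x_v,
bond features e_vw and ReLU activation tau:

    h0_vw = tau(W_i [x_v || e_vw])
    h^t_vw = tau(h0_vw + W_m sum_{k in N(v)\\{w}} h^{t-1}_kv),  t = 1..T-1
    h_v   = tau(W_a [x_v || sum_{k in N(v)} h_kv] + b_a)
    mol   = mean_v h_v            (sum readout available)

The molecule vector, optionally concatenated with z-scored molecule-level
descriptors, feeds a 2-layer feed-forward head with dropout and a sigmoid
output: the antagonist probability.  Loss is binary cross-entropy, the
optimizer Adam with a linear warmup.  Bondless molecules (single heavy
atom) bypass message passing: the readout sees a zero bond sum.

Implemented in NumPy with handwritten backpropagation; exact permutation
invariance follows from the sum/mean aggregations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator, ClassifierMixin

from muorpred.ligands import InvalidSmilesError
from muorpred.metrics import f1_at_threshold, optimize_threshold
from muorpred.sampling import make_folds
from muorpred.trees import _labels01

# ---------------------------------------------------------------------------
# Feature schema (versioned: changing it invalidates checkpoints)

FEATURE_SCHEMA_VERSION = 1

ELEMENTS = ["C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B", "Si"]  # + other
HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]  # + other
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]

ATOM_DIM = (len(ELEMENTS) + 1) + 6 + 5 + 1 + 5 + (len(HYBRIDIZATIONS) + 1)
BOND_DIM = len(BOND_TYPES) + 2


def _one_hot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    feats = _one_hot(atom.GetSymbol(), ELEMENTS)
    feats += [1.0 if atom.GetDegree() == d else 0.0 for d in range(6)]
    feats += [1.0 if atom.GetFormalCharge() == c else 0.0 for c in (-2, -1, 0, 1, 2)]
    feats += [1.0 if atom.GetIsAromatic() else 0.0]
    feats += [1.0 if atom.GetTotalNumHs() == h else 0.0 for h in range(5)]
    feats += _one_hot(atom.GetHybridization(), HYBRIDIZATIONS)
    return feats


def _bond_features(bond: Chem.Bond) -> list[float]:
    return _one_hot(bond.GetBondType(), BOND_TYPES)[:-1] + [
        1.0 if bond.GetIsConjugated() else 0.0,
        1.0 if bond.IsInRing() else 0.0,
    ]


@dataclass
class MoleculeGraph:
    """Directed-edge molecular graph with fixed-layout feature vectors."""

    atom_features: np.ndarray  # (n_atoms, ATOM_DIM)
    bond_features: np.ndarray  # (n_edges, BOND_DIM)
    edge_src: np.ndarray  # (n_edges,) source atom per directed edge
    edge_dst: np.ndarray  # (n_edges,)
    rev_index: np.ndarray  # (n_edges,) index of the reversed edge

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_src.shape[0]


def smiles_to_graph(smiles: str) -> MoleculeGraph:
    """Build the directed graph; each bond contributes two directed edges."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    atoms = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=float)
    if atoms.size == 0:
        raise InvalidSmilesError(smiles)
    src, dst, bf, rev = [], [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        e = len(src)
        src += [i, j]
        dst += [j, i]
        bf += [_bond_features(bond)] * 2
        rev += [e + 1, e]
    return MoleculeGraph(
        atom_features=atoms,
        bond_features=np.array(bf, dtype=float).reshape(len(src), BOND_DIM),
        edge_src=np.array(src, dtype=int),
        edge_dst=np.array(dst, dtype=int),
        rev_index=np.array(rev, dtype=int),
    )


@dataclass
class _Batch:
    x: np.ndarray
    e: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    rev: np.ndarray
    atom_mol: np.ndarray  # molecule index per atom
    n_mols: int
    mol_sizes: np.ndarray


def _make_batch(graphs: Sequence[MoleculeGraph]) -> _Batch:
    xs, es, srcs, dsts, revs, amol = [], [], [], [], [], []
    a_off = e_off = 0
    sizes = []
    for m, g in enumerate(graphs):
        xs.append(g.atom_features)
        es.append(g.bond_features)
        srcs.append(g.edge_src + a_off)
        dsts.append(g.edge_dst + a_off)
        revs.append(g.rev_index + e_off)
        amol.append(np.full(g.n_atoms, m))
        sizes.append(g.n_atoms)
        a_off += g.n_atoms
        e_off += g.n_edges
    return _Batch(
        x=np.vstack(xs),
        e=np.vstack(es) if e_off else np.zeros((0, BOND_DIM)),
        src=np.concatenate(srcs) if srcs else np.zeros(0, int),
        dst=np.concatenate(dsts) if dsts else np.zeros(0, int),
        rev=np.concatenate(revs) if revs else np.zeros(0, int),
        atom_mol=np.concatenate(amol),
        n_mols=len(graphs),
        mol_sizes=np.array(sizes, dtype=float),
    )


# ---------------------------------------------------------------------------
# Parameters, forward, backward

def init_params(
    hidden: int,
    n_mol_features: int = 0,
    ffn_hidden: int | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Xavier-uniform parameter initialization."""
    rng = np.random.default_rng(seed)
    ffn_hidden = hidden if ffn_hidden is None else ffn_hidden

    def xavier(shape):
        bound = np.sqrt(6.0 / (shape[0] + shape[1]))
        return rng.uniform(-bound, bound, size=shape)

    d_in = hidden + n_mol_features
    return {
        "W_i": xavier((hidden, ATOM_DIM + BOND_DIM)),
        "W_m": xavier((hidden, hidden)),
        "W_a": xavier((hidden, ATOM_DIM + hidden)),
        "b_a": np.zeros(hidden),
        "W_1": xavier((ffn_hidden, d_in)),
        "b_1": np.zeros(ffn_hidden),
        "W_2": xavier((1, ffn_hidden)),
        "b_2": np.zeros(1),
    }


def _forward(
    params: dict,
    batch: _Batch,
    depth: int,
    readout: str = "mean",
    mol_features: np.ndarray | None = None,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Antagonist probabilities for a batch; fills ``cache`` for backward."""
    A, E = batch.x.shape[0], batch.src.shape[0]
    H = params["W_m"].shape[0]
    if E:
        z0 = np.hstack([batch.x[batch.src], batch.e])
        p0 = z0 @ params["W_i"].T
        h0 = np.maximum(p0, 0.0)
        h = h0
        steps = []
        for _ in range(1, depth):
            a_in = np.zeros((A, H))
            np.add.at(a_in, batch.dst, h)
            m = a_in[batch.src] - h[batch.rev]
            s = h0 + m @ params["W_m"].T
            h_new = np.maximum(s, 0.0)
            steps.append((h, m, s > 0))
            h = h_new
        am = np.zeros((A, H))
        np.add.at(am, batch.dst, h)
    else:
        z0 = p0 = h0 = h = np.zeros((0, H))
        steps = []
        am = np.zeros((A, H))
    za = np.hstack([batch.x, am])
    sa = za @ params["W_a"].T + params["b_a"]
    hv = np.maximum(sa, 0.0)
    mol = np.zeros((batch.n_mols, H))
    np.add.at(mol, batch.atom_mol, hv)
    if readout == "mean":
        mol = mol / batch.mol_sizes[:, None]
    full = mol if mol_features is None else np.hstack([mol, mol_features])
    s1 = full @ params["W_1"].T + params["b_1"]
    u1 = np.maximum(s1, 0.0)
    if dropout > 0 and rng is not None:
        mask = (rng.random(u1.shape) >= dropout) / (1.0 - dropout)
        u1d = u1 * mask
    else:
        mask = None
        u1d = u1
    logit = (u1d @ params["W_2"].T + params["b_2"]).ravel()
    prob = 1.0 / (1.0 + np.exp(-logit))
    if cache is not None:
        cache.update(
            z0=z0, p0=p0, h0=h0, steps=steps, h_last=h, am=am, za=za, sa=sa,
            hv=hv, full=full, s1=s1, u1d=u1d, mask=mask, prob=prob,
            mol_features=mol_features, readout=readout,
        )
    return prob


def _backward(
    params: dict, batch: _Batch, cache: dict, y: np.ndarray, depth: int
) -> dict[str, np.ndarray]:
    """Gradients of mean binary cross-entropy w.r.t. all parameters."""
    A, E = batch.x.shape[0], batch.src.shape[0]
    H = params["W_m"].shape[0]
    n = len(y)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    # BCE + sigmoid
    g_logit = (cache["prob"] - y) / n  # (M,)
    grads["W_2"] = g_logit[None, :] @ cache["u1d"]
    grads["b_2"] = np.array([g_logit.sum()])
    g_u1d = np.outer(g_logit, params["W_2"].ravel())
    if cache["mask"] is not None:
        g_u1d = g_u1d * cache["mask"]
    g_s1 = g_u1d * (cache["s1"] > 0)
    grads["W_1"] = g_s1.T @ cache["full"]
    grads["b_1"] = g_s1.sum(axis=0)
    g_full = g_s1 @ params["W_1"]
    g_mol = g_full[:, :H]  # molecule-feature columns carry no parameters
    if cache["readout"] == "mean":
        g_hv = g_mol[batch.atom_mol] / batch.mol_sizes[batch.atom_mol][:, None]
    else:
        g_hv = g_mol[batch.atom_mol]
    g_sa = g_hv * (cache["sa"] > 0)
    grads["W_a"] = g_sa.T @ cache["za"]
    grads["b_a"] = g_sa.sum(axis=0)
    g_za = g_sa @ params["W_a"]
    g_am = g_za[:, batch.x.shape[1]:]
    if E == 0:
        return grads
    g_h = g_am[batch.dst]  # into h at the final step
    g_h0_acc = np.zeros_like(cache["h0"])
    for h_prev, m, relu_mask in reversed(cache["steps"]):
        g_s = g_h * relu_mask
        g_h0_acc += g_s
        grads["W_m"] += g_s.T @ m
        g_m = g_s @ params["W_m"]
        g_ain = np.zeros((A, H))
        np.add.at(g_ain, batch.src, g_m)
        g_h = g_ain[batch.dst] - g_m[batch.rev]
    g_h0 = g_h + g_h0_acc
    g_p0 = g_h0 * (cache["p0"] > 0)
    grads["W_i"] = g_p0.T @ cache["z0"]
    return grads


class _Adam:
    def __init__(self, params: dict, lr: float = 1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr_scale: float = 1.0) -> None:
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= lr_scale * self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MoleculeFeatureNormalizer:
    """Z-score normalizer for molecule-level features (train rows only).

    Features with zero training SD are dropped.
    """

    def fit(self, X) -> "MoleculeFeatureNormalizer":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        self.keep_ = self.sd_ > 0
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "mean_"):
            raise ValueError("normalizer not fitted")
        X = np.asarray(X, dtype=float)
        return (X[:, self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]

    def inverse_transform(self, Z) -> np.ndarray:
        return np.asarray(Z) * self.sd_[self.keep_] + self.mean_[self.keep_]

    @property
    def n_features_out(self) -> int:
        return int(self.keep_.sum())


def add_molecule_features(
    vector: np.ndarray, descriptor_row: np.ndarray, normalizer: MoleculeFeatureNormalizer
) -> np.ndarray:
    """Concatenate a graph output vector with normalized descriptors."""
    z = normalizer.transform(np.atleast_2d(descriptor_row))[0]
    return np.concatenate([np.asarray(vector), z])


class DMPNNClassifier(BaseEstimator, ClassifierMixin):
    """Directed-MPNN binary classifier on SMILES (sklearn-style).

    Desk-scale defaults (hidden 64, depth 3, 30 epochs) train in seconds on
    a CPU; :meth:`reference_config` returns the printed-protocol setting
    (depth 6, hidden 500, 2 FFN layers, dropout 0.1, 100 epochs, batch 50).

    Early stopping monitors F1 of the antagonist class on a stratified
    validation carve-out (``val_fraction``) with the given ``patience``.

    Attributes
    ----------
    params_ : dict of weight arrays.
    threshold_ : F1-optimal decision threshold from validation scores.
    normalizer_ : fitted feature normalizer (when molecule features are used).
    """

    def __init__(
        self,
        depth: int = 3,
        hidden: int = 64,
        ffn_layers: int = 2,
        dropout: float = 0.1,
        epochs: int = 30,
        batch_size: int = 50,
        lr: float = 1e-3,
        warmup_epochs: int = 2,
        readout: str = "mean",
        use_molecule_features: bool = False,
        val_fraction: float = 0.1,
        patience: int = 10,
        seed: int = 0,
    ):
        self.depth = depth
        self.hidden = hidden
        self.ffn_layers = ffn_layers
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.warmup_epochs = warmup_epochs
        self.readout = readout
        self.use_molecule_features = use_molecule_features
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    @classmethod
    def reference_config(cls, **overrides) -> "DMPNNClassifier":
        cfg = dict(depth=6, hidden=500, ffn_layers=2, dropout=0.1, epochs=100, batch_size=50)
        cfg.update(overrides)
        return cls(**cfg)

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        smiles: Sequence[str],
        y,
        val_smiles: Sequence[str] | None = None,
        val_y=None,
    ) -> "DMPNNClassifier":
        if self.depth < 1 or self.hidden <= 0 or not 0 <= self.dropout < 1:
            raise ValueError("bad network configuration")
        y01 = _labels01(y)
        if len(np.unique(y01)) < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(self.seed)
        graphs = [smiles_to_graph(s) for s in smiles]
        feats = None
        if self.use_molecule_features:
            from muorpred.features import compute_descriptors

            table = compute_descriptors(list(smiles))
            self.normalizer_ = MoleculeFeatureNormalizer().fit(table.to_numpy())
            feats = self.normalizer_.transform(table.to_numpy())
        n_mf = 0 if feats is None else feats.shape[1]
        if val_smiles is None and self.val_fraction > 0 and self.patience > 0:
            idx = np.arange(len(graphs))
            val_idx = _stratified_carveout(y01, self.val_fraction, rng)
            tr_idx = np.setdiff1d(idx, val_idx)
        else:
            tr_idx = np.arange(len(graphs))
            val_idx = np.array([], dtype=int)
        ext_val_graphs = [smiles_to_graph(s) for s in val_smiles] if val_smiles else None
        self.params_ = init_params(self.hidden, n_mf, seed=int(rng.integers(2**31)))
        opt = _Adam(self.params_, lr=self.lr)
        best_f1, best_params, wait = -1.0, None, 0
        steps_per_epoch = max(1, int(np.ceil(len(tr_idx) / self.batch_size)))
        self.loss_history_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            epoch_loss = 0.0
            for b in range(0, len(order), self.batch_size):
                sel = order[b : b + self.batch_size]
                batch = _make_batch([graphs[i] for i in sel])
                mf = feats[sel] if feats is not None else None
                cache: dict = {}
                prob = _forward(
                    self.params_, batch, self.depth, self.readout, mf,
                    self.dropout, rng, cache,
                )
                yb = y01[sel].astype(float)
                eps = 1e-12
                epoch_loss += float(
                    -np.mean(yb * np.log(prob + eps) + (1 - yb) * np.log(1 - prob + eps))
                ) * len(sel)
                grads = _backward(self.params_, batch, cache, yb, self.depth)
                warm_steps = self.warmup_epochs * steps_per_epoch
                scale = min(1.0, (opt.t + 1) / warm_steps) if warm_steps > 0 else 1.0
                opt.step(self.params_, grads, lr_scale=scale)
            self.loss_history_.append(epoch_loss / max(1, len(order)))
            # early stopping on validation F1
            monitor_graphs = ext_val_graphs if ext_val_graphs is not None else [
                graphs[i] for i in val_idx
            ]
            if monitor_graphs:
                mon_y = (
                    _labels01(val_y) if ext_val_graphs is not None else y01[val_idx]
                )
                mon_feats = None
                if feats is not None:
                    if ext_val_graphs is not None:
                        from muorpred.features import compute_descriptors

                        mon_feats = self.normalizer_.transform(
                            compute_descriptors(list(val_smiles)).to_numpy()
                        )
                    else:
                        mon_feats = feats[val_idx]
                scores = _forward(
                    self.params_, _make_batch(monitor_graphs), self.depth,
                    self.readout, mon_feats,
                )
                f1 = f1_at_threshold(scores, mon_y, 0.5)
                if f1 > best_f1 + 1e-12:
                    best_f1, wait = f1, 0
                    best_params = {k: v.copy() for k, v in self.params_.items()}
                else:
                    wait += 1
                    if wait >= self.patience:
                        break
        if best_params is not None:
            self.params_ = best_params
        # decision threshold from validation (fall back to training) scores
        if len(val_idx) > 0:
            thr_scores = self._predict_graphs(
                [graphs[i] for i in val_idx], feats[val_idx] if feats is not None else None
            )
            thr_y = y01[val_idx]
        else:
            thr_scores = self._predict_graphs(graphs, feats)
            thr_y = y01
        if len(np.unique(thr_y)) == 2:
            self.threshold_ = optimize_threshold(thr_scores, thr_y)
        else:
            self.threshold_ = 0.5
        self.classes_ = np.array([0, 1])
        return self

    # -- prediction --------------------------------------------------------
    def _predict_graphs(
        self, graphs: Sequence[MoleculeGraph], feats: np.ndarray | None
    ) -> np.ndarray:
        out = []
        for b in range(0, len(graphs), 500):
            batch = _make_batch(graphs[b : b + 500])
            mf = feats[b : b + 500] if feats is not None else None
            out.append(_forward(self.params_, batch, self.depth, self.readout, mf))
        return np.concatenate(out) if out else np.zeros(0)

    def predict_proba(self, smiles: Sequence[str]) -> np.ndarray:
        graphs = [smiles_to_graph(s) for s in smiles]
        feats = None
        if self.use_molecule_features:
            from muorpred.features import compute_descriptors

            feats = self.normalizer_.transform(
                compute_descriptors(list(smiles)).to_numpy()
            )
        p1 = self._predict_graphs(graphs, feats)
        return np.column_stack([1 - p1, p1])

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        return (self.predict_proba(smiles)[:, 1] >= self.threshold_).astype(int)


def _stratified_carveout(y01: np.ndarray, fraction: float, rng) -> np.ndarray:
    """Indices of a stratified validation carve-out (>=1 per class)."""
    val = []
    for c in np.unique(y01):
        idx = np.flatnonzero(y01 == c)
        k = max(1, int(round(fraction * len(idx))))
        val.extend(rng.permutation(idx)[:k])
    return np.array(sorted(val), dtype=int)


class DMPNNEnsemble(BaseEstimator, ClassifierMixin):
    """Fold ensemble of D-MPNNs: one model per CV fold, mean probability.

    Each member trains on k-1 folds with its own fold as the early-stopping
    validation part.  ``k = 1`` degenerates to a single model with an
    internal 10% validation carve-out.  The ensemble decision threshold
    maximizes F1(AN) over the pooled out-of-fold validation scores.
    """

    def __init__(self, k: int = 5, seed: int = 0, **member_kwargs):
        self.k = k
        self.seed = seed
        self.member_kwargs = member_kwargs

    def fit(self, smiles: Sequence[str], y) -> "DMPNNEnsemble":
        smiles = list(smiles)
        y01 = _labels01(y)
        self.models_ = []
        self.fold_scores_ = []
        if self.k <= 1:
            model = DMPNNClassifier(seed=self.seed, **self.member_kwargs).fit(smiles, y01)
            self.models_.append(model)
            self.threshold_ = model.threshold_
            self.classes_ = np.array([0, 1])
            return self
        folds = make_folds(range(len(smiles)), y01, self.k, self.seed)
        pooled_scores, pooled_y = [], []
        for f in range(self.k):
            tr = np.flatnonzero(folds != f)
            va = np.flatnonzero(folds == f)
            if len(np.unique(y01[va])) < 2 or len(np.unique(y01[tr])) < 2:
                raise ValueError(f"fold {f} has a single class")
            model = DMPNNClassifier(seed=self.seed + f, **self.member_kwargs)
            model.fit(
                [smiles[i] for i in tr], y01[tr],
                val_smiles=[smiles[i] for i in va], val_y=y01[va],
            )
            self.models_.append(model)
            val_scores = model.predict_proba([smiles[i] for i in va])[:, 1]
            from muorpred.metrics import auc as _auc

            self.fold_scores_.append(float(_auc(val_scores, y01[va])))
            pooled_scores.append(val_scores)
            pooled_y.append(y01[va])
        self.threshold_ = optimize_threshold(
            np.concatenate(pooled_scores), np.concatenate(pooled_y)
        )
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, smiles: Sequence[str]) -> np.ndarray:
        probs = np.mean([m.predict_proba(smiles)[:, 1] for m in self.models_], axis=0)
        return np.column_stack([1 - probs, probs])

    def predict(self, smiles: Sequence[str]) -> np.ndarray:
        return (self.predict_proba(smiles)[:, 1] >= self.threshold_).astype(int)


def train_mpnn(smiles, y, k: int = 5, seed: int = 0, **kwargs) -> DMPNNEnsemble:
    """Functional wrapper: fold-ensemble D-MPNN training."""
    return DMPNNEnsemble(k=k, seed=seed, **kwargs).fit(smiles, y)
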