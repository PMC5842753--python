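"""Balanced random forest on scikit-learn trees, with OOB permutation importance.

A balanced forest differs from a standard random forest only in the bootstrap:
every tree is grown on an equal-count with-replacement resample from the two
classes (size 2 x the minority class count), so the ensemble is not biased
toward the majority class.  Splits are chosen among floor(log2(M)) randomly
drawn features, prediction is by majority vote over trees, and vote ties go to
the positive class.

Out-of-bag (OOB) machinery is the workhorse of feature selection: a tree's OOB
samples are the subjects absent from its bootstrap, and OOB accuracy is the
vote accuracy over each subject's OOB trees.  Permutation importance of a
feature is the drop in OOB accuracy when its column is permuted; only trees
that actually split on the feature can change their prediction, so the
implementation re-evaluates exactly those trees (a feature no tree uses has
importance identically zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.tree import DecisionTreeClassifier


def split_candidates_for(n_features: int) -> int:
    """floor(log2(M)) features examined per split, at least 1."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return max(1, int(np.floor(np.log2(n_features))))


@dataclass
class BalancedForestSpec:
    """Configuration of a balanced random forest.

    ``split_candidates=None`` means floor(log2(M)) with M the number of
    features in the table the forest is fitted on.
    """

    n_trees: int = 1000
    split_candidates: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.split_candidates is not None and self.split_candidates < 1:
            raise ValueError("split_candidates must be >= 1")


class BalancedRandomForest:
    """Two-class balanced-bootstrap forest.

    Parameters
    ----------
    spec:
        Forest configuration (tree count, split candidates, seed).
    positive_class:
        Label treated as the positive class; vote ties resolve toward it.
        If omitted, the lexicographically larger label is positive.
    """

    def __init__(self, spec: BalancedForestSpec | None = None, positive_class=None):
        self.spec = spec or BalancedForestSpec()
        self.positive_class = positive_class
        self._trees = None

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, seed: int | None = None) -> "BalancedRandomForest":
        X = np.ascontiguousarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] == 0 or X.shape[1] == 0:
            raise ValueError("X must be a non-empty 2-D table")
        classes = sorted(set(y.tolist()))
        if len(classes) != 2:
            raise ValueError(f"exactly two classes required, got {classes}")
        pos = self.positive_class if self.positive_class is not None else classes[-1]
        if pos not in classes:
            raise ValueError(f"positive_class {pos!r} not present in labels")
        neg = classes[0] if classes[1] == pos else classes[1]
        self.classes_ = (neg, pos)
        y01 = (y == pos).astype(np.intp)
        idx_neg = np.flatnonzero(y01 == 0)
        idx_pos = np.flatnonzero(y01 == 1)
        if len(idx_neg) < 2 or len(idx_pos) < 2:
            raise ValueError("each class needs at least 2 subjects for a balanced bootstrap")
        n, M = X.shape
        n_min = min(len(idx_neg), len(idx_pos))
        mtry = self.spec.split_candidates or split_candidates_for(M)
        mtry = min(mtry, M)

        rng = np.random.default_rng(self.spec.seed if seed is None else seed)
        tree_states = rng.integers(0, 2**31 - 1, size=self.spec.n_trees)
        self._X, self._y01 = X, y01
        self._trees, self._oob_rows, self._leaf_class, self._oob_pred = [], [], [], []
        for t in range(self.spec.n_trees):
            boot = np.concatenate(
                [rng.choice(idx_neg, n_min, replace=True),
                 rng.choice(idx_pos, n_min, replace=True)]
            )
            tree = DecisionTreeClassifier(
                max_features=mtry, random_state=int(tree_states[t])
            )
            tree.fit(X[boot], y01[boot], check_input=False)
            in_bag = np.zeros(n, dtype=bool)
            in_bag[boot] = True
            oob = np.flatnonzero(~in_bag)
            value = tree.tree_.value[:, 0, :]
            if value.shape[1] == 1:  # bootstrap degenerate to one class cannot happen,
                leaf_class = np.full(value.shape[0], int(y01[boot][0]))  # but be safe
            else:
                leaf_class = (value[:, 1] >= value[:, 0]).astype(np.intp)
            self._trees.append(tree)
            self._oob_rows.append(oob)
            self._leaf_class.append(leaf_class)
            self._oob_pred.append(leaf_class[tree.tree_.apply(X[oob])] if oob.size else
                                  np.empty(0, dtype=np.intp))

        V = np.zeros((n, 2))
        for oob, pred in zip(self._oob_rows, self._oob_pred):
            if oob.size:
                np.add.at(V, (oob, pred), 1)
        self._oob_votes = V
        self._covered = V.sum(axis=1) > 0
        self._features_by_tree = [
            np.unique(t.tree_.feature[t.tree_.feature >= 0]) for t in self._trees
        ]
        return self

    def _require_fitted(self) -> None:
        if self._trees is None:
            raise RuntimeError("forest is not fitted")

    @property
    def n_features_(self) -> int:
        self._require_fitted()
        return self._X.shape[1]

    def features_used(self) -> np.ndarray:
        """Sorted indices of features used by at least one tree."""
        self._require_fitted()
        if not any(f.size for f in self._features_by_tree):
            return np.empty(0, dtype=np.intp)
        return np.unique(np.concatenate(self._features_by_tree))

    # -- prediction --------------------------------------------------------

    def vote_fractions(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive class, per row."""
        self._require_fitted()
        X = np.ascontiguousarray(X, dtype=np.float32)
        if X.ndim == 1:
            X = X[None, :]
        votes = np.zeros(X.shape[0])
        for tree, leaf_class in zip(self._trees, self._leaf_class):
            votes += leaf_class[tree.tree_.apply(X)]
        return votes / len(self._trees)

    def predict(self, X) -> np.ndarray:
        """Majority-vote labels; exact ties go to the positive class."""
        frac = self.vote_fractions(X)
        neg, pos = self.classes_
        return np.where(frac >= 0.5, pos, neg)

    def training_accuracy(self) -> float:
        pred01 = self.vote_fractions(self._X) >= 0.5
        return float(np.mean(pred01 == (self._y01 == 1)))

    # -- out-of-bag machinery ---------------------------------------------

    def _acc_from_votes(self, V: np.ndarray) -> float:
        c = self._covered
        pred = V[c, 1] >= V[c, 0]
        return float(np.mean(pred == (self._y01[c] == 1)))

    def oob_accuracy(self) -> float:
        """OOB vote accuracy over subjects covered by at least one OOB tree."""
        self._require_fitted()
        return self._acc_from_votes(self._oob_votes)

    def oob_error(self) -> float:
        return 1.0 - self.oob_accuracy()

    @property
    def n_oob_covered(self) -> int:
        self._require_fitted()
        return int(self._covered.sum())

    def permutation_importance(
        self, n_repeats: int = 50, seed: int = 0, mode: str = "per_tree",
        X_eval: np.ndarray | None = None,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """OOB permutation importance of every feature.

        For each repeat, a feature's column is permuted across subjects and
        the loss of OOB accuracy recorded.  Two flavours:

        ``per_tree`` (default, Breiman's importance): the accuracy drop is
        measured per tree over the tree's own OOB samples and averaged over
        all trees.  This stays informative when several features carry
        redundant signal -- the ensemble majority vote barely moves when one
        of them is permuted, but each tree that split on the feature loses
        accuracy individually.

        ``ensemble``: the drop of the forest-level OOB vote accuracy.  With
        many redundant features this saturates toward zero.

        ``X_eval`` substitutes a modified copy of the training table as the
        evaluation data (same subjects and feature layout); the per-tree and
        ensemble baselines are then recomputed on it.  This supports
        conditional importances -- e.g. measuring every feature's importance
        while another feature's column is held permuted -- without refitting.

        Returns ``(mean, sd, raw)`` with ``raw`` of shape
        (n_features, n_repeats); features no tree splits on have identically
        zero rows.
        """
        self._require_fitted()
        if n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if mode not in ("per_tree", "ensemble"):
            raise ValueError("mode must be 'per_tree' or 'ensemble'")
        n, M = self._X.shape
        trees_by_feature: list[list[int]] = [[] for _ in range(M)]
        for ti, feats in enumerate(self._features_by_tree):
            for f in feats:
                trees_by_feature[f].append(ti)

        rng = np.random.default_rng(seed)
        n_trees = len(self._trees)
        if X_eval is None:
            oob_pred = self._oob_pred
            oob_votes = self._oob_votes
        else:
            X_eval = np.ascontiguousarray(X_eval, dtype=np.float32)
            if X_eval.shape != self._X.shape:
                raise ValueError("X_eval must match the training table shape")
            oob_pred = [
                self._leaf_class[ti][self._trees[ti].tree_.apply(X_eval[oob])]
                if oob.size else np.empty(0, dtype=np.intp)
                for ti, oob in enumerate(self._oob_rows)
            ]
            oob_votes = np.zeros((n, 2))
            for oob, pred in zip(self._oob_rows, oob_pred):
                if oob.size:
                    np.add.at(oob_votes, (oob, pred), 1)
        base_acc = self._acc_from_votes(oob_votes)
        tree_acc = np.array([
            np.mean(pred == self._y01[oob]) if oob.size else 0.0
            for oob, pred in zip(self._oob_rows, oob_pred)
        ])
        raw = np.zeros((M, n_repeats))
        Xw = (self._X if X_eval is None else X_eval).copy()
        for f in range(M):
            affected = trees_by_feature[f]
            if not affected:
                continue  # importance exactly 0
            col = Xw[:, f].copy()
            for r in range(n_repeats):
                Xw[:, f] = col[rng.permutation(n)]
                if mode == "per_tree":
                    drop = 0.0
                    for ti in affected:
                        oob = self._oob_rows[ti]
                        if not oob.size:
                            continue
                        new_pred = self._leaf_class[ti][
                            self._trees[ti].tree_.apply(Xw[oob])
                        ]
                        drop += tree_acc[ti] - np.mean(new_pred == self._y01[oob])
                    raw[f, r] = drop / n_trees
                else:
                    V = oob_votes.copy()
                    for ti in affected:
                        oob = self._oob_rows[ti]
                        if not oob.size:
                            continue
                        new_pred = self._leaf_class[ti][
                            self._trees[ti].tree_.apply(Xw[oob])
                        ]
                        np.add.at(V, (oob, oob_pred[ti]), -1)
                        np.add.at(V, (oob, new_pred), 1)
                    raw[f, r] = base_acc - self._acc_from_votes(V)
            Xw[:, f] = col
        sd = raw.std(axis=1, ddof=1) if n_repeats > 1 else np.zeros(M)
        return raw.mean(axis=1), sd, raw
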