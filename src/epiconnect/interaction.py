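"""Pairwise feature-interaction effects on permutation importance.

The interaction effect of feature f1 on feature f2 is the change in f2's
permutation importance when f1 is removed from the design, operationalized by
permuting f1's column (in training and evaluation) and retraining the forest.
Entry (r, c) of the matrix is

    effect(r, c) = importance(c | r permuted out) - importance(c | baseline)

averaged over repeated permutations of r.  A negative entry means the
discriminative information in c is only usable while r is in the design (the
signature of jointly-informative features such as an XOR pair); a positive
entry means c becomes more relevant once r is broken.  The diagonal is fixed
at zero.

Both importances are measured within one fitted forest (per-tree OOB
permutation importance), with the conditional one evaluated on data in which
r's column is held permuted.  Refitting the forest without r would instead
measure redundancy competition -- two features carrying the same signal would
show a large spurious "interaction" simply because the refitted forest leans
harder on the survivor -- whereas the fixed-forest measure isolates joint use
within trees: only trees that split on both features react to the
conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureTable
from .forest import BalancedForestSpec, BalancedRandomForest


@dataclass
class InteractionMatrix:
    feature_names: list
    effects: np.ndarray  # (k, k); row = permuted-out feature, col = affected
    baseline_importance: np.ndarray
    baseline_sd: np.ndarray  # permutation-repeat sd of the baseline importances

    def __post_init__(self) -> None:
        k = len(self.feature_names)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (k, k):
            raise ValueError("effects must be k x k")
        if not np.isfinite(self.effects).all():
            raise ValueError("non-finite interaction effects")
        if np.abs(np.diag(self.effects)).max(initial=0.0) != 0:
            raise ValueError("diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.effects, index=self.feature_names,
                            columns=self.feature_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.12g")


def interaction_matrix(
    table: FeatureTable,
    forest_spec: BalancedForestSpec | None = None,
    n_repeats: int = 20,
    inner_repeats: int = 5,
    seed: int = 0,
    positive_class=None,
) -> InteractionMatrix:
    """Interaction-effect matrix over the (selected) features of ``table``.

    ``n_repeats`` permutations of the removed feature are averaged; under
    each, the remaining features' importances are measured with
    ``inner_repeats`` permutation repeats in the same fitted forest.
    """
    k = table.n_features
    if k < 2:
        raise ValueError("interaction analysis needs at least 2 features")
    labels = np.asarray(table.labels)
    rng = np.random.default_rng(seed)
    n = table.n_subjects

    forest = BalancedRandomForest(forest_spec, positive_class=positive_class)
    forest.fit(table.values, labels, seed=int(rng.integers(2**31 - 1)))
    base_mean, base_sd, _ = forest.permutation_importance(
        n_repeats=max(n_repeats, inner_repeats), seed=int(rng.integers(2**31 - 1))
    )

    effects = np.zeros((k, k))
    for r in range(k):
        acc = np.zeros(k)
        for _ in range(n_repeats):
            Xp = table.values.astype(np.float32).copy()
            Xp[:, r] = Xp[rng.permutation(n), r]
            cond_mean, _, _ = forest.permutation_importance(
                n_repeats=inner_repeats, seed=int(rng.integers(2**31 - 1)),
                X_eval=Xp,
            )
            acc += cond_mean
        effects[r] = acc / n_repeats - base_mean
        effects[r, r] = 0.0

    return InteractionMatrix(
        feature_names=list(table.feature_names),
        effects=effects,
        baseline_importance=base_mean,
        baseline_sd=base_sd,
    )


def interaction_heatmap(matrix: InteractionMatrix, path) -> None:
    """Diverging heat map of the interaction matrix (blue = negative)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(matrix.feature_names)
    lim = max(np.abs(matrix.effects).max(), 1e-12)
    fig, ax = plt.subplots(figsize=(1.2 * k + 2, 1.0 * k + 1.5))
    im = ax.imshow(matrix.effects, cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(k), matrix.feature_names, rotation=45, ha="right")
    ax.set_yticks(range(k), matrix.feature_names)
    ax.set_xlabel("affected feature")
    ax.set_ylabel("feature permuted out of the design")
    fig.colorbar(im, ax=ax, label="change in permutation importance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
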