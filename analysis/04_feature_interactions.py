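"""Pairwise interaction effects between the selected features.

For each task, measures how each selected feature's permutation importance
changes when another selected feature is permuted out of the design (within
the fitted forest, no refit).  Negative entries (blue in the heat map) mark
features whose discriminative information is only usable jointly; positive
entries mark features that step in once a competitor is broken.  Writes one
square CSV and one heat map per task.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from epiconnect import classify, interaction
from epiconnect.features import FeatureTable
from epiconnect.pipeline import scaled_config

OUT = Path("results/analysis")


def main() -> None:
    cfg = scaled_config(seed=1)
    table = FeatureTable.from_csv(OUT / "features.csv")
    labels = np.asarray(table.labels)
    tasks = {
        "diagnosis": (
            table.with_labels(classify.to_diagnosis_labels(labels)),
            classify.DIAGNOSIS_POSITIVE,
        ),
        "lateralization": (
            table.restrict_subjects(labels != "CONTROL"),
            classify.LATERALIZATION_POSITIVE,
        ),
    }
    for name, (task_table, pos) in tasks.items():
        selected = pd.read_csv(OUT / f"selection_{name}.csv")["feature"].tolist()
        if len(selected) < 2:
            print(f"[{name}] fewer than 2 selected features; skipping")
            continue
        mat = interaction.interaction_matrix(
            task_table.restrict_features(selected), cfg.forest,
            n_repeats=cfg.interaction_repeats, seed=cfg.seed, positive_class=pos,
        )
        mat.to_csv(OUT / f"interaction_{name}.csv")
        interaction.interaction_heatmap(mat, OUT / f"interaction_{name}.png")
        off = mat.effects[~np.eye(len(selected), dtype=bool)]
        r, c = np.unravel_index(np.argmin(mat.effects), mat.effects.shape)
        print(f"[{name}] interaction effects over {len(selected)} features: "
              f"min {off.min():+.4f}, max {off.max():+.4f}")
        print(f"  strongest negative: permuting out {selected[r]} "
              f"drops the importance of {selected[c]} by {-mat.effects[r, c]:.4f}")
    print(f"wrote {OUT}/interaction_*.csv and heat maps")


if __name__ == "__main__":
    main()
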