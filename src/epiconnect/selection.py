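"""Two-step feature selection on balanced-forest permutation importance.

Step 1 (screening): train one balanced forest on the full table, measure each
feature's OOB permutation importance over repeated permutations, and drop the
features whose importance is not significantly above zero.

Step 2 (minimal subset): rank the surviving features by mean importance,
remove redundant information (a candidate that is nearly collinear with an
already-kept feature is skipped), and evaluate the OOB error of the top-k
prefixes, k = 1..cap with cap = floor(n_subjects / 10) (one feature per ten
subjects).  The selected set is the smallest prefix whose OOB error is
within ``tol_se`` standard errors of the best prefix error -- the smallest
set that carries the maximum discriminant information.  A duplicated feature
is filtered as redundant; a jointly-informative pair (e.g. an XOR pair) is
uncorrelated, survives the filter, and is admitted because the error only
drops once both members are in the prefix.

Per-feature two-sided Mann-Whitney-Wilcoxon p-values accompany the selected
set; note that features can be individually non-significant yet carry strong
joint discriminative power, which is exactly what the interaction analysis
quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import FeatureTable
from .forest import BalancedForestSpec, BalancedRandomForest


def feature_cap(n_subjects: int) -> int:
    """Maximum number of selected features: one per ten subjects, at least 1."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return max(1, n_subjects // 10)


@dataclass
class ImportanceReport:
    feature_names: list
    mean_importance: np.ndarray
    importance_sd: np.ndarray
    raw: np.ndarray  # (n_features, n_repeats)
    significant: np.ndarray  # bool per feature
    alpha: float
    oob_accuracy: float

    def __post_init__(self) -> None:
        if (self.importance_sd < 0).any():
            raise ValueError("importance sd must be >= 0")
        if (self.significant & ~(self.mean_importance > 0)).any():
            raise ValueError("a significant feature must have positive importance")


def _significance(raw: np.ndarray, alpha: float, method: str) -> np.ndarray:
    """One-sided test per feature that the repeat importances exceed zero."""
    mean = raw.mean(axis=1)
    sd = raw.std(axis=1, ddof=1) if raw.shape[1] > 1 else np.zeros(raw.shape[0])
    sig = np.zeros(raw.shape[0], dtype=bool)
    for f in range(raw.shape[0]):
        if mean[f] <= 0:
            continue
        if sd[f] == 0:
            # every permutation gave the same positive drop
            sig[f] = True
            continue
        if method == "ttest":
            p = stats.ttest_1samp(raw[f], 0.0, alternative="greater").pvalue
            sig[f] = p < alpha
        elif method == "zscore":
            # conservative: the mean must clear the single-permutation noise
            # scale, not the standard error of the mean
            sig[f] = mean[f] > stats.norm.ppf(1 - alpha) * sd[f]
        else:
            raise ValueError(f"unknown significance method {method!r}")
    return sig


def permutation_importance(
    table: FeatureTable,
    forest_spec: BalancedForestSpec | None = None,
    n_repeats: int = 50,
    alpha: float = 0.05,
    seed: int = 0,
    positive_class=None,
    significance: str = "zscore",
    mode: str = "per_tree",
) -> ImportanceReport:
    """Screening importances: one balanced forest, repeated column permutation."""
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    forest = BalancedRandomForest(forest_spec, positive_class=positive_class)
    forest.fit(table.values, np.asarray(table.labels), seed=seed)
    mean, sd, raw = forest.permutation_importance(n_repeats=n_repeats, seed=seed + 1,
                                                  mode=mode)
    sig = _significance(raw, alpha, significance)
    return ImportanceReport(
        feature_names=list(table.feature_names),
        mean_importance=mean,
        importance_sd=sd,
        raw=raw,
        significant=sig,
        alpha=alpha,
        oob_accuracy=forest.oob_accuracy(),
    )


def drop_insignificant(report: ImportanceReport) -> list:
    """Names of the significantly important features, original order preserved."""
    return [n for n, s in zip(report.feature_names, report.significant) if s]


@dataclass
class SelectionResult:
    """Selected features, most to least important, with MWW p-values."""

    selected: list
    importances: np.ndarray  # aligned to `selected`, descending
    mww_p: np.ndarray  # aligned to `selected`
    cap: int
    prefix_oob_errors: list = field(default_factory=list)  # diagnostic, k = 1..

    def __post_init__(self) -> None:
        if len(self.selected) > self.cap:
            raise ValueError("selected set exceeds the cap")
        imps = np.asarray(self.importances, dtype=float)
        if (np.diff(imps) > 1e-12).any():
            raise ValueError("selected features must be in descending importance order")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature": self.selected,
                "importance_x100": np.round(100 * np.asarray(self.importances), 2),
                "p_value": np.round(self.mww_p, 3),
            }
        )

    def to_dict(self) -> dict:
        return {
            "selected": list(self.selected),
            "importances": [float(v) for v in self.importances],
            "mww_p": [float(v) for v in self.mww_p],
            "cap": self.cap,
            "prefix_oob_errors": [float(v) for v in self.prefix_oob_errors],
        }


def mww_test(x, y) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value between two samples.

    Uses the exact U distribution when both samples have at most 20
    observations and there are no ties, and the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both classes must be non-empty")
    pooled = np.concatenate([x, y])
    exact = x.size <= 20 and y.size <= 20 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def _mww_by_label(table: FeatureTable, names) -> np.ndarray:
    labels = np.asarray(table.labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("MWW p-values need exactly two classes")
    mask = labels == classes[0]
    out = []
    for name in names:
        col = table.values[:, table.feature_names.index(name)]
        out.append(mww_test(col[mask], col[~mask]))
    return np.asarray(out)


def minimal_subset(
    table: FeatureTable,
    forest_spec: BalancedForestSpec | None = None,
    cap: int | None = None,
    seed: int = 0,
    importances: np.ndarray | None = None,
    tol_se: float = 1.0,
    positive_class=None,
    n_repeats: int = 20,
    redundancy_r: float | None = 0.8,
) -> SelectionResult:
    """Smallest importance-ranked prefix within ``tol_se`` SE of the best OOB error.

    ``table`` should already be restricted to the screened features.
    ``importances`` (aligned to ``table.feature_names``) may be passed to
    reuse the screening importances; otherwise they are recomputed.  Equal
    importances break ties lexicographically by feature name.

    Redundant information is removed before the prefix evaluation: walking
    the ranking in importance order, a candidate whose absolute Pearson
    correlation with an already-kept feature exceeds ``redundancy_r``
    (default 0.8; None disables) is skipped.  Band-resolved connectivity
    features duplicate each other heavily, and without this filter the
    capped prefix is spent on copies of one signal.
    """
    if table.n_features == 0:
        raise ValueError("screened feature set is empty")
    if cap is None:
        cap = feature_cap(table.n_subjects)
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if importances is None:
        importances = permutation_importance(
            table, forest_spec, n_repeats=n_repeats, seed=seed,
            positive_class=positive_class,
        ).mean_importance
    importances = np.asarray(importances, dtype=float)
    if importances.shape != (table.n_features,):
        raise ValueError("importances must align with table features")

    order = sorted(
        range(table.n_features),
        key=lambda i: (-importances[i], table.feature_names[i]),
    )
    if redundancy_r is not None:
        kept: list[int] = []
        for i in order:
            col = table.values[:, i]
            if all(
                abs(np.nan_to_num(np.corrcoef(col, table.values[:, j])[0, 1]))
                <= redundancy_r
                for j in kept
            ):
                kept.append(i)
            if len(kept) == cap:
                break
        order = kept
    ranked = [table.feature_names[i] for i in order]

    labels = np.asarray(table.labels)
    k_max = min(cap, len(ranked))
    errors, ses = [], []
    rng = np.random.default_rng(seed)
    for k in range(1, k_max + 1):
        sub = table.restrict_features(ranked[:k])
        forest = BalancedRandomForest(forest_spec, positive_class=positive_class)
        forest.fit(sub.values, labels, seed=int(rng.integers(2**31 - 1)))
        err = forest.oob_error()
        errors.append(err)
        ses.append(np.sqrt(err * (1 - err) / max(forest.n_oob_covered, 1)))
        if err == 0.0:
            break
    best = int(np.argmin(errors))
    threshold = errors[best] + tol_se * ses[best]
    k_sel = next(k for k, e in enumerate(errors, start=1) if e <= threshold)

    selected = ranked[:k_sel]
    sel_imp = np.asarray([importances[order[i]] for i in range(k_sel)])
    return SelectionResult(
        selected=selected,
        importances=sel_imp,
        mww_p=_mww_by_label(table, selected),
        cap=cap,
        prefix_oob_errors=errors,
    )


def screen_and_select(
    table: FeatureTable,
    forest_spec: BalancedForestSpec | None = None,
    cap: int | None = None,
    alpha: float = 0.05,
    n_repeats: int = 50,
    tol_se: float = 1.0,
    seed: int = 0,
    positive_class=None,
    significance: str = "zscore",
    redundancy_r: float | None = 0.8,
) -> tuple[SelectionResult, ImportanceReport]:
    """Full selection pipeline: screen by importance significance, then pick
    the minimal subset.  If nothing survives screening (an uninformative
    table), the single most important feature is carried forward so that a
    classifier can still be trained."""
    report = permutation_importance(
        table, forest_spec, n_repeats=n_repeats, alpha=alpha, seed=seed,
        positive_class=positive_class, significance=significance,
    )
    screened = drop_insignificant(report)
    if not screened:
        order = sorted(
            range(table.n_features),
            key=lambda i: (-report.mean_importance[i], table.feature_names[i]),
        )
        screened = [table.feature_names[order[0]]]
    sub = table.restrict_features(screened)
    imps = np.asarray(
        [report.mean_importance[report.feature_names.index(n)] for n in screened]
    )
    result = minimal_subset(
        sub, forest_spec, cap=cap, seed=seed + 1, importances=imps,
        tol_se=tol_se, positive_class=positive_class, redundancy_r=redundancy_r,
    )
    return result, report
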