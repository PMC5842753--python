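"""Flatten band connectivity tensors into a named subjects x features table.

Feature names follow the field's arrow notation ``band:SENDER->RECEIVER``
(e.g. ``alpha:ACC-R->Hipp-R``), ordered band-major, then sender, then
receiver.  Self-pairs (sender == receiver) are kept: the full 82-region grid
yields 82 x 82 x 3 = 20,172 features and the 14-region limbic subset
14 x 14 x 3 = 588, which only come out right when diagonals are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import ConnectivityTensor


@dataclass
class FeatureTable:
    """Subjects x named directed-connectivity features with class labels."""

    subject_ids: list
    feature_names: list
    values: np.ndarray  # (n_subjects, n_features)
    labels: list

    def __post_init__(self) -> None:
        self.subject_ids = list(self.subject_ids)
        self.feature_names = list(self.feature_names)
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.subject_ids) != n or len(self.labels) != n:
            raise ValueError("subject_ids/labels length must match the row count")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length must match the column count")
        if len(set(self.feature_names)) != m:
            raise ValueError("duplicate feature names")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def restrict_features(self, names) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.subject_ids, list(names), self.values[:, idx], self.labels)

    def restrict_subjects(self, keep) -> "FeatureTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return FeatureTable(
            [self.subject_ids[i] for i in keep],
            self.feature_names,
            self.values[keep],
            [self.labels[i] for i in keep],
        )

    def with_labels(self, labels) -> "FeatureTable":
        return FeatureTable(self.subject_ids, self.feature_names, self.values, list(labels))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "label", self.labels)
        frame.insert(0, "subject_id", self.subject_ids)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        frame = pd.read_csv(path, float_precision="round_trip")
        names = [c for c in frame.columns if c not in ("subject_id", "label")]
        return cls(
            subject_ids=frame["subject_id"].tolist(),
            feature_names=names,
            values=frame[names].to_numpy(dtype=float),
            labels=frame["label"].tolist(),
        )


def feature_name(band: str, sender: str, receiver: str) -> str:
    return f"{band}:{sender}->{receiver}"


def flatten(tensor: ConnectivityTensor, roi_subset=None) -> tuple[np.ndarray, list]:
    """One row of features from a band tensor: every ordered (sender, receiver)
    pair within the subset (self-pairs included), per band, band-major order.
    """
    if tensor.axis_kind != "bands":
        raise ValueError("flatten expects a band-reduced tensor")
    rois = list(tensor.roi_names) if roi_subset is None else list(roi_subset)
    index = {name: i for i, name in enumerate(tensor.roi_names)}
    unknown = [r for r in rois if r not in index]
    if unknown:
        raise KeyError(f"unknown ROI name(s): {unknown}")
    sel = np.array([index[r] for r in rois])
    names, values = [], []
    for k, band in enumerate(tensor.band_names):
        block = tensor.values[np.ix_(sel, sel, [k])][:, :, 0]  # (recv, send)
        for j, sender in enumerate(rois):
            for i, receiver in enumerate(rois):
                names.append(feature_name(band, sender, receiver))
                values.append(block[i, j])
    return np.asarray(values), names


def build_table(tensors, labels, subject_ids=None, roi_subset=None) -> FeatureTable:
    """Stack per-subject band tensors into a FeatureTable (rows follow input order)."""
    tensors = list(tensors)
    labels = list(labels)
    if len(tensors) != len(labels):
        raise ValueError("one label per tensor required")
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(tensors))]
    ref_names = None
    rows = []
    for sid, tensor in zip(subject_ids, tensors):
        row, names = flatten(tensor, roi_subset)
        if ref_names is None:
            ref_names, ref_sid = names, sid
        elif names != ref_names:
            raise ValueError(
                f"feature layout mismatch between subjects {ref_sid} and {sid}"
            )
        rows.append(row)
    return FeatureTable(
        subject_ids=list(subject_ids),
        feature_names=ref_names or [],
        values=np.vstack(rows) if rows else np.empty((0, 0)),
        labels=labels,
    )
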