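"""Directed functional connectivity: MVAR fit -> PDC -> wPDC -> band means.

The estimator follows the standard partial-directed-coherence construction.
For an MVAR model ``x_t = sum_r A_r x_{t-r} + e_t`` the spectral transfer
quantity is

    Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs)

and the (unweighted) PDC from sender j to receiver i at frequency f is

    PDC(i<-j, f) = |Abar(f)_ij| / sqrt(sum_k |Abar(f)_kj|^2),

i.e. column-normalized over the sender's outgoing column, so that
``sum_i PDC(i<-j, f)^2 = 1`` for every sender and frequency.  The weighted
variant (wPDC) multiplies each sender column by the sender's mean-square
amplitude in the epoch, max-normalized within the epoch, which damps
connections that originate from low-power signals.

Per subject, one model is fitted per epoch, wPDC is averaged across epochs on
a frequency grid, and the grid is reduced to theta/alpha/beta band means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}
DEFAULT_FREQS = np.arange(1.0, 31.0)  # 1-Hz grid, 1..30 Hz


@dataclass
class BandSpec:
    """Named frequency bands as closed-open [lo, hi) intervals in Hz.

    Closed-open intervals make every grid frequency belong to exactly one
    band even at shared edges (8 Hz goes to alpha, 12 Hz to beta).
    """

    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        intervals = sorted(self.bands.values())
        for lo, hi in intervals:
            if not lo < hi:
                raise ValueError(f"band interval [{lo}, {hi}) is empty")
        for (_, hi), (lo, _) in zip(intervals, intervals[1:]):
            if lo < hi:
                raise ValueError("band intervals overlap")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.bands)

    def grid_members(self, freqs: np.ndarray) -> dict[str, np.ndarray]:
        """Indices of the grid frequencies falling in each band."""
        freqs = np.asarray(freqs, dtype=float)
        out = {}
        for name, (lo, hi) in self.bands.items():
            members = np.flatnonzero((freqs >= lo) & (freqs < hi))
            if members.size == 0:
                raise ValueError(f"band {name} [{lo}, {hi}) captures no grid frequency")
            out[name] = members
        return out


@dataclass
class MVARModel:
    """Fitted (or ground-truth) multivariate autoregressive model."""

    order: int
    coeffs: np.ndarray  # (order, R, R); (i, j) = influence of channel j on i
    noise_cov: np.ndarray
    fs: float
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        if self.order < 1 or self.coeffs.ndim != 3:
            raise ValueError("order must be >= 1 and coeffs (order, R, R)")
        if self.coeffs.shape[0] != self.order:
            raise ValueError("coeffs first axis must equal order")
        if not np.isfinite(self.coeffs).all():
            raise ValueError("non-finite coefficients")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        self.roi_names = tuple(self.roi_names)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]


@dataclass
class ConnectivityTensor:
    """Directed connectivity, sender j -> receiver i, per frequency or band.

    ``values[i, j, k]`` is the flow from sender j into receiver i at the k-th
    frequency (``axis_kind='frequency_grid'``) or band (``axis_kind='bands'``).
    """

    values: np.ndarray  # (R, R, F), nonnegative
    axis_kind: str  # 'frequency_grid' | 'bands'
    freqs_or_bands: object  # ndarray of Hz, or BandSpec
    roi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_names = tuple(self.roi_names)
        if self.axis_kind not in ("frequency_grid", "bands"):
            raise ValueError("axis_kind must be 'frequency_grid' or 'bands'")
        R = len(self.roi_names)
        if self.values.shape[:2] != (R, R):
            raise ValueError("values must be (R, R, F)")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("connectivity values must be finite and >= 0")

    @property
    def band_names(self) -> tuple[str, ...]:
        if self.axis_kind != "bands":
            raise ValueError("not a band-reduced tensor")
        return self.freqs_or_bands.names

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: sender, receiver, band_or_freq, value."""
        if self.axis_kind == "bands":
            axis_labels = list(self.freqs_or_bands.names)
        else:
            axis_labels = [float(f) for f in self.freqs_or_bands]
        rows = []
        for k, lab in enumerate(axis_labels):
            for j, sender in enumerate(self.roi_names):
                for i, receiver in enumerate(self.roi_names):
                    rows.append((sender, receiver, lab, self.values[i, j, k]))
        return pd.DataFrame(rows, columns=["sender", "receiver", "band_or_freq", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConnectivityTensor":
        """Rebuild a tensor from the long format written by :meth:`to_frame`."""
        senders = list(dict.fromkeys(frame["sender"]))
        axis_labels = list(dict.fromkeys(frame["band_or_freq"]))
        R, F = len(senders), len(axis_labels)
        if frame["band_or_freq"].dtype == object:
            axis_kind = "bands"
            bands = BandSpec({name: DEFAULT_BANDS[name] for name in axis_labels})
        else:
            axis_kind = "frequency_grid"
            bands = np.asarray(axis_labels, dtype=float)
        index = {name: i for i, name in enumerate(senders)}
        k_index = {lab: k for k, lab in enumerate(axis_labels)}
        values = np.zeros((R, R, F))
        for sender, receiver, lab, value in frame.itertuples(index=False):
            values[index[receiver], index[sender], k_index[lab]] = value
        return cls(values=values, axis_kind=axis_kind, freqs_or_bands=bands,
                   roi_names=tuple(senders))

    @classmethod
    def from_csv(cls, path) -> "ConnectivityTensor":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def to_npz(self, path) -> None:
        """Compact binary container (numpy .npz)."""
        if self.axis_kind == "bands":
            axis = np.array(list(self.freqs_or_bands.names))
            edges = np.array([self.freqs_or_bands.bands[n] for n in axis])
        else:
            axis = np.asarray(self.freqs_or_bands, dtype=float)
            edges = np.empty((0, 2))
        np.savez_compressed(
            path, values=self.values, axis_kind=self.axis_kind,
            axis=axis, band_edges=edges, roi_names=np.array(self.roi_names),
        )

    @classmethod
    def from_npz(cls, path) -> "ConnectivityTensor":
        with np.load(path, allow_pickle=False) as data:
            kind = str(data["axis_kind"])
            if kind == "bands":
                axis = BandSpec({
                    name: (float(lo), float(hi))
                    for name, (lo, hi) in zip(data["axis"], data["band_edges"])
                })
            else:
                axis = data["axis"].astype(float)
            return cls(values=data["values"], axis_kind=kind,
                       freqs_or_bands=axis,
                       roi_names=tuple(str(n) for n in data["roi_names"]))


def fit_mvar(epoch: np.ndarray, order: int, fs: float, roi_names=()) -> MVARModel:
    """Ordinary-least-squares MVAR fit of one epoch (channels x samples).

    Every channel is regressed on the ``order`` lags of all channels jointly
    (no intercept; source time series are zero-mean by construction).  The
    innovation covariance is the residual covariance with a degrees-of-freedom
    correction.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2:
        raise ValueError("epoch must be a (R, n_samples) array")
    R, n = epoch.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if n <= R * order + order:
        raise ValueError(
            f"epoch too short: need n_samples > R*order + order = {R * order + order}, "
            f"got {n}"
        )
    x = epoch.T  # (n, R)
    Y = x[order:]
    Z = np.concatenate([x[order - r - 1 : n - r - 1] for r in range(order)], axis=1)
    B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < R * order:
        raise np.linalg.LinAlgError(
            f"rank-deficient regressor matrix (rank {rank} < {R * order})"
        )
    resid = Y - Z @ B
    dof = max(Y.shape[0] - R * order, 1)
    noise_cov = resid.T @ resid / dof
    coeffs = B.T.reshape(R, order, R).transpose(1, 0, 2)
    return MVARModel(order=order, coeffs=coeffs, noise_cov=noise_cov, fs=fs,
                     roi_names=tuple(roi_names))


def select_order(
    epoch: np.ndarray, max_order: int, criterion: str = "bic", fs: float = 250.0
) -> int:
    """Information-criterion model-order selection over 1..max_order.

    All candidate orders are fitted on the common sample (the first
    ``max_order`` samples are dropped for every candidate) so that criteria
    are comparable.  AIC = ln det(Sigma_ML) + 2 m / n, BIC uses ln(n) m / n,
    with m = p R^2 parameters.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if criterion not in ("aic", "bic"):
        raise ValueError("criterion must be 'aic' or 'bic'")
    epoch = np.asarray(epoch, dtype=float)
    R, n = epoch.shape
    x = epoch.T
    best, best_ic = None, np.inf
    for p in range(1, max_order + 1):
        try:
            Y = x[max_order:]
            Z = np.concatenate([x[max_order - r - 1 : n - r - 1] for r in range(p)], axis=1)
            B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
            if rank < R * p:
                continue
        except np.linalg.LinAlgError:
            continue
        resid = Y - Z @ B
        n_eff = Y.shape[0]
        sigma_ml = resid.T @ resid / n_eff
        sign, logdet = np.linalg.slogdet(sigma_ml)
        if sign <= 0:
            continue
        m = p * R * R
        penalty = 2.0 * m / n_eff if criterion == "aic" else np.log(n_eff) * m / n_eff
        ic = logdet + penalty
        if ic < best_ic:
            best, best_ic = p, ic
    if best is None:
        raise ValueError("no candidate order could be fitted")
    return best


def transfer_matrix(model: MVARModel, freqs) -> np.ndarray:
    """Abar(f) = I - sum_r A_r exp(-i 2 pi f r / fs), shape (F, R, R)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    lags = np.arange(1, model.order + 1)
    z = np.exp(-2j * np.pi * freqs[:, None] * lags[None, :] / model.fs)  # (F, p)
    R = model.n_channels
    return np.eye(R)[None] - np.einsum("fr,rij->fij", z, model.coeffs)


def pdc_spectrum(model: MVARModel, freqs) -> ConnectivityTensor:
    """Unweighted PDC of the model on a frequency grid (sender-column normalized)."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if ((freqs <= 0) | (freqs >= model.fs / 2)).any():
        raise ValueError("all frequencies must lie in (0, fs/2)")
    A = np.abs(transfer_matrix(model, freqs))  # (F, R, R)
    col_norm = np.sqrt((A**2).sum(axis=1))  # (F, R) over receivers k
    if (col_norm == 0).any():
        raise ValueError("degenerate model: a sender column has zero norm")
    pdc = A / col_norm[:, None, :]
    return ConnectivityTensor(
        values=pdc.transpose(1, 2, 0),
        axis_kind="frequency_grid",
        freqs_or_bands=freqs,
        roi_names=model.roi_names or tuple(f"ch{c}" for c in range(model.n_channels)),
    )


def sender_weights(epoch: np.ndarray) -> np.ndarray:
    """Per-channel mean-square amplitude, max-normalized within the epoch."""
    epoch = np.asarray(epoch, dtype=float)
    power = (epoch**2).mean(axis=1)
    if (power == 0).any():
        dead = np.flatnonzero(power == 0)
        raise ValueError(f"zero-power channel(s) {dead.tolist()}; weights undefined")
    return power / power.max()


def weight_pdc(pdc: ConnectivityTensor, epoch: np.ndarray,
               model: MVARModel | None = None) -> ConnectivityTensor:
    """wPDC: scale each sender column of the PDC by the sender's power weight."""
    if pdc.axis_kind != "frequency_grid":
        raise ValueError("weighting applies to the frequency-grid PDC")
    w = sender_weights(epoch)
    if w.size != len(pdc.roi_names):
        raise ValueError("epoch channel count does not match the PDC tensor")
    return ConnectivityTensor(
        values=pdc.values * w[None, :, None],
        axis_kind="frequency_grid",
        freqs_or_bands=pdc.freqs_or_bands,
        roi_names=pdc.roi_names,
    )


def band_reduce(tensor: ConnectivityTensor, bands: BandSpec) -> ConnectivityTensor:
    """Arithmetic mean of grid values within each closed-open band interval."""
    if tensor.axis_kind != "frequency_grid":
        raise ValueError("band reduction needs a frequency-grid tensor")
    members = bands.grid_members(np.asarray(tensor.freqs_or_bands))
    values = np.stack(
        [tensor.values[:, :, members[name]].mean(axis=2) for name in bands.names],
        axis=2,
    )
    return ConnectivityTensor(
        values=values, axis_kind="bands", freqs_or_bands=bands, roi_names=tensor.roi_names
    )


def subject_connectivity(
    subject,
    order: int | str = 5,
    freqs: np.ndarray = DEFAULT_FREQS,
    bands: BandSpec | None = None,
    max_order: int = 10,
    weighted: bool = True,
) -> ConnectivityTensor:
    """Band-reduced wPDC of one subject: per-epoch fit, epoch mean, band mean.

    ``order`` is either a fixed lag count (default 5, i.e. 20 ms of history at
    250 Hz) or ``'aic'``/``'bic'`` to select the order on the subject's first
    epoch and reuse it for all epochs (one order per subject keeps features
    comparable across epochs).
    """
    bands = bands or BandSpec()
    if subject.n_epochs < 1:
        raise ValueError("subject has no epochs")
    if isinstance(order, str):
        order = select_order(subject.epochs[0], max_order=max_order,
                             criterion=order, fs=subject.fs)
    freqs = np.asarray(freqs, dtype=float)
    acc = None
    for e in range(subject.n_epochs):
        epoch = subject.epochs[e]
        try:
            model = fit_mvar(epoch, order=order, fs=subject.fs,
                             roi_names=subject.roi_names)
            tensor = pdc_spectrum(model, freqs)
            if weighted:
                tensor = weight_pdc(tensor, epoch, model)
        except Exception as exc:
            raise RuntimeError(
                f"connectivity failed on epoch {e} of {subject.subject_id}"
            ) from exc
        acc = tensor.values if acc is None else acc + tensor.values
    mean_tensor = ConnectivityTensor(
        values=acc / subject.n_epochs,
        axis_kind="frequency_grid",
        freqs_or_bands=freqs,
        roi_names=subject.roi_names,
    )
    return band_reduce(mean_tensor, bands)
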