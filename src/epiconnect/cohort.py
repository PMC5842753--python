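"""Synthetic cohorts of source-space ROI time series with known directed networks.

Real inputs to this kind of analysis are source time courses obtained by
electrical source imaging of high-density EEG.  Since those cannot be shared,
the cohort generator produces subjects whose regional signals come from stable
multivariate autoregressive (MVAR) processes with planted, group-specific
directed couplings.  Partial directed coherence is exactly defined on an MVAR
process, so the generator gives every downstream stage a known answer:
connectivity estimation can be checked against the generating coefficients and
classification against the planted group differences.

Three groups are emulated: healthy controls, a left-TLE-like group and a
right-TLE-like group.  Pathology is planted as reduced outflow from the
ipsilateral hippocampus- and anterior-cingulate-labelled nodes, mirrored
between hemispheres for the two patient groups.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("CONTROL", "LTLE", "RTLE")

#: The 14 preselected temporal/limbic regions (left and right): hippocampus,
#: amygdala, parahippocampus, anterior and posterior cingulate, olfactory
#: cortex and medial temporal pole.
DEFAULT_ROI_NAMES = (
    "Hipp-L", "Hipp-R",
    "Amyg-L", "Amyg-R",
    "PHipp-L", "PHipp-R",
    "ACC-L", "ACC-R",
    "PCC-L", "PCC-R",
    "Olf-L", "Olf-R",
    "TPMid-L", "TPMid-R",
)

#: Directed coupling edges of the control network, written on region stems and
#: instantiated ipsilaterally in both hemispheres (mirror-symmetric).  The
#: edge set is feedforward (acyclic), so the couplings leave the companion
#: eigenvalues of the per-region oscillators untouched and can be strong
#: without threatening stability.  Senders with stems in EFFECT_SENDER_STEMS
#: are the ones whose outflow the patient groups lose.
BASE_EDGE_STEMS = (
    ("Hipp", "Amyg"),
    ("Hipp", "PHipp"),
    ("Hipp", "ACC"),
    ("Hipp", "TPMid"),
    ("ACC", "Amyg"),
    ("ACC", "PCC"),
    ("ACC", "Olf"),
    ("PHipp", "TPMid"),
    ("PCC", "Olf"),
)

EFFECT_SENDER_STEMS = ("Hipp", "ACC")

#: The outflow edges the patient groups lose (a subset of each effect
#: sender's projections).  Reducing a subset rather than the sender's whole
#: outgoing column matters: partial directed coherence is normalized over the
#: sender's column, so a uniform scaling of all outflows would largely cancel
#: in the ratio near the sender's resonance, whereas losing specific
#: projections shows up directly.
EFFECT_EDGE_STEMS = (
    ("Hipp", "Amyg"),
    ("Hipp", "ACC"),
    ("ACC", "Amyg"),
    ("ACC", "PCC"),
)

_STABILITY_MARGIN = 0.95


@dataclass(frozen=True)
class EdgeEffect:
    """One planted modification of a directed coupling coefficient."""

    sender: str
    receiver: str
    lag: int  # 1-based lag index
    delta: float


@dataclass
class NetworkTemplate:
    """Ground-truth MVAR network for one group.

    ``coeffs[r]`` is the R x R coefficient matrix at lag r+1; entry (i, j) is
    the influence of region j on region i.  ``effect_spec`` lists the planted
    deviations from the control network (already applied to ``coeffs``).
    """

    group_label: str
    roi_names: tuple[str, ...]
    order: int
    coeffs: np.ndarray  # (order, R, R)
    noise_cov: np.ndarray  # (R, R)
    effect_spec: tuple[EdgeEffect, ...] = ()

    def __post_init__(self) -> None:
        self.roi_names = tuple(self.roi_names)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        R = len(self.roi_names)
        if self.group_label not in GROUPS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if self.order < 1 or self.coeffs.shape != (self.order, R, R):
            raise ValueError(
                f"coeffs must have shape (order, R, R) = ({self.order}, {R}, {R}); "
                f"got {self.coeffs.shape}"
            )
        if self.noise_cov.shape != (R, R) or not np.allclose(
            self.noise_cov, self.noise_cov.T
        ):
            raise ValueError("noise_cov must be a symmetric R x R matrix")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise ValueError("noise_cov must be positive definite")
        valid = set(self.roi_names)
        for e in self.effect_spec:
            if e.sender not in valid or e.receiver not in valid:
                raise ValueError(f"effect edge {e} names an unknown ROI")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @property
    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coeffs)

    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0


@dataclass
class SubjectEpochs:
    """Epoch-segmented ROI time series for one subject."""

    subject_id: str
    group_label: str
    fs: float
    epochs: np.ndarray  # (n_epochs, R, n_samples)
    roi_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a (n_epochs, R, n_samples) array")
        if not np.isfinite(self.epochs).all():
            raise ValueError(f"non-finite samples in subject {self.subject_id}")
        if self.roi_names and len(self.roi_names) != self.epochs.shape[1]:
            raise ValueError("roi_names length does not match channel axis")
        self.roi_names = tuple(self.roi_names)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_rois(self) -> int:
        return self.epochs.shape[1]


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a lag-coefficient stack."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, R, _ = coeffs.shape
    companion = np.zeros((p * R, p * R))
    companion[:R] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        companion[R:, : R * (p - 1)] = np.eye(R * (p - 1))
    return float(np.abs(np.linalg.eigvals(companion)).max())


def stationary_covariance(coeffs: np.ndarray, noise_cov: np.ndarray) -> np.ndarray:
    """Analytic stationary covariance of the MVAR process (Lyapunov solve).

    Returns the R x R zero-lag covariance, obtained from the companion-form
    discrete Lyapunov equation.
    """
    from scipy.linalg import solve_discrete_lyapunov

    coeffs = np.asarray(coeffs, dtype=float)
    p, R, _ = coeffs.shape
    if companion_spectral_radius(coeffs) >= 1.0:
        raise ValueError("process is not stable; stationary covariance undefined")
    companion = np.zeros((p * R, p * R))
    companion[:R] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        companion[R:, : R * (p - 1)] = np.eye(R * (p - 1))
    Q = np.zeros((p * R, p * R))
    Q[:R, :R] = noise_cov
    big = solve_discrete_lyapunov(companion, Q)
    return big[:R, :R]


def _split_roi(name: str) -> tuple[str, str]:
    """Split 'Hipp-L' into ('Hipp', 'L'); raise if not a sided name."""
    if name.endswith("-L") or name.endswith("-R"):
        return name[:-2], name[-1]
    raise ValueError(f"ROI name {name!r} lacks an -L/-R hemisphere suffix")


def mirror_roi(name: str) -> str:
    """Contralateral homologue of a sided ROI name."""
    stem, side = _split_roi(name)
    return f"{stem}-{'R' if side == 'L' else 'L'}"


def _check_paired(roi_names) -> None:
    names = set(roi_names)
    if len(roi_names) % 2:
        raise ValueError("roi_names must have even length (left/right pairs)")
    for name in roi_names:
        if mirror_roi(name) not in names:
            raise ValueError(f"ROI {name} has no contralateral partner")


def _base_edges(roi_names) -> list[tuple[str, str]]:
    """Instantiate the stem-level edge list on the given sided ROI set."""
    names = set(roi_names)
    edges = []
    for s_stem, r_stem in BASE_EDGE_STEMS:
        for side in ("L", "R"):
            sender = f"{s_stem}-{side}"
            receiver = f"{r_stem}-{side}"
            if sender in names and receiver in names and sender != receiver:
                edges.append((sender, receiver))
    if not edges:
        # Generic fallback for ROI sets without the curated stems: couple
        # contralateral homologues in both directions (note this creates
        # 2-cycles, so such couplings may be rescaled for stability).
        for name in roi_names:
            edges.append((name, mirror_roi(name)))
    return edges


def make_template(
    group_label: str,
    roi_names=DEFAULT_ROI_NAMES,
    order: int = 2,
    base_coupling_strength: float = 0.25,
    effect_size: float = 0.0,
    contralateral_fraction: float = 0.5,
    seed: int = 0,
    noise_scale: float = 1.0,
    max_rescale_attempts: int = 30,
) -> NetworkTemplate:
    """Build the ground-truth network template for one group.

    Each region is an AR(2) oscillator (pole modulus 0.65, resonant frequency
    drawn per region from 4-25 Hz at a 250 Hz clock, so the theta, alpha and
    beta bands all carry structure; reproducible from ``seed``), coupled by
    lag-1 directed edges of strength ``base_coupling_strength`` along the
    curated limbic edge list.  Innovation variances are equalized on the
    effect-free base so that stationary channel power is comparable across
    regions, as it is for source-projected EEG.  For the patient groups,
    designated outflow projections of the ipsilateral hippocampus and
    anterior cingulate are reduced by the fraction ``effect_size``, and their
    contralateral homologues by ``contralateral_fraction * effect_size``
    (temporal lobe epilepsy alters networks bilaterally with ipsilateral
    predominance); the two patient templates are exact mirror images of each
    other.

    If the assembled coefficient set is unstable, the off-diagonal couplings
    are shrunk geometrically; a bounded number of attempts is made before
    raising.
    """
    if group_label not in GROUPS:
        raise ValueError(f"group_label must be one of {GROUPS}")
    if order < 1:
        raise ValueError("order must be >= 1")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    roi_names = tuple(roi_names)
    _check_paired(roi_names)
    R = len(roi_names)
    idx = {name: i for i, name in enumerate(roi_names)}

    rng = np.random.default_rng(seed)
    coeffs = np.zeros((order, R, R))
    rho = 0.65
    if order >= 2:
        # per-region resonance; the same seed gives every group the same base
        f0 = rng.uniform(4.0, 25.0, size=R)
        theta = 2 * np.pi * f0 / 250.0
        coeffs[0][np.diag_indices(R)] = 2 * rho * np.cos(theta)
        coeffs[1][np.diag_indices(R)] += -(rho**2)
    else:
        coeffs[0][np.diag_indices(R)] = 0.55

    edges = _base_edges(roi_names)
    for sender, receiver in edges:
        coeffs[0, idx[receiver], idx[sender]] = base_coupling_strength

    # Stabilize the shared effect-free base first, so every group's template
    # differs from CONTROL only by its effect_spec.  The curated edge set is
    # acyclic and never triggers this; the generic fallback can.
    off_mask = ~np.eye(R, dtype=bool)
    for _ in range(max_rescale_attempts):
        if companion_spectral_radius(coeffs) < _STABILITY_MARGIN:
            break
        coeffs[:, off_mask] *= 0.9
    else:
        raise RuntimeError(
            "could not stabilize template after rescaling; spectral radius = "
            f"{companion_spectral_radius(coeffs):.4f}"
        )

    # Equalize stationary channel power on the shared base (innovation
    # variances are part of the common background, not of the group effect).
    sigma2 = np.ones(R)
    for _ in range(12):
        v = np.diag(stationary_covariance(coeffs, np.diag(sigma2)))
        sigma2 = np.clip(sigma2 / v, 0.05, 1.0)

    effect_side = {"LTLE": "L", "RTLE": "R"}.get(group_label)
    effect_spec: list[EdgeEffect] = []
    if effect_side is not None and effect_size > 0:
        contra_side = "R" if effect_side == "L" else "L"
        ipsi = {
            (f"{s}-{effect_side}", f"{r}-{effect_side}") for s, r in EFFECT_EDGE_STEMS
        } & set(edges)
        contra = {
            (f"{s}-{contra_side}", f"{r}-{contra_side}") for s, r in EFFECT_EDGE_STEMS
        } & set(edges)
        if not ipsi:
            raise ValueError(
                "no effect edges (Hipp/ACC outflow) present for a patient group"
            )
        for sender, receiver in edges:
            if (sender, receiver) in ipsi:
                frac = effect_size
            elif (sender, receiver) in contra:
                frac = contralateral_fraction * effect_size
            else:
                continue
            delta = -frac * coeffs[0, idx[receiver], idx[sender]]
            effect_spec.append(EdgeEffect(sender, receiver, lag=1, delta=delta))
    for e in effect_spec:
        coeffs[e.lag - 1, idx[e.receiver], idx[e.sender]] += e.delta
    if companion_spectral_radius(coeffs) >= 1.0:
        raise RuntimeError(
            "template unstable after planting effects; spectral radius = "
            f"{companion_spectral_radius(coeffs):.4f}"
        )

    return NetworkTemplate(
        group_label=group_label,
        roi_names=roi_names,
        order=order,
        coeffs=coeffs,
        noise_cov=noise_scale * np.diag(sigma2),
        effect_spec=tuple(effect_spec),
    )


def _simulate_epochs(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_epochs: int,
    n_samples: int,
    burn_in: int,
    rng: np.random.Generator,
    obs_noise_sd: float = 0.0,
) -> np.ndarray:
    """Simulate independent epochs of the MVAR process, vectorized over epochs."""
    p, R, _ = coeffs.shape
    total = burn_in + n_samples
    chol = np.linalg.cholesky(noise_cov)
    innov = rng.standard_normal((n_epochs, total, R)) @ chol.T
    x = np.zeros((n_epochs, total, R))
    for t in range(total):
        acc = innov[:, t].copy()
        for r in range(min(p, t)):
            acc += x[:, t - r - 1] @ coeffs[r].T
        x[:, t] = acc
    out = x[:, burn_in:].transpose(0, 2, 1).copy()  # (E, R, S)
    if obs_noise_sd > 0:
        out += obs_noise_sd * rng.standard_normal(out.shape)
    return out


def simulate_subject(
    template: NetworkTemplate,
    n_epochs: int = 60,
    epoch_seconds: float = 1.0,
    fs: float = 250.0,
    subject_jitter_sd: float = 0.025,
    seed: int = 0,
    subject_id: str = "sub-000",
    obs_noise_sd: float = 0.1,
    max_jitter_attempts: int = 50,
) -> SubjectEpochs:
    """Simulate one subject: jitter the template once, then draw independent epochs.

    Inter-subject variability is i.i.d. Gaussian jitter (sd ``subject_jitter_sd``)
    on the nonzero template coefficients only, so the sparsity pattern of the
    network is common to all subjects.  The jittered model is re-checked for
    stability (fresh jitter is drawn on failure, a bounded number of times).
    Each epoch is an independent realization with a discarded burn-in of
    10 x order samples; ``obs_noise_sd`` adds white measurement noise on top
    of the process output.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if fs <= 0 or epoch_seconds <= 0:
        raise ValueError("fs and epoch_seconds must be positive")
    if not template.is_stable():
        raise ValueError("template is unstable")
    rng = np.random.default_rng(seed)
    nz = template.coeffs != 0

    coeffs = None
    for _ in range(max_jitter_attempts):
        cand = template.coeffs.copy()
        if subject_jitter_sd > 0:
            cand[nz] += subject_jitter_sd * rng.standard_normal(int(nz.sum()))
        if companion_spectral_radius(cand) < 1.0:
            coeffs = cand
            break
    if coeffs is None:
        raise RuntimeError(
            f"jittered model unstable after {max_jitter_attempts} attempts "
            f"(subject {subject_id})"
        )

    n_samples = int(round(epoch_seconds * fs))
    burn_in = 10 * template.order
    epochs = _simulate_epochs(
        coeffs, template.noise_cov, n_epochs, n_samples, burn_in, rng, obs_noise_sd
    )
    if not np.isfinite(epochs).all():
        raise RuntimeError(f"non-finite simulation output for subject {subject_id}")
    return SubjectEpochs(
        subject_id=subject_id,
        group_label=template.group_label,
        fs=fs,
        epochs=epochs,
        roi_names=template.roi_names,
    )


def simulate_cohort(
    n_control: int = 35,
    n_ltle: int = 20,
    n_rtle: int = 20,
    template_params: dict | None = None,
    seed: int = 0,
    n_epochs: int = 60,
    epoch_seconds: float = 1.0,
    fs: float = 250.0,
    subject_jitter_sd: float = 0.025,
    obs_noise_sd: float = 0.1,
) -> tuple[list[SubjectEpochs], dict]:
    """Simulate a three-group cohort and return (subjects, manifest).

    ``template_params`` are forwarded to :func:`make_template` (all groups share
    the same template seed and base network; only the planted effects differ).
    The manifest records every parameter and per-subject seed needed to
    reproduce the arrays exactly.
    """
    if min(n_control, n_ltle, n_rtle) < 0:
        raise ValueError("group sizes must be >= 0")
    template_params = dict(template_params or {})
    template_params.setdefault("seed", seed)
    rng = np.random.default_rng(seed)

    plan = (
        [("CONTROL", k) for k in range(n_control)]
        + [("LTLE", k) for k in range(n_ltle)]
        + [("RTLE", k) for k in range(n_rtle)]
    )
    templates = {}
    subjects: list[SubjectEpochs] = []
    manifest_subjects = []
    for i, (group, _) in enumerate(plan):
        if group not in templates:
            templates[group] = make_template(group, **template_params)
        sid = f"sub-{i:03d}"
        s_seed = int(rng.integers(0, 2**31 - 1))
        try:
            subj = simulate_subject(
                templates[group],
                n_epochs=n_epochs,
                epoch_seconds=epoch_seconds,
                fs=fs,
                subject_jitter_sd=subject_jitter_sd,
                seed=s_seed,
                subject_id=sid,
                obs_noise_sd=obs_noise_sd,
            )
        except Exception as exc:  # attach the subject id to any failure
            raise RuntimeError(f"simulation failed for subject {sid}") from exc
        subjects.append(subj)
        manifest_subjects.append({"subject_id": sid, "group": group, "seed": s_seed})

    manifest = {
        "generator": "epiconnect.cohort.simulate_cohort",
        "seed": seed,
        "group_sizes": {"CONTROL": n_control, "LTLE": n_ltle, "RTLE": n_rtle},
        "n_epochs": n_epochs,
        "epoch_seconds": epoch_seconds,
        "fs": fs,
        "subject_jitter_sd": subject_jitter_sd,
        "obs_noise_sd": obs_noise_sd,
        "template_params": template_params,
        "roi_names": list(subjects[0].roi_names) if subjects else [],
        "subjects": manifest_subjects,
    }
    return subjects, manifest


def cohort_from_manifest(manifest: dict) -> list[SubjectEpochs]:
    """Re-simulate a cohort exactly from its manifest."""
    template_params = dict(manifest["template_params"])
    templates: dict[str, NetworkTemplate] = {}
    subjects = []
    for entry in manifest["subjects"]:
        group = entry["group"]
        if group not in templates:
            templates[group] = make_template(group, **template_params)
        subjects.append(
            simulate_subject(
                templates[group],
                n_epochs=manifest["n_epochs"],
                epoch_seconds=manifest["epoch_seconds"],
                fs=manifest["fs"],
                subject_jitter_sd=manifest["subject_jitter_sd"],
                seed=entry["seed"],
                subject_id=entry["subject_id"],
                obs_noise_sd=manifest["obs_noise_sd"],
            )
        )
    return subjects


# ---------------------------------------------------------------------------
# Cohort on disk: one CSV per subject (epoch index column + one column per
# ROI, rows are samples) plus a JSON manifest.
# ---------------------------------------------------------------------------

def write_cohort(subjects: list[SubjectEpochs], manifest: dict, outdir) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = dict(manifest)
    files = {}
    for subj in subjects:
        E, R, S = subj.epochs.shape
        frame = pd.DataFrame(
            subj.epochs.transpose(0, 2, 1).reshape(E * S, R),
            columns=list(subj.roi_names),
        )
        frame.insert(0, "epoch", np.repeat(np.arange(E), S))
        path = outdir / f"{subj.subject_id}.csv"
        frame.to_csv(path, index=False, float_format="%.10g")
        files[subj.subject_id] = path.name
    manifest["files"] = files
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


def read_cohort(indir) -> tuple[list[SubjectEpochs], dict]:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    subjects = []
    groups = {e["subject_id"]: e["group"] for e in manifest["subjects"]}
    for sid, fname in manifest["files"].items():
        frame = pd.read_csv(indir / fname)
        roi_names = [c for c in frame.columns if c != "epoch"]
        epoch_ids = frame["epoch"].to_numpy()
        n_epochs = int(epoch_ids.max()) + 1
        S = int((epoch_ids == 0).sum())
        values = frame[roi_names].to_numpy().reshape(n_epochs, S, len(roi_names))
        subjects.append(
            SubjectEpochs(
                subject_id=sid,
                group_label=groups[sid],
                fs=manifest["fs"],
                epochs=values.transpose(0, 2, 1),
                roi_names=tuple(roi_names),
            )
        )
    return subjects, manifest
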