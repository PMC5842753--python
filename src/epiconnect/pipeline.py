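"""End-to-end orchestration: simulate -> connectivity -> features -> selection
-> interaction -> classification, from a single config with one master seed.

Every stochastic stage derives its seed deterministically from
``RunConfig.seed``, so re-running a config reproduces every artifact
byte-for-byte.  All intermediate artifacts are plain text (CSV/JSON) so runs
can be diffed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, cohort, connectivity, features, interaction, selection
from .classify import SelectionConfig
from .forest import BalancedForestSpec


@dataclass
class CohortConfig:
    n_control: int = 35
    n_ltle: int = 20
    n_rtle: int = 20
    n_epochs: int = 60
    epoch_seconds: float = 1.0
    fs: float = 250.0
    order: int = 2
    base_coupling_strength: float = 0.25
    effect_size: float = 0.8
    contralateral_fraction: float = 0.5
    subject_jitter_sd: float = 0.025
    obs_noise_sd: float = 0.1


@dataclass
class ConnectivityConfig:
    order: int | str = 5  # fixed lag count, or 'aic'/'bic'
    freq_lo: float = 1.0
    freq_hi: float = 30.0
    freq_step: float = 1.0
    weighted: bool = True

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.freq_lo, self.freq_hi + self.freq_step / 2, self.freq_step)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results/run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    forest: BalancedForestSpec = field(default_factory=BalancedForestSpec)
    interaction_repeats: int = 10
    write_timeseries: bool = False
    write_connectivity: bool = True

    def validate(self) -> None:
        c = self.cohort
        if min(c.n_control, c.n_ltle, c.n_rtle) < 0 or c.n_epochs < 1:
            raise ValueError("cohort sizes and epoch count must be non-negative/positive")
        if c.fs <= 0 or c.epoch_seconds <= 0:
            raise ValueError("fs and epoch_seconds must be positive")
        connectivity.BandSpec()  # default bands must be well-formed
        if self.connectivity.freq_lo <= 0:
            raise ValueError("frequency grid must start above 0 Hz")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (
            ("cohort", CohortConfig),
            ("connectivity", ConnectivityConfig),
            ("selection", SelectionConfig),
            ("forest", BalancedForestSpec),
        ):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def scaled_config(seed: int = 0, outdir: str = "results/run") -> RunConfig:
    """The strong-effect configuration at the reduced forest sizes used for
    routine runs: 300-tree forests and 6 screening repeats per fold keep a
    full 75-subject LOOCV to a few minutes on one core (see docs/methods.md);
    the cohort itself is at full scale (35/20/20 subjects, 60 x 1 s epochs)."""
    return RunConfig(
        seed=seed,
        outdir=outdir,
        selection=SelectionConfig(n_repeats=6),
        forest=BalancedForestSpec(n_trees=300),
        interaction_repeats=10,
    )


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(v) for v in np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write all artifacts under ``config.outdir``.

    Returns a dict of artifact paths.  Fails fast with the offending stage
    and subject named in the exception chain.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    s_cohort, s_select, s_inter, s_classify = _stage_seeds(config.seed, 4)
    artifacts: dict[str, str] = {"config": str(outdir / "config.yaml")}
    log_lines = [
        f"master_seed={config.seed}",
        f"stage_seeds simulate={s_cohort} select={s_select} "
        f"interaction={s_inter} classify={s_classify}",
    ]

    def _log(line: str) -> None:
        log_lines.append(line)
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    # -- simulate ----------------------------------------------------------
    c = config.cohort
    subjects, manifest = cohort.simulate_cohort(
        n_control=c.n_control, n_ltle=c.n_ltle, n_rtle=c.n_rtle,
        template_params={
            "order": c.order,
            "base_coupling_strength": c.base_coupling_strength,
            "effect_size": c.effect_size,
            "contralateral_fraction": c.contralateral_fraction,
        },
        seed=s_cohort, n_epochs=c.n_epochs, epoch_seconds=c.epoch_seconds,
        fs=c.fs, subject_jitter_sd=c.subject_jitter_sd, obs_noise_sd=c.obs_noise_sd,
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    artifacts["manifest"] = str(outdir / "manifest.json")
    _log(f"simulate: {len(subjects)} subjects written to manifest")
    if config.write_timeseries:
        cohort.write_cohort(subjects, manifest, outdir / "timeseries")
        artifacts["timeseries"] = str(outdir / "timeseries")

    # -- connectivity + features ------------------------------------------
    tensors = []
    conn_dir = outdir / "connectivity"
    if config.write_connectivity:
        conn_dir.mkdir(exist_ok=True)
    for subj in subjects:
        tensor = connectivity.subject_connectivity(
            subj, order=config.connectivity.order,
            freqs=config.connectivity.freqs, weighted=config.connectivity.weighted,
        )
        tensors.append(tensor)
        if config.write_connectivity:
            tensor.to_csv(conn_dir / f"{subj.subject_id}_bands.csv")
    table = features.build_table(
        tensors, labels=[s.group_label for s in subjects],
        subject_ids=[s.subject_id for s in subjects],
    )
    table.to_csv(outdir / "features.csv")
    artifacts["features"] = str(outdir / "features.csv")
    _log(f"connectivity: {table.n_subjects} x {table.n_features} feature table")

    # -- cohort-level selection + interaction (diagnosis & lateralization) -
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
    sel_seeds = _stage_seeds(s_select, len(tasks))
    int_seeds = _stage_seeds(s_inter, len(tasks))
    for (name, (task_table, pos)), s1, s2 in zip(tasks.items(), sel_seeds, int_seeds):
        sel, report = selection.screen_and_select(
            task_table, config.forest,
            alpha=config.selection.alpha, n_repeats=config.selection.n_repeats,
            tol_se=config.selection.tol_se, seed=s1, positive_class=pos,
            significance=config.selection.significance,
        )
        sel.to_frame().to_csv(outdir / f"selection_{name}.csv", index=False)
        artifacts[f"selection_{name}"] = str(outdir / f"selection_{name}.csv")
        _log(f"selection[{name}]: {len(sel.selected)} of cap {sel.cap}: "
             + ", ".join(sel.selected))
        if len(sel.selected) >= 2:
            mat = interaction.interaction_matrix(
                task_table.restrict_features(sel.selected), config.forest,
                n_repeats=config.interaction_repeats, seed=s2, positive_class=pos,
            )
            mat.to_csv(outdir / f"interaction_{name}.csv")
            artifacts[f"interaction_{name}"] = str(outdir / f"interaction_{name}.csv")

    # -- sequential LOOCV system ------------------------------------------
    seq = classify.sequential_loocv(table, config.selection, config.forest,
                                    seed=s_classify)
    report_out = {
        "diagnosis": seq.diagnosis.report().to_dict(),
        "lateralization": seq.lateralization.report().to_dict(),
        "sequential": seq.to_dict(),
    }
    (outdir / "classification.json").write_text(
        json.dumps(report_out, indent=2, sort_keys=True)
    )
    seq.confusion.to_csv(outdir / "confusion_three_class.csv")
    fold_log = {
        "diagnosis": [s.to_dict() for s in seq.diagnosis.fold_selections],
        "lateralization": [s.to_dict() for s in seq.lateralization.fold_selections],
    }
    (outdir / "fold_selections.json").write_text(
        json.dumps(fold_log, indent=2, sort_keys=True)
    )
    artifacts["classification"] = str(outdir / "classification.json")
    artifacts["confusion_three_class"] = str(outdir / "confusion_three_class.csv")
    artifacts["fold_selections"] = str(outdir / "fold_selections.json")
    _log(f"classify: overall three-class accuracy {seq.overall_accuracy}%")
    artifacts["run_log"] = str(outdir / "run.log")
    return artifacts
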