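"""Simulate the synthetic study cohort.

Generates the strong-effect cohort emulating the study design -- 35 controls,
20 left-TLE-like and 20 right-TLE-like subjects, each with 60 one-second
epochs of 14-region source time series at 250 Hz -- and writes the manifest
that reproduces it exactly.  The raw time series are regenerated on demand
from the manifest by the later steps, so nothing bulky is stored.
"""

import json
from pathlib import Path

import numpy as np

from epiconnect import cohort
from epiconnect.pipeline import scaled_config

OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = scaled_config(seed=1)
    c = cfg.cohort
    subjects, manifest = cohort.simulate_cohort(
        n_control=c.n_control, n_ltle=c.n_ltle, n_rtle=c.n_rtle,
        template_params={
            "order": c.order,
            "base_coupling_strength": c.base_coupling_strength,
            "effect_size": c.effect_size,
            "contralateral_fraction": c.contralateral_fraction,
        },
        seed=cfg.seed, n_epochs=c.n_epochs, epoch_seconds=c.epoch_seconds,
        fs=c.fs, subject_jitter_sd=c.subject_jitter_sd, obs_noise_sd=c.obs_noise_sd,
    )
    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    radii = []
    for group in cohort.GROUPS:
        t = cohort.make_template(group, **manifest["template_params"])
        radii.append((group, t.spectral_radius, len(t.effect_spec)))
    print(f"cohort: {len(subjects)} subjects "
          f"({c.n_control} CONTROL / {c.n_ltle} LTLE / {c.n_rtle} RTLE), "
          f"{c.n_epochs} x {c.epoch_seconds:.0f} s epochs at {c.fs:.0f} Hz")
    for group, radius, n_eff in radii:
        print(f"  {group:7s} template: spectral radius {radius:.3f}, "
              f"{n_eff} planted edge effects")
    var = np.var(subjects[0].epochs, axis=(0, 2))
    print(f"  channel variance spread (subject 0): "
          f"{var.min():.2f} .. {var.max():.2f}")
    print(f"wrote {OUT/'manifest.json'}")


if __name__ == "__main__":
    main()
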