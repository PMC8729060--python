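"""Deterministic fixture generation for regression tests and demos."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .params import default_scenario
from .population import sample_cohort, nodal_status, STAGES
from .natural_history import calibrate_scenario
from .outcomes import run_simulation


def generate_fixtures(seed: int, outdir, n_cohort: int = 1000,
                      n_sim: int = 20_000) -> dict:
    """Write a small cohort CSV and a snapshot summary; idempotent in seed.

    Returns the manifest dict (also written as JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = default_scenario()
    cfg.master_seed = seed
    cfg.n_women = n_sim
    cfg.calibration.n_cal = max(50_000, n_sim)

    cohort = sample_cohort(cfg.cohort, seed, n=n_cohort)
    df = pd.DataFrame({
        "id": cohort.ids, "age_dx": cohort.age_dx.round(6),
        "birth_year": cohort.birth_year,
        "stage": [STAGES[i] for i in cohort.stage_idx],
        "nodal": [nodal_status(STAGES[i]) for i in cohort.stage_idx],
    })
    cohort_path = outdir / "cohort.csv"
    df.to_csv(cohort_path, index=False)

    model = calibrate_scenario(cfg)
    res = run_simulation(cfg, model)
    summary_path = outdir / "summary.csv"
    res.summary().round(6).to_csv(summary_path, index=False)

    manifest = {"seed": seed, "n_cohort": n_cohort, "n_sim": n_sim,
                "files": [cohort_path.name, summary_path.name]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
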