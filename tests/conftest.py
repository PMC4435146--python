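import numpy as np
import pandas as pd
import pytest

from actimet.calibration import standardized_bout_table
from actimet.cli_io import (
    RunConfig,
    calibrate_run,
    classify_run,
    estimate_run,
    simulate_run,
    validate_run,
)
from actimet.protocol import build_standardized_protocol
from actimet.signal_features import AccelRecording, compute_counts
from actimet.synthetic_data import (
    GroundTruthEEModel,
    SignalModel,
    default_cohort,
    simulate_cohort,
)


def make_recording(xyz: np.ndarray, fs: float = 30.0, site: str = "thigh"
                   ) -> AccelRecording:
    """Wrap a raw (n, 3) array as a recording on a uniform clock."""
    n = len(xyz)
    return AccelRecording(
        site=site,
        fs=fs,
        data=pd.DataFrame(
            {"time_s": np.arange(n) / fs, "x_g": xyz[:, 0], "y_g": xyz[:, 1],
             "z_g": xyz[:, 2]}
        ),
    )


def posture_recording(vec, duration_s=60, fs=30.0, noise_sd=0.0, seed=0,
                      site="thigh") -> AccelRecording:
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    xyz = np.tile(np.asarray(vec, dtype=float), (n, 1))
    if noise_sd > 0:
        xyz = xyz + rng.normal(0, noise_sd, xyz.shape)
    return make_recording(xyz, fs, site)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """14-subject noiseless standardized cohort plus its pipeline-derived
    calibration table (thigh site)."""
    sm, em = SignalModel.noiseless(), GroundTruthEEModel.noiseless()
    cohort = default_cohort(8, 6, seed=7)
    sims = simulate_cohort(
        cohort, lambda p, s: build_standardized_protocol(p), sm, em, seed=7
    )
    tables = []
    for p, sim in zip(cohort, sims):
        ep = compute_counts(sim.thigh)
        tables.append(
            standardized_bout_table(ep, sim.bouts, sim.bout_starts_s, sim.ee,
                                    p.id, p.sex)
        )
    return cohort, sims, pd.concat(tables, ignore_index=True)


def run_full_pipeline(run_dir, seed=1, n_female=1, n_male=1):
    cfg = RunConfig(seed=seed, n_female=n_female, n_male=n_male)
    simulate_run(run_dir, cfg)
    classify_run(run_dir, cfg)
    calibrate_run(run_dir, cfg)
    estimate_run(run_dir, cfg)
    return validate_run(run_dir, cfg)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One complete two-subject pipeline run (simulate → … → validate)."""
    run_dir = tmp_path_factory.mktemp("runA")
    report = run_full_pipeline(run_dir, seed=1)
    return run_dir, report
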