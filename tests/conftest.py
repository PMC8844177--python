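import numpy as np
import pandas as pd
import pytest

from dlasym import (
    CohortSpec,
    TemplateGrid,
    build_stimulus_set,
    simulate_covariates,
    simulate_li,
    simulate_volumes,
)
from dlasym.pipeline import analyze_ai_study


def make_trials(response_fn, subject_id="S0001") -> pd.DataFrame:
    """Full 36-trial table for one subject; response_fn(pair) -> syllable or ''."""
    pairs = build_stimulus_set()
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial_index": range(len(pairs)),
            "left_syllable": [p.left_syllable for p in pairs],
            "right_syllable": [p.right_syllable for p in pairs],
            "response": [response_fn(p) for p in pairs],
        }
    )


@pytest.fixture(scope="session")
def grid() -> TemplateGrid:
    return TemplateGrid()


@pytest.fixture(scope="session")
def null_study(grid):
    """One simulated null study (no planted effects), fitted: shared by GLM tests."""
    seed = 20240
    rng = np.random.default_rng(seed)
    spec = CohortSpec(n_subjects=60, seed=seed)
    truth = simulate_li(spec, rng)
    li = truth["li"].to_numpy()
    ok = np.isfinite(li)
    cov = simulate_covariates(spec, rng)[ok].reset_index(drop=True)
    study = simulate_volumes(spec, grid, [], li[ok], covariates=cov, rng=rng)
    result, ai, smoothed, valid = analyze_ai_study(
        study.volumes, grid, study.mask, cov, li[ok]
    )
    return {
        "spec": spec,
        "li": li[ok],
        "cov": cov,
        "study": study,
        "result": result,
        "ai": ai,
        "smoothed": smoothed,
        "valid": valid,
    }
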