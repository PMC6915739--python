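import numpy as np
import pytest

from arbrl.config import TaskConfig
from arbrl.task_env import build_state_space


@pytest.fixture(scope="session")
def config():
    return TaskConfig()


@pytest.fixture(scope="session")
def model(config):
    return build_state_space(config)


@pytest.fixture(scope="session")
def smoke_dataset(config, model):
    """A small single-subject dataset generated by the baseline variant."""
    from arbrl.synthetic_data import CohortSpec, simulate_cohort

    cohort = CohortSpec(variant_id="lee2014", n_subjects=1, n_sessions=2,
                        trials_per_session=40, master_seed=11)
    dataset, traces, sidecar = simulate_cohort(cohort, config, model)
    return dataset, traces, sidecar


@pytest.fixture(scope="session")
def recovery_cohort(config, model):
    """The 20-subject x 400-trial cohort generated under the best-fitting
    variant, with the best variant and four comparison variants fitted to
    every subject.  Shared across the model-recovery, parameter-recovery and
    P_MB condition-effect tests because fitting is the expensive step."""
    from arbrl.inference import fit_subject
    from arbrl.synthetic_data import CohortSpec, simulate_cohort

    cohort = CohortSpec(variant_id="best", n_subjects=20, n_sessions=5,
                        trials_per_session=80, master_seed=2024)
    dataset, traces, sidecar = simulate_cohort(cohort, config, model)

    # the best variant plus its single-factor ablations and the baseline
    variant_ids = [
        "3Q_int2_exc_mf2mb_explore",   # generating (best) variant
        "1MF_null_noexp",              # lee2014 baseline
        "1MF_int2_exc_mf2mb_explore",  # ablate goal-driven MF
        "3Q_int1_exc_mf2mb_explore",   # ablate interaction type
        "3Q_int2_exc_mf2mb_noexp",     # ablate exploration effect
    ]
    fits = {}
    for j, vid in enumerate(variant_ids):
        for i, subj in enumerate(dataset.subjects):
            rng = np.random.default_rng(np.random.SeedSequence((7, i, j)))
            fits[(subj, vid)] = fit_subject(
                vid, dataset.for_subject(subj), n_starts=20, rng=rng, model=model)
    return {
        "dataset": dataset, "traces": traces, "sidecar": sidecar,
        "variant_ids": variant_ids, "fits": fits,
    }
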