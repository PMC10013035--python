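import numpy as np
import pytest

from physiocausal import Hypnogram, SleeperConfig, StageParams, SubjectRecording, synthetic_sleeper


def ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) sample path (burn-in discarded)."""
    w = rng.standard_normal(n + 100)
    x = np.empty(n + 100)
    x[0] = w[0]
    for t in range(1, n + 100):
        x[t] = phi * x[t - 1] + w[t]
    return x[100:]


@pytest.fixture(scope="session")
def ar1_gen():
    return ar1


def make_sleeper_cohort(seed, q: float = 0.5, n_subjects: int = 4, edge=("B", "H")):
    """Cohort of synthetic sleepers with one planted directed coupling.

    The coupling (default B -> H, strength q, lag 2 s) is present in every
    sleep stage; stage-dependent mean/scale shifts on H and B make segment
    boundaries non-stationary so the ADF splitter has work to do.
    """
    shifts = {"LS": (0.0, 1.0), "DS": (1.5, 0.6), "REM": (-1.0, 1.3)}
    params = {
        stage: StageParams(
            couplings={edge: (q, 2)} if q > 0 else {},
            mean={"H": m},
            scale={"H": s, "B": s},
        )
        for stage, (m, s) in shifts.items()
    }
    ss = np.random.SeedSequence(seed)
    cohort = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        H, B, E, hyp = synthetic_sleeper(SleeperConfig(stage_params=params, seed=child))
        cohort.append(SubjectRecording(f"s{i}", H, B, E, Hypnogram(tuple(hyp))))
    return cohort


@pytest.fixture(scope="session")
def sleeper_cohort_factory():
    return make_sleeper_cohort
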