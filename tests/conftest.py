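import numpy as np
import pandas as pd
import pytest

from socialdiscount.cohort import CohortSpec, GroupSpec, generate_cohort
from socialdiscount.design import generative_pairs, make_uniform_targets


@pytest.fixture(scope="session")
def ladder_50():
    """The fixed 50-target generative pair ladder used in recovery."""
    return generative_pairs(make_uniform_targets(50))


@pytest.fixture(scope="session")
def small_cohort():
    """One 12-subject group with moderate susceptibility, fixed seed."""
    spec = CohortSpec(
        groups=(GroupSpec("G", 12, -2.0, 0.6, 0.5, 0.15, 0.3, 0.3),), seed=42
    )
    return generate_cohort(spec)


def simulate_ku_trials(km, ku, pairs, rng):
    """Tidy trial table for KU choosers with the given per-subject params."""
    from scipy.special import ndtr

    km = np.asarray(km)
    ku = np.asarray(ku)
    thresh = np.array([p.indifference_logk for p in pairs])
    p = ndtr((thresh[None, :] - km[:, None]) / ku[:, None])
    y = rng.random(p.shape) < p
    n, t = p.shape
    return pd.DataFrame(
        {
            "subject_id": np.repeat(np.arange(n), t),
            "ss_amount": np.tile([q.ss.amount for q in pairs], n),
            "ll_amount": np.tile([q.ll.amount for q in pairs], n),
            "delay_days": np.tile([q.ll.delay for q in pairs], n),
            "choice": np.where(y.ravel(), "LL", "SS"),
        }
    )
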