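import numpy as np
import pytest

from mcifuse.cohortsim import SimConfig, simulate_cohort
from mcifuse.datamodel import Cohort, ModalitySequence, ModalitySpec, Subject
from mcifuse.rnn_core import batch_loss


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed cohort with the stock missingness pattern."""
    cfg = SimConfig(n_cn=25, n_mci_c=20, n_mci_nc=25, n_ad=20, seed=123)
    return simulate_cohort(cfg)


@pytest.fixture()
def toy_registry():
    return [
        ModalitySpec("cognitive", n_features=2, hidden_dim=3, longitudinal=True),
        ModalitySpec("mri", n_features=3, hidden_dim=4, longitudinal=False),
    ]


@pytest.fixture()
def toy_cohort(toy_registry):
    s1 = Subject(
        id="S1",
        baseline_group="MCI",
        conversion_month=12.0,
        followup_month=36.0,
        sequences={
            "cognitive": ModalitySequence(
                "cognitive", [0.0, 6.0], [[1.0, 2.0], [0.5, 1.5]]
            ),
            "mri": ModalitySequence("mri", [0.0], [[3.0, 2.0, 1.0]]),
        },
    )
    s2 = Subject(
        id="S2",
        baseline_group="CN",
        conversion_month=None,
        followup_month=24.0,
        sequences={
            "cognitive": ModalitySequence("cognitive", [0.0], [[0.1, 0.2]]),
        },
    )
    return Cohort([s1, s2], toy_registry)


def numerical_gradients(params, sequences, labels, eps=1e-5):
    """Central-difference gradient of the batch cross-entropy, entry by entry.

    Independent oracle: perturbs each parameter entry in place and calls the
    loss twice; never touches the reverse-mode code path.
    """
    out = params.zeros_like()
    for name, arr in params.arrays().items():
        g = out.arrays()[name]
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = batch_loss(params, sequences, labels)
            arr[idx] = orig - eps
            lm = batch_loss(params, sequences, labels)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2.0 * eps)
    return out


def max_relative_gradient_error(analytic, numeric, floor=1e-6):
    """Worst-case entrywise relative discrepancy between two gradient pytrees."""
    worst = 0.0
    for name, a in analytic.arrays().items():
        n = numeric.arrays()[name]
        denom = np.maximum(np.maximum(np.abs(a), np.abs(n)), floor)
        worst = max(worst, float(np.max(np.abs(a - n) / denom)))
    return worst
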