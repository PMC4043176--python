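import logging
import warnings

import pytest

from applause.event_data import Bout, ClapRecord
from applause.simulator import SimConfig, run_ensemble
from applause.starting_models import StartParams
from applause.stopping_models import StopParams
from applause.synthetic_data import StudyDesign, generate_study

# diagnostic warnings (low ESS, underflow) are expected in stress tests
logging.getLogger("applause").setLevel(logging.ERROR)


def toy_bout() -> Bout:
    """Three starters with hand-enumerable times.

    Starts at 0, 1, 2 s; stops at 4, 5, 6 s.  Seats: two in the front
    row, one behind, so A neighbours both B and C.
    """
    return Bout(
        (
            ClapRecord("t", 1, "A", 0, 0, 0.0, 4.0, (0.0, 1.0, 2.0, 3.0, 4.0)),
            ClapRecord("t", 1, "B", 0, 1, 1.0, 5.0, (1.0, 2.2, 3.1, 5.0)),
            ClapRecord("t", 1, "C", 1, 0, 2.0, 6.0, (2.0, 3.0, 6.0)),
        )
    )


@pytest.fixture(name="toy")
def toy_fixture() -> Bout:
    return toy_bout()


BEST_FIT_START = StartParams(lam2=2.15)
BEST_FIT_STOP = StopParams(gamma2=0.63, gamma3=0.05, n_max=30)

#: design used by recovery / selection experiments: data generated exactly
#: under the fitted model (no forced non-starters)
RECOVERY_DESIGN = StudyDesign(n_non_starters=0)


def best_fit_study(seed: int, design: StudyDesign = RECOVERY_DESIGN):
    """One 12-bout study generated at the best-fit start/stop parameters."""
    return generate_study(
        design, "L2", BEST_FIT_START, "G2+G3", BEST_FIT_STOP, seed=seed
    )


@pytest.fixture(scope="session")
def default_ensemble():
    """A 2000-run simulator ensemble at the best-fit parameters (shared)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_ensemble(SimConfig(n_runs=2000, seed=20))
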