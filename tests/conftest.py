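import numpy as np
import pandas as pd
import pytest

import ltfimpute as lt


@pytest.fixture(scope="session")
def worked_example():
    """The two-by-two gender/mortality tracing example.

    100 women: 50 documented dead + 50 documented alive (all complete).
    100 men: 20 documented dead + 20 documented alive + 60 LTF, all of whom
    are traced and found dead.
    """
    rows, pid = [], 0

    def add(n, male, dead, status):
        nonlocal pid
        for _ in range(n):
            pid += 1
            rows.append(
                dict(patient_id=pid, male=male, dead10=dead, status=status)
            )

    add(50, 0, 1.0, "dead_documented")
    add(50, 0, 0.0, "alive_in_care")
    add(20, 1, 1.0, "dead_documented")
    add(20, 1, 0.0, "alive_in_care")
    ltf_ids = []
    for _ in range(60):
        pid += 1
        rows.append(dict(patient_id=pid, male=1, dead10=np.nan, status="ltf"))
        ltf_ids.append(pid)
    observed = pd.DataFrame(rows)
    tracing = lt.TracingResult(
        n_ltf=60,
        n_attempted=60,
        n_found=60,
        n_found_dead=60,
        records=pd.DataFrame(
            {"patient_id": ltf_ids, "found": 1, "dead_if_found": 1.0}
        ),
    )
    return observed, tracing


@pytest.fixture(scope="session")
def sim_model():
    """A default-sized simulated cohort shared across read-only tests."""
    return lt.LtfCohortModel.simulate(seed=3)


@pytest.fixture(scope="session")
def reference_margins():
    """A 910-patient cohort with the reference status margins.

    Statuses are overridden to exactly 445 alive-in-care, 238 documented
    dead, 156 LTF and 71 transferred; tracing finds 45 of the 156 LTF, 8 of
    them dead, leaving 111 unresolved.  Covariates and their missingness come
    from the generator.
    """
    config = lt.GeneratorConfig(seed=42)
    truth = lt.generate_cohort(config)
    observed = lt.apply_missingness(truth, config)

    rng = np.random.default_rng(7)
    order = rng.permutation(len(observed))
    ltf_idx = order[:156]
    transfer_idx = order[156:227]
    dead_idx = order[227:465]
    alive_idx = order[465:]

    observed = observed.copy()
    observed.loc[:, "status"] = "alive_in_care"
    observed.loc[:, "dead10"] = 0.0
    observed.loc[observed.index[dead_idx], "status"] = "dead_documented"
    observed.loc[observed.index[dead_idx], "dead10"] = 1.0
    observed.loc[observed.index[transfer_idx], "status"] = "transferred"
    observed.loc[observed.index[ltf_idx], "status"] = "ltf"
    observed.loc[observed.index[ltf_idx], "dead10"] = np.nan

    ltf_ids = observed.loc[observed.index[ltf_idx], "patient_id"].to_numpy()
    found = np.zeros(156, dtype=int)
    found[:45] = 1
    dead_if_found = np.full(156, np.nan)
    dead_if_found[:8] = 1.0
    dead_if_found[8:45] = 0.0
    tracing = lt.TracingResult(
        n_ltf=156,
        n_attempted=156,
        n_found=45,
        n_found_dead=8,
        records=pd.DataFrame(
            {"patient_id": ltf_ids, "found": found, "dead_if_found": dead_if_found}
        ),
    )
    return observed, tracing
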