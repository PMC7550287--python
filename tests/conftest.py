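import numpy as np
import pytest

from isobol import DoseGroup, ProbitFit


def make_fit(
    drug_id: str,
    ed50: float,
    sem_ed50: float = 1.0,
    slope: float = 6.0,
    se_slope: float = 0.5,
    n_total: int = 32,
    converged: bool = True,
) -> ProbitFit:
    """Hand-built fit for arithmetic tests that need exact ED50/SEM values."""
    log_ed50 = np.log10(ed50)
    sem_log = sem_ed50 / (ed50 * np.log(10.0))
    return ProbitFit(
        drug_id=drug_id,
        slope=slope,
        intercept=-slope * log_ed50,
        ed50=ed50,
        sem_ed50=sem_ed50,
        log_ed50=log_ed50,
        sem_log_ed50=sem_log,
        param_covariance=np.diag([se_slope**2, 0.1]),
        n_total=n_total,
        df=2,
        converged=converged,
        loglik=0.0,
    )


@pytest.fixture
def three_drug_fits():
    """Single-drug fits of the published three-drug worked example.

    The component ED50s are fixed by the additive breakdown of an
    equi-effective 1:1:1 mixture (each component dose is ED50/3):
    2.42, 2.17 and 99.53 mg/kg for LCM, LTG and VPA respectively, hence
    ED50s of 7.26, 6.51 and 298.59 mg/kg.
    """
    return [
        make_fit("LCM", 7.26, sem_ed50=0.9, n_total=32),
        make_fit("LTG", 6.51, sem_ed50=0.8, n_total=32),
        make_fit("VPA", 298.59, sem_ed50=14.0, n_total=24),
    ]


def simple_groups(drug="X", doses=(1.0, 4.0), protected=(2, 6), n=8):
    return [
        DoseGroup(drug, d, n, k) for d, k in zip(doses, protected)
    ]
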