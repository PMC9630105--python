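import numpy as np
import pytest

from paleotrophic.chronology import CalibrationCurve, RadiocarbonDate
from paleotrophic.synthetic import SyntheticScenario, synthetic_curve


@pytest.fixture
def identity_curve():
    """Curve where 14C age equals calendar age and the curve error is zero."""
    grid = np.arange(30000.0, 50001.0, 20.0)
    return CalibrationCurve(grid=grid, mu14c=grid.copy(),
                            sigma_curve=np.zeros_like(grid), name="identity")


@pytest.fixture
def syn_curve():
    return synthetic_curve()


@pytest.fixture
def scenario():
    return SyntheticScenario(seed=0)


def make_date(age=40000.0, err=100.0, lab="D1", site="s1", level="L1",
              region="Eurosiberian", culture="Mousterian", method="14C",
              material="bone", flags=()):
    return RadiocarbonDate(lab_code=lab, site_id=site, level_id=level,
                           region=region, culture=culture, method=method,
                           age=age, error_1sigma=err, material=material,
                           flags=frozenset(flags))
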