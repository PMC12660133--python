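import numpy as np
import pytest
from hypothesis import settings

from oxibench import make_pulse_template

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return make_pulse_template("child_nsr", 125)


def welch_oracle(a, b, alpha=0.05):
    """Hand-coded Welch test (b vs a): statistic, Satterthwaite df, p, CI.

    Written from the textbook formulas, independently of the package's
    statsmodels-backed implementation; used as the cross-check oracle.
    """
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    se = np.sqrt(va + vb)
    diff = b.mean() - a.mean()
    t_stat = diff / se
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2 * tdist.sf(abs(t_stat), df)
    half = tdist.ppf(1 - alpha / 2, df) * se
    return t_stat, df, p, (diff - half, diff + half)
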