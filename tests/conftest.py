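import mpmath as mp
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def ac_oracle(x: int, y: int, n1: int, n2: int, dps: int = 50) -> float:
    """Arbitrary-precision two-sided tag-count p-value.

    Sums exact conditional terms p(k|x) = r^k (x+k)!/(x!k!) / (1+r)^(x+k+1)
    with r = N2/N1 at ``dps`` decimal digits; the upper tail is accumulated
    upward from k = y until the residual contribution is below 1e-18 of the
    running total.  Independent of the package implementation.
    """
    with mp.workdps(dps):
        r = mp.mpf(n2) / mp.mpf(n1)

        def term(k: int) -> mp.mpf:
            return (
                mp.power(r, k)
                * mp.gamma(x + k + 1)
                / (mp.gamma(x + 1) * mp.gamma(k + 1))
                / mp.power(1 + r, x + k + 1)
            )

        lower = mp.fsum(term(k) for k in range(y + 1))
        upper = mp.mpf(0)
        k = y
        while True:
            t = term(k)
            upper += t
            k += 1
            if t < upper * mp.mpf("1e-18"):
                break
        return float(min(mp.mpf(1), 2 * min(lower, upper)))


@pytest.fixture(scope="session")
def table1_fixture():
    from symbioscreen.synthetic import make_table1_fixture

    return make_table1_fixture()


@pytest.fixture(scope="session")
def pathway_fixtures():
    from symbioscreen.synthetic import make_pathway_fixtures

    return make_pathway_fixtures()
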