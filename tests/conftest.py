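import numpy as np
import pytest

import psmcea as p


@pytest.fixture(scope="session")
def overall_models():
    return p.orient15_survival("overall")


@pytest.fixture(scope="session")
def subgroup_models():
    return p.orient15_survival("cps_ge_10")


@pytest.fixture(scope="session")
def econ_inputs():
    return p.orient15_economics()


@pytest.fixture(scope="session")
def reference_evaluator(overall_models, econ_inputs):
    """Base-case evaluator on the published (reference) time grid."""
    return p.CEAEvaluator(overall_models, econ_inputs, wtp=37654.50,
                          time_grid="reference")


@pytest.fixture(scope="session")
def calendar_evaluator(overall_models, econ_inputs):
    """Same inputs on the faithful 21-day calendar grid."""
    return p.CEAEvaluator(overall_models, econ_inputs, wtp=37654.50,
                          time_grid="calendar")


def fd_hessian(f, x, eps=1e-4):
    """Central finite-difference Hessian (for observed-information SEs)."""
    x = np.asarray(x, dtype=float)
    k = x.size
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = eps
            ej = np.zeros(k); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H
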