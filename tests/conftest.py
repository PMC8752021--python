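import numpy as np
import pytest
from hypothesis import settings

from protolearn.parameters import ParameterDef, ParameterSet

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def unit_defs():
    """Three generic probability parameters on [1e-12, 1]."""
    return tuple(
        ParameterDef(name=n, initial=v)
        for n, v in (("a", 0.4), ("b", 0.2), ("c", 0.1))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_params(*values, lower=1e-12, upper=1.0, kind=None):
    if kind is None:
        kind = "probability" if upper <= 1.0 else "positive"
    defs = tuple(
        ParameterDef(name=f"p{i+1}", initial=v, kind=kind, lower=lower, upper=upper)
        for i, v in enumerate(values)
    )
    return ParameterSet.from_defs(defs)
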