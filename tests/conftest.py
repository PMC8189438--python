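import itertools

import numpy as np
import pytest

from c1trace import ElementAbundances, default_metabolites


@pytest.fixture(scope="session")
def defs():
    return default_metabolites()


@pytest.fixture(scope="session")
def abundances():
    return ElementAbundances()


def enumerate_natural_abundance(formula: dict, abundances: ElementAbundances):
    """Exhaustive per-atom enumeration oracle for the natural envelope.

    Walks every combination of isotope choices over all atoms of the formula
    and accumulates probability mass by total mass shift.  Exponential in the
    atom count, so only usable for small molecules.
    """
    atoms = []
    for element, count in formula.items():
        atoms.extend([abundances.table[element]] * count)
    width = sum(max(shift for shift, _ in options) for options in atoms) + 1
    dist = np.zeros(width)
    for combo in itertools.product(*atoms):
        shift = sum(s for s, _ in combo)
        prob = np.prod([a for _, a in combo])
        dist[shift] += prob
    return dist / dist.sum()
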