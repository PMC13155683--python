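"""Bundled parameterizations: the ten-species study community and the
discrete kinetic-rate grids used for random sampling.

The ten-species table is the standard worked example throughout the package:
association rates between 72.5 and 100, dissociation rates between 5 and 10,
replication rates between 1.6 and 5.  Species 3 doubles as the E-species
variant: with ``exponential_species_3=True`` its association rate is set to
zero (all other rates unchanged), turning it into the exponentially growing
competitor with intrinsic growth rate 2.000 at r = 1.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .kinetics import SpeciesKinetics

__all__ = ["table1_fixture", "methods_parameter_grid", "methods_bc_grid"]

# columns: label, a, b, c
_TABLE1 = [
    ("1", 72.5, 5.0, 3.4),
    ("2", 72.5, 6.0, 5.0),
    ("3", 72.5, 7.0, 3.6),
    ("4", 72.5, 7.75, 5.0),
    ("5", 77.5, 8.75, 2.0),
    ("6", 77.5, 9.75, 1.6),
    ("7", 77.5, 10.0, 4.4),
    ("8", 82.5, 6.0, 2.8),
    ("9", 87.5, 5.5, 4.4),
    ("10", 100.0, 7.0, 4.0),
]


def table1_fixture(exponential_species_3: bool = False) -> list[SpeciesKinetics]:
    """The ten-species study community.

    With the flag set, species 3 becomes an E-species (a = 0 instead of 72.5);
    every other rate is unchanged.
    """
    out = []
    for label, a, b, c in _TABLE1:
        if exponential_species_3 and label == "3":
            a = 0.0
        out.append(SpeciesKinetics(a=a, b=b, c=c, label=label))
    return out


def _grid_values():
    a_vals = np.linspace(50.0, 100.0, 21)   # step 2.5
    b_vals = np.linspace(5.0, 10.0, 21)     # step 0.25
    c_vals = np.linspace(1.0, 5.0, 21)      # step 0.2
    return a_vals, b_vals, c_vals


def methods_parameter_grid() -> list[SpeciesKinetics]:
    """Full 21^3 = 9261 grid of permissible (a, b, c) combinations.

    Deterministic a-major ordering (a slowest, then b, then c).  The grid
    targets the regime where association is the fastest and replication the
    slowest elementary step at order-one concentrations.
    """
    a_vals, b_vals, c_vals = _grid_values()
    return [
        SpeciesKinetics(a=a, b=b, c=c, label=f"a{a:g}_b{b:g}_c{c:g}")
        for a, b, c in product(a_vals, b_vals, c_vals)
    ]


def methods_bc_grid() -> list[tuple[float, float]]:
    """The 21^2 = 441 (b, c) combinations used when all species share one
    association rate (the fluctuating-environment protocol)."""
    _, b_vals, c_vals = _grid_values()
    return [(float(b), float(c)) for b, c in product(b_vals, c_vals)]
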