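"""Shared fixtures: small designs and cached equilibrium solves.

Expensive solves are session-scoped so multiple tests can interrogate the
same solution (everything here is deterministic).
"""

from __future__ import annotations

import pytest

from dnafem import fixtures as fx
from dnafem.mechanics import ElasticParams, build_model, close_loop
from dnafem.solver import solve_equilibrium
from dnafem.topology import build_topology


@pytest.fixture(scope="session")
def params() -> ElasticParams:
    return ElasticParams()


@pytest.fixture(scope="session")
def duplex21():
    design = fx.make_duplex_design(21)
    topo = build_topology(design)
    return design, topo


@pytest.fixture(scope="session")
def junction_design():
    design = fx.make_single_junction_design(10)
    topo = build_topology(design)
    return design, topo


@pytest.fixture(scope="session")
def tile2x2():
    spec = fx.LatticeSpec(21, 21, 2, 2)
    design = fx.make_lattice_design(spec)
    topo = build_topology(design)
    return spec, design, topo


@pytest.fixture(scope="session")
def solved_ring_closure():
    """100-bp duplex drawn as a 300-deg arc, closed with a free-twist weld."""
    design = fx.make_duplex_design(100, arc_angle_deg=300.0)
    topo = build_topology(design)
    model = build_model(topo, design)
    close_loop(model, 99, 0, free_twist=True)
    sol = solve_equilibrium(model)
    return design, topo, model, sol


@pytest.fixture(scope="session")
def solved_straight100():
    design = fx.make_duplex_design(100)
    topo = build_topology(design)
    model = build_model(topo, design)
    sol = solve_equilibrium(model)
    return design, topo, model, sol


@pytest.fixture(scope="session")
def solved_junction(junction_design):
    design, topo = junction_design
    model = build_model(topo, design)
    sol = solve_equilibrium(model)
    return design, topo, model, sol
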