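"""Shared fixtures: one synthetic complex set, a potential table, a tiny model."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from pairbind.graph import build_complex_graph
from pairbind.network import NetworkConfig, PairRankNet, compile_graph
from pairbind.potentials import fit_reference_potential
from pairbind.structures import Structure, extract_pocket
from pairbind.synthetic import SyntheticSpec, make_pocket, make_series


@pytest.fixture(scope="session")
def spec7():
    return SyntheticSpec(seed=7)


@pytest.fixture(scope="session")
def pocket7(spec7):
    return make_pocket(spec7)


@pytest.fixture(scope="session")
def series7(spec7):
    series, truth = make_series(spec7)
    return series, truth


@pytest.fixture(scope="session")
def complexes7(pocket7, series7):
    """(pocket, ligand Structure, ComplexGraph) per ligand, shared pocket."""
    series, _ = series7
    first = Structure(series.ligands[0].mol, "ligand")
    pocket = extract_pocket(pocket7, first, cutoff=8.0)
    out = []
    for lig in series.ligands:
        ls = Structure(lig.mol, "ligand", name=lig.ligand_id)
        out.append((lig, ls, build_complex_graph(pocket, ls)))
    return pocket, out


@pytest.fixture(scope="session")
def table7(complexes7):
    _, items = complexes7
    return fit_reference_potential([g for _, _, g in items])


@pytest.fixture(scope="session")
def compiled7(complexes7, table7):
    _, items = complexes7
    return {lig.ligand_id: compile_graph(g, table7, name=lig.ligand_id)
            for lig, _, g in items}


@pytest.fixture(scope="session")
def labels7(series7):
    series, _ = series7
    return {l.ligand_id: l.pic50 for l in series.ligands}


@pytest.fixture(scope="session")
def tiny_model(table7):
    return PairRankNet(NetworkConfig(m=8, n_layers=1, pocket_depth=1,
                                     readout_steps=1, dropout=0.0, seed=3), table7)
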