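"""Shared fixtures: small hand-built networks and the synthetic toy model."""

from __future__ import annotations

import numpy as np
import pytest

from succdesign.model_io import (
    MetaboliteRecord,
    MetabolicNetwork,
    ReactionRecord,
    parse_gpr,
)
from succdesign.synth_fixtures import ToyNetworkSpec, make_toy_network

# Excerpt of a differential-expression table for glycerol-metabolism genes
# (log2 fold-changes of the glp regulon plus fumarase/fumarate reductase).
TABLE1_EXP3 = {
    "glpD": 1.69, "glpC": 2.61, "glpB": 2.87, "glpA": 1.28,
    "glpT": 5.41, "glpQ": 5.25, "glpF": 4.17, "glpK": 5.36,
    "glpX": 2.76, "fumA": 1.46, "frdA": 0.68, "frdB": 0.89,
    "frdC": 0.74, "frdD": 0.16,
}


def build_net(reactions, objective=None, net_id="test"):
    """Assemble a network from (id, stoich, lb, ub, gpr) tuples."""
    recs = []
    mets: dict[str, None] = {}
    for rid, stoich, lb, ub, *rest in reactions:
        gpr = parse_gpr(rest[0]) if rest else None
        recs.append(ReactionRecord(rid, dict(stoich), lb, ub, gpr))
        for m in stoich:
            mets.setdefault(m)
    metabolites = [MetaboliteRecord(m, m.rsplit("_", 1)[-1] if "_" in m else "c")
                   for m in mets]
    return MetabolicNetwork(metabolites, recs, [], objective, id=net_id)


@pytest.fixture(scope="session")
def toy_net():
    return make_toy_network()


@pytest.fixture(scope="session")
def toy_spec():
    return ToyNetworkSpec()


@pytest.fixture()
def chain_net():
    """EX_a (uptake <= 10) -> A -> B -> EX_b; maximizing EX_b gives 10."""
    return build_net(
        [
            ("EX_a", {"a_c": -1}, -10, 1000),
            ("AB", {"a_c": -1, "b_c": 1}, 0, 1000, "g_ab"),
            ("EX_b", {"b_c": -1}, 0, 1000),
        ],
        objective="EX_b",
    )


@pytest.fixture()
def table1_tsv(tmp_path):
    path = tmp_path / "table1_exp3.tsv"
    lines = ["gene_id\tlog2fc"] + [f"{g}\t{v}" for g, v in TABLE1_EXP3.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
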