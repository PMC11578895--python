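import numpy as np
import pytest

from atlaskit.netcore import GenomicInterval, NetworkNode, RegulatoryNetwork
from atlaskit.synthetic import (
    ExpressionSpec,
    GrnSpec,
    GwasSpec,
    gen_expression,
    gen_grn,
    gen_gwas,
)


def make_path_network() -> RegulatoryNetwork:
    """TF1 -- chr1:100-200 -- G1 chain with unit importances."""
    nodes = [
        NetworkNode("TF1", "TF"),
        NetworkNode("chr1:100-200", "region", GenomicInterval("chr1", 100, 200)),
        NetworkNode("G1", "gene"),
    ]
    edges = [
        ("TF1", "chr1:100-200", 1.0, "tf-region"),
        ("chr1:100-200", "G1", 1.0, "region-gene"),
    ]
    return RegulatoryNetwork(nodes, edges)


def make_random_network(seed: int, n_tf=3, n_region=15, n_gene=25, module=5):
    return gen_grn(
        GrnSpec(n_tf=n_tf, n_region=n_region, n_gene=n_gene, module_size=module),
        seed=seed,
    )


@pytest.fixture
def path_net() -> RegulatoryNetwork:
    return make_path_network()


@pytest.fixture(scope="session")
def small_scene():
    """One fixed synthetic scene shared by propagation tests: network with
    planted module, GWAS with signal on the module, expression tied to it."""
    net, planted = gen_grn(GrnSpec(), seed=1)
    syn_gwas = gen_gwas(GwasSpec(), net, planted, seed=2)
    planted_genes = sorted(n for n in planted if net.nodes[n].kind == "gene")
    expr = gen_expression(ExpressionSpec(), seed=3, planted_genes=planted_genes)
    return net, planted, syn_gwas, expr


@pytest.fixture(scope="session")
def expr_fixture():
    return gen_expression(ExpressionSpec(), seed=3)
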