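import pandas as pd
import pytest

from ocrlandscape.intervals import annotate_ocrs, parse_gff3, read_bed
from ocrlandscape.simulate import SimulationSpec, simulate


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic bundle (seed 7), shared across the whole suite."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate(SimulationSpec(seed=7), out)


@pytest.fixture(scope="session")
def genes(bundle):
    gene_models = parse_gff3(bundle.paths["gff"])
    expr = pd.read_csv(bundle.paths["expression"], sep="\t")
    fpkm = dict(zip(expr.gene_id, expr.fpkm))
    for g in gene_models:
        g.fpkm = float(fpkm[g.id])
    return gene_models


@pytest.fixture(scope="session")
def ocrs(bundle):
    return read_bed(bundle.paths["ocrs"])


@pytest.fixture(scope="session")
def annotations(ocrs, genes):
    return annotate_ocrs(ocrs, genes)
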