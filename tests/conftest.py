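import numpy as np
import pytest
from hypothesis import settings

import phylofoot as pf

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library() -> pf.MatrixLibrary:
    return pf.default_matrix_library()


@pytest.fixture(scope="session")
def dataset() -> "pf.synthetic_data.SimulatedDataset":
    """One representative synthetic dataset shared across tests."""
    return pf.simulate_cog_dataset(pf.example_design(seed=101, n_cogs=2))


@pytest.fixture(scope="session")
def analysis(dataset):
    """Scan + occurrence + classification + modules for the shared dataset."""
    hits = pf.scan_promoters(
        dataset.library, dataset.promoters, background=(0.25,) * 4
    )
    occ = pf.build_occurrence_matrix(hits, dataset.promoters, dataset.library.class_map)
    cogs = pf.cog_definitions_from_table(dataset.cog_table)
    reports = pf.classify_cogs(occ, cogs)
    by_gene: dict[str, list] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    modules = {
        cog.cog_id: pf.detect_core_modules(
            {g: by_gene.get(g, []) for g in cog.ortholog_genes},
            {g: by_gene.get(g, []) for g in cog.paralogs},
            cog_id=cog.cog_id,
        )
        for cog in cogs
    }
    return {
        "hits": hits,
        "occ": occ,
        "cogs": {c.cog_id: c for c in cogs},
        "reports": reports,
        "modules": modules,
        "by_gene": by_gene,
    }


def make_matrix(rows, id="M_01", cls=None, **kw) -> pf.MotifMatrix:
    return pf.MotifMatrix(
        id=id, class_label=cls or id.split("_")[0], freqs=np.asarray(rows, float), **kw
    )


@pytest.fixture
def toy_matrix() -> pf.MotifMatrix:
    """6-mer with an unambiguous 4-position core (positions 1-4)."""
    strong = lambda b: [0.91 if i == b else 0.03 for i in range(4)]
    weak = lambda b: [0.55 if i == b else 0.15 for i in range(4)]
    return make_matrix(
        [weak(0), strong(1), strong(0), strong(2), strong(3), weak(2)],
        id="TOY_01",
    )
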