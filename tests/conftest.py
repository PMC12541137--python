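import numpy as np
import pandas as pd
import pytest

from cervidiet import synthetic
from cervidiet.io_model import MOTUCatalog, ReadCountTable, taxonomy_path
from cervidiet.pipeline import RunConfig, run_pipeline


@pytest.fixture(scope="session")
def small_spec():
    """A reduced community for fast unit tests (same structure)."""
    return synthetic.make_default_spec(
        n_transects={"coastal_boreal": 3, "boreo_nemoral": 3})


@pytest.fixture(scope="session")
def small_sim(small_spec):
    return synthetic.simulate_dataset(small_spec, seed=11)


@pytest.fixture(scope="session")
def default_result(tmp_path_factory):
    """Full pipeline on the default community spec (used end-to-end)."""
    out = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(out_dir=str(out), seed=1, n_perm=1999)
    return run_pipeline(config)


@pytest.fixture()
def mammal_catalog():
    rows = [
        ("mA", "mammal", 72, 100.0, taxonomy_path("Cervidae", "Alces",
                                                  "moose"), True),
        ("mB", "mammal", 70, 100.0, taxonomy_path("Cervidae", "Cervus",
                                                  "red"), True),
        ("mC", "mammal", 39, 95.0, taxonomy_path("unassigned"), False),
        ("mD", "mammal", 75, 90.0, taxonomy_path("unassigned"), False),
    ]
    return MOTUCatalog(pd.DataFrame(
        rows, columns=["motu_id", "marker", "length_bp", "best_similarity",
                       "taxonomy", "is_reference_exact"]))


def make_plant_counts(rows, motus):
    """Helper: build a plant-marker ReadCountTable from count tuples.

    ``rows`` is a list of (sample_id, replicate_index, control_kind,
    counts-list).
    """
    recs = []
    for i, (sid, rep, ctrl, counts) in enumerate(rows):
        rec = {"pcr_id": f"pcr{i}", "sample_id": sid, "marker": "plant",
               "replicate_index": rep, "control_kind": ctrl}
        rec.update(dict(zip(motus, counts)))
        recs.append(rec)
    return ReadCountTable(pd.DataFrame(recs))


@pytest.fixture()
def plant_catalog():
    rows = []
    for i in range(6):
        rows.append((f"t{i}", "plant", 60, 98.0,
                     taxonomy_path("Ericaceae", "Vaccinium"), True))
    rows.append(("low_sim", "plant", 60, 94.9,
                 taxonomy_path("unassigned"), False))
    return MOTUCatalog(pd.DataFrame(
        rows, columns=["motu_id", "marker", "length_bp", "best_similarity",
                       "taxonomy", "is_reference_exact"]))
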