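import pandas as pd
import pytest

from trgkit.pipeline import RunConfig, run_all
from trgkit.simulate import WorldConfig, generate_world

# Session world: large enough that every stage (including the classifier,
# which needs >= 5 essential TRGs for stratified folds) runs.
WORLD_N_GENES = 1200
WORLD_SEED = 11


@pytest.fixture(scope="session")
def world(tmp_path_factory):
    """A generated synthetic world directory plus its ground truth."""
    out = tmp_path_factory.mktemp("world")
    cfg = WorldConfig(n_genes=WORLD_N_GENES, seed=WORLD_SEED)
    truth = generate_world(cfg, out)
    return out, truth, cfg


@pytest.fixture(scope="session")
def world_report(world):
    """One full pipeline run over the session world."""
    out, truth, cfg = world
    report = run_all(RunConfig.from_world(out, seed=WORLD_SEED))
    return out, truth, report


@pytest.fixture()
def toy_classes():
    """A tiny hand-written four-class table."""
    rows = [
        ("a1", "TRG", True, "TRG-E", False),
        ("a2", "TRG", False, "TRG-NE", False),
        ("a3", "TRG", False, "TRG-NE", False),
        ("b1", "shared", True, "Shared-E", False),
        ("b2", "shared", False, "Shared-NE", False),
    ]
    return pd.DataFrame(rows, columns=["gene", "conservation", "essential",
                                       "four_class", "trg_excluded_by_domain"])
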