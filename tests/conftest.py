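import pytest

from g4annotate import SyntheticSpec, build_g4
from g4annotate.pipeline import annotate_structure

ALL_TOPOLOGIES = [
    "parallel",
    "antiparallel-chair",
    "antiparallel-basket",
    "antiparallel-basket2",
    "hybrid1",
    "hybrid2",
    "hybrid3",
    "hybrid4",
]

TABLE1_GROOVES = {
    "parallel": "iiii",
    "antiparallel-chair": "wnwn",
    "antiparallel-basket": "wini",
    "antiparallel-basket2": "iwin",
    "hybrid1": "iwni",
    "hybrid2": "iiwn",
    "hybrid3": "wnii",
    "hybrid4": "wiin",
}

TABLE1_COMBINATIONS = {
    "parallel": "-p-p-p",
    "antiparallel-chair": "+l+l+l",
    "antiparallel-basket": "-ld+l",
    "antiparallel-basket2": "+ld-l",
    "hybrid1": "-p-l-l",
    "hybrid2": "-pd+l",
    "hybrid3": "-l-l-p",
    "hybrid4": "+l+p+p",
}

TABLE4_SIDES = {
    "parallel": "opposite",
    "antiparallel-chair": "same",
    "antiparallel-basket": "same",
    "antiparallel-basket2": "same",
    "hybrid1": "opposite",
    "hybrid2": "opposite",  # DNA
    "hybrid3": "opposite",  # DNA
    "hybrid4": "same",  # without the 5'-bottom snapback
}


@pytest.fixture(scope="session")
def parallel_model():
    return build_g4(SyntheticSpec(topology="parallel", n_tetrads=3))


@pytest.fixture(scope="session")
def chair_model():
    return build_g4(SyntheticSpec(topology="antiparallel-chair", n_tetrads=2))


@pytest.fixture(scope="session")
def grid_annotations():
    """(topology, n_tetrads) -> (model, annotation) over the full grid."""
    out = {}
    for topo in ALL_TOPOLOGIES:
        for n in (2, 3, 4):
            model = build_g4(SyntheticSpec(topology=topo, n_tetrads=n))
            out[(topo, n)] = (model, annotate_structure(model))
    return out
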