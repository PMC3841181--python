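import numpy as np
import pytest

from chemoflock.simulate import (
    ChemotypeSpec, CohortDesign, CompoundSpec, simulate_cohort,
)


def make_compound(cid="c1", rt=2.5, sigma=0.2, fragments=((250, 1.0),),
                  base=100.0):
    return CompoundSpec(compound_id=cid, rt_center=rt, rt_sigma=sigma,
                        fragment_pattern=tuple(fragments), base_abundance=base)


@pytest.fixture
def small_design():
    """Two disjoint-suite chemotypes on a short scan grid; deterministic."""
    ct1 = ChemotypeSpec(
        "alpha",
        compounds=(make_compound("a1", rt=2.3, fragments=((250, 1.0), (253, 0.6))),
                   make_compound("a2", rt=2.7, fragments=((300, 1.0),))),
        proportions=(1.0, 0.5),
    )
    ct2 = ChemotypeSpec(
        "beta",
        compounds=(make_compound("b1", rt=2.4, fragments=((350, 1.0), (354, 0.5))),
                   make_compound("b2", rt=2.8, fragments=((400, 1.0),))),
        proportions=(1.0, 0.5),
    )
    return CohortDesign(
        chemotypes=(ct1, ct2), n_per_chemotype=3,
        abundance_cv=0.1, compound_cv=0.05,
        baseline_level=1.0, baseline_drift=0.0, noise_sd=0.2,
        rt_window=(2.0, 3.5), scan_interval=0.05,
        genetic_map={"alpha": "PG1", "beta": "PG2"}, seed=11,
    )


@pytest.fixture
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture
def noiseless_design(small_design):
    """Same chemotypes, but fully deterministic signal."""
    from chemoflock.simulate import asdict_shallow

    fields = asdict_shallow(small_design)
    fields.update(abundance_cv=0.0, compound_cv=0.0, baseline_level=0.0,
                  baseline_drift=0.0, noise_sd=0.0)
    return CohortDesign(**fields)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
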