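import warnings
from types import SimpleNamespace

import pytest

import ancrecomb as ar
from ancrecomb.ratemaps import assign_quartiles, make_windows, map_rates_to_windows


def build_scenario(seed: int, **overrides) -> SimpleNamespace:
    """Simulate a full multi-species scenario and call conserved regions."""
    config = ar.SimConfig(seed=seed, **overrides)
    sim = ar.simulate_karyotypes(config)
    maps = ar.simulate_recombination_landscape(sim)
    tracks = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in sim.species:
            windowed = map_rates_to_windows(maps[g.name], make_windows(g.chrom_sizes))
            tracks[g.name] = assign_quartiles(windowed)
    ref_to_species = {
        g.name: g.to_reference.invert() for g in sim.species if g.name != sim.reference
    }
    alr, ahr, log = ar.call_conserved_regions(tracks, sim.reference, ref_to_species)
    return SimpleNamespace(
        config=config, sim=sim, maps=maps, tracks=tracks,
        ref_to_species=ref_to_species, alr=alr, ahr=ahr, log=log,
    )


@pytest.fixture(scope="session")
def scenario() -> SimpleNamespace:
    """The default four-species study scenario (seed 1), built once."""
    return build_scenario(seed=1)
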