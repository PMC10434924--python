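import pytest

from thripspop import reference, simulate


@pytest.fixture(scope="session")
def panel():
    """The bundled 58-haplotype reference panel, reconstructed once."""
    return reference.build_reference_fixture(background_seed=0)


@pytest.fixture(scope="session")
def small_sim():
    """A small deterministic simulated survey spanning all reproductive modes."""
    cfg = simulate.SimConfig(
        seed=11, n_locations=5, n_per_location=12, small_sample=None,
        mode_composition={0: (1.0, 0.0, 0.0, 0.0),
                          1: (0.5, 0.3, 0.2, 0.0),
                          2: (0.4, 0.3, 0.2, 0.1),
                          3: (0.6, 0.2, 0.2, 0.0),
                          4: (0.5, 0.4, 0.1, 0.0)},
    )
    return simulate.simulate(cfg)


def records_to_seqs(records):
    return [r.nucleotides for r in records]
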