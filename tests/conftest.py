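import pytest

from medscreen import generate_experiment, load_catalog, load_contraindications


@pytest.fixture(scope="session")
def small_catalog():
    catalog, _ = load_catalog(
        [
            "Acer cap.(0.1g)",
            "Acer cap.(0.2g)",
            "Zomig tab.(2.5mg)",
            "Betadine soln.(10%)",
            "Cortex gran.(500mg)",
            "Novamed inj.(5mL)",
        ]
    )
    return catalog


@pytest.fixture(scope="session")
def small_table():
    table, _ = load_contraindications(
        [
            ("Acer cap.(0.1g)", "Zomig tab.(2.5mg)"),
            ("Cortex gran.", "Novamed inj."),
        ]
    )
    return table


@pytest.fixture(scope="session")
def clean_experiment():
    """The benchmark experiment with all noise switched off."""
    return generate_experiment(1, noise_scale=0.0)


@pytest.fixture(scope="session")
def noisy_experiment():
    """The benchmark experiment at its default noise conditions."""
    return generate_experiment(1)


def bag(experiment, bag_id):
    return next(b for b in experiment.bags if b.bag_id == bag_id)
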