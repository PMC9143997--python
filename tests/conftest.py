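import warnings

import pytest

import pamdsi as pm


@pytest.fixture(scope="session")
def tiny_spec():
    """One genotype per class, three blocks, one season: 288 AOIs per
    genotype x condition — enough for Monte-Carlo class contrasts."""
    return pm.DesignSpec(
        n_genotypes=4,
        n_seasons=1,
        n_blocks=3,
        plants_per_genotype=4,
        leaves_per_plant=4,
        leaflets_per_leaf=3,
        aois_per_leaflet=2,
        seed=7,
    )


TINY_SIZES = {"MR": 1, "MS": 1, "S": 1, "HS": 1}


@pytest.fixture(scope="session")
def tiny_run(tiny_spec):
    panel = pm.build_panel(tiny_spec, class_sizes=TINY_SIZES)
    measurements = pm.simulate_measurements(panel, tiny_spec)
    fluor = pm.compute_table(measurements)
    return {"spec": tiny_spec, "panel": panel,
            "measurements": measurements, "fluor": fluor}


@pytest.fixture(scope="session")
def default_run():
    """Full default panel (59 genotypes, 2 seasons, 3 blocks), seed 0,
    carried through parameters, DSI, features and typology assignment."""
    spec = pm.DesignSpec(seed=0)
    panel = pm.build_panel(spec)
    measurements = pm.simulate_measurements(panel, spec)
    fluor = pm.compute_table(measurements)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dsi = pm.dsi_pipeline(fluor)
        features = pm.build_feature_matrix(fluor, dsi["dsi"])
    clusters = pm.ward_cluster(features, 4)
    assignment = pm.label_classes(clusters, dsi["dsi"].reindex(features.index))
    return {
        "spec": spec,
        "panel": panel,
        "fluor": fluor,
        "dsi": dsi,
        "features": features,
        "assignment": assignment,
    }
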