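import numpy as np
import pandas as pd
import pytest

from splicemorph import synthetic as syn


@pytest.fixture(scope="session")
def junction_sim():
    """Junction reads for psi in {0, 0.1, 0.5, 0.9, 1}, 200 cells, depth 50."""
    psi = pd.DataFrame(
        {"glut": [0.0, 0.1, 0.5, 0.9, 1.0]},
        index=[f"ev{i}" for i in range(5)],
    )
    truth = syn.SplicingTruth(
        psi=psi, cells_per_subclass=200, mean_depth=50.0, seed=11
    )
    table, matrix = syn.simulate_junction_reads(truth)
    return truth, table, matrix


@pytest.fixture(scope="session")
def vessel_networks():
    """Noiseless rendered networks with known geometry."""
    nets = {
        "tube": (
            [((50.0, 100.0), (150.0, 100.0), 4.0)],
            {"n_branch": 0, "length": 100.0, "width": 4.0},
        ),
        "Y": (
            [
                ((100.0, 40.0), (100.0, 100.0), 5.0),
                ((60.0, 160.0), (100.0, 100.0), 4.0),
                ((140.0, 160.0), (100.0, 100.0), 3.0),
            ],
            {"n_branch": 1},
        ),
        "double_junction": (
            [
                ((40.0, 60.0), (100.0, 60.0), 4.0),
                ((100.0, 60.0), (160.0, 60.0), 4.0),
                ((100.0, 60.0), (100.0, 140.0), 5.0),
                ((100.0, 140.0), (40.0, 170.0), 4.0),
                ((100.0, 140.0), (160.0, 170.0), 3.0),
                ((100.0, 60.0), (60.0, 30.0), 3.0),
            ],
            {"n_branch": 2},
        ),
    }
    out = {}
    for name, (segs, expect) in nets.items():
        truth = syn.VesselGroundTruth(
            segments=segs, shape_um=(200.0, 200.0), pixel_size=0.5
        )
        image, mask = syn.render_vessel_image(truth)
        out[name] = (truth, image, mask, expect)
    return out


@pytest.fixture(scope="session")
def contact_scene():
    """Tube plus 10 puncta at alternating 0.5/2.0 um surface distances."""
    distances = [0.5, 2.0] * 5
    truth = syn.make_contact_truth(
        distances,
        shape_um=(20.0, 44.0, 20.0),
        voxel_size=(0.2, 0.2, 0.4),
        radius_um=4.0,
    )
    tube, puncta, mask = syn.render_contact_volume(truth)
    return truth, tube, puncta, mask


@pytest.fixture
def rng():
    return np.random.default_rng(42)
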