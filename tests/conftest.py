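import numpy as np
import pytest

from microhemo import imaging, network, tracking


@pytest.fixture
def fluid():
    return network.FluidParams()


@pytest.fixture
def trunk3():
    return network.build_trunk_network(n_se_pairs=3)


@pytest.fixture
def trunk16():
    return network.build_trunk_network(n_se_pairs=16)


@pytest.fixture
def y_network():
    """Symmetric bifurcation: inlet stem, two identical branches, common outlet."""
    nodes = {"i": (0.0, 0.0), "m": (100.0, 0.0), "x": (200.0, 50.0),
             "y": (200.0, -50.0), "o": (300.0, 0.0)}
    edges = [
        network.VesselEdge("in", "i", "m", 100.0, 6.0, 0.0, "DA"),
        network.VesselEdge("b1", "m", "x", 100.0, 4.0, 0.0, "SeA"),
        network.VesselEdge("b2", "m", "y", 100.0, 4.0, 0.0, "SeA"),
        network.VesselEdge("o1", "x", "o", 120.0, 4.0, 0.0, "SeV"),
        network.VesselEdge("o2", "y", "o", 120.0, 4.0, 0.0, "SeV"),
    ]
    return network.TrunkNetwork(
        nodes, edges, network.BoundaryConditions("i", "o", 100.0, 0.0))


@pytest.fixture
def straight_trace():
    return tracking.VesselTrace("v0", np.array([[0.0, 18.0], [995.0, 18.0]]))


@pytest.fixture
def linear_movie(straight_trace):
    """Noiseless 50-cell constant-speed movie plus its ground truth.

    Speed 0.01 cm/s at 20 fps gives 5 um/frame, well under both the 30 um
    link cutoff and half the 14 um cell spacing (so nearest-neighbour
    linking is unambiguous).
    """
    speed_cms = 0.01
    traj = imaging.make_linear_trajectories(50, speed_cms, 0.7, 20.0,
                                            spacing_um=14.0)
    config = imaging.ImagingConfig(field_shape=(32, 880), noise_model=None)
    centerlines = {"v0": straight_trace.vertices}
    stack, truth = imaging.render_movie(traj, centerlines, config, seed=0)
    return stack, truth, speed_cms
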