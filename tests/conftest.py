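"""Shared fixtures: small simulated colonies, rendered stacks and the
measurement tables derived from them.

Everything is generated at test time from seeds; the heavier famine and
growth runs are session-scoped so several test modules can share them.
"""

import warnings

import numpy as np
import pytest

import calsense as cs
from calsense import imaging, quant, tracking
from calsense.protocols import make_protocol


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def params():
    return cs.KineticParams()


@pytest.fixture(scope="session")
def imaging_params():
    return imaging.ImagingParams()


@pytest.fixture(scope="session")
def famine_colony(params):
    """One feast/famine/feast colony (shortened restore) with ground
    truth, used across tracking/phenotype/trace tests."""
    return cs.simulate_colony(
        4, params, make_protocol("famine_carbon"), seed=1)


@pytest.fixture(scope="session")
def famine_stack(famine_colony, imaging_params):
    return imaging.render_stack(famine_colony, imaging_params, seed=1001)


@pytest.fixture(scope="session")
def famine_measured(famine_stack):
    cell_table, bg_table, masks = quant.measure_stack(
        famine_stack, return_masks=True)
    return cell_table, bg_table, masks


@pytest.fixture(scope="session")
def short_division_run(params, imaging_params):
    """Short feast run rich in divisions, with stack, measurements and
    tracked forests for both the ground-truth-mask and segmentation
    paths."""
    col = cs.simulate_colony(
        2, params,
        make_protocol("famine_carbon", total=480.0, feast_end=240.0,
                      famine_end=400.0),
        seed=4)
    stack = imaging.render_stack(col, imaging_params, seed=5)
    out = {}
    for bypass in (True, False):
        ct, bt, masks = quant.measure_stack(stack, bypass_ground_truth=bypass,
                                            return_masks=True)
        forest = tracking.track_observations(
            ct, pixel_size=imaging_params.pixel_size, masks=masks)
        out[bypass] = (ct, bt, forest)
    return col, stack, out


def track_to_gt_cell(stack, node, pixel_size):
    """Map a reconstructed track to the ground-truth cell id it follows
    (majority vote of the label image at the track centroids)."""
    ids = []
    for o in node.observations:
        r = int(round(o.y / pixel_size))
        c = int(round(o.x / pixel_size))
        v = stack.labels[o.frame][r, c]
        if v > 0:
            ids.append(int(v))
    return max(set(ids), key=ids.count) if ids else None
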