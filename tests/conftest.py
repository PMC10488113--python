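"""Shared synthetic fixtures.

The large tissue fixtures are expensive to render, so they are generated
once per session and shared across test modules.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from myoslice import SliceSpec, generate_slice
from myoslice.pipeline import RunConfig, compute_channel_masks, run_pipeline
from myoslice.segmentation import segment_cells

#: ~100 cells at the default rod geometry; the standard segmentation fixture.
SPEC100 = SliceSpec(image_size_px=(4600, 4600), n_cells_target=100, seed=11)

#: 200-cell classification benchmark (slightly smaller rods keep the image
#: at a tractable size).
SPEC200 = SliceSpec(
    image_size_px=(5000, 5000),
    n_cells_target=200,
    cell_length_um=(45.0, 10.0),
    cell_width_um=(13.0, 2.0),
    seed=21,
)

#: Same tissue but with mutually exclusive viability states.
SPEC_EXCLUSIVE = dataclasses.replace(
    SPEC200,
    class_proportions={
        "live": 0.5, "dead": 0.5, "double_positive": 0.0, "double_negative": 0.0,
    },
    seed=31,
)

#: Small slice for fast pipeline / CLI smoke tests.  Kept tissue-dense
#: (myocytes occupy most of real myocardium, and the WGA threshold's
#: mode statistic presumes the stain is not the modal population).
SPEC_SMALL = SliceSpec(
    image_size_px=(900, 900),
    n_cells_target=10,
    cell_length_um=(40.0, 8.0),
    cell_width_um=(12.0, 2.0),
    seed=5,
)


@pytest.fixture(scope="session")
def slice100():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return generate_slice(SPEC100)


@pytest.fixture(scope="session")
def masks100(slice100):
    image, _ = slice100
    config = RunConfig(slice_spec=SPEC100)
    masks, _ = compute_channel_masks(image, config)
    return masks


@pytest.fixture(scope="session")
def labels100(masks100, slice100):
    image, _ = slice100
    return segment_cells(masks100["WGA"], image.pixel_size_um)


@pytest.fixture(scope="session")
def result200():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_pipeline(RunConfig(slice_spec=SPEC200), write=False)


@pytest.fixture(scope="session")
def result_exclusive():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_pipeline(RunConfig(slice_spec=SPEC_EXCLUSIVE), write=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
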