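"""Shared synthetic fixtures.

Rendering and registering image stacks is the expensive part of the suite, so
the rendered ROI (and its planted-transform sibling) are session-scoped and
shared between the imaging tests and the acceptance checks.
"""

import numpy as np
import pytest

from mihckit.fixtures import (
    default_archetypes,
    render_round_images,
    synth_cell_table,
    synth_tissue_layout,
)
from mihckit.registration import SimilarityTransform

PLANTED = SimilarityTransform(scale=1.02, angle=np.radians(3.0), translation=(10.0, -5.0))


@pytest.fixture(scope="session")
def archetypes():
    return default_archetypes()


@pytest.fixture(scope="session")
def small_scene(archetypes):
    """100 well-separated cells of three phenotypes in a 130x130 µm ROI."""
    table = synth_cell_table(
        archetypes,
        {"CD8+ T cells": 30, "B cells": 30, "Epithelial cells": 40},
        noise_seed=7,
        roi_id="R1",
    )
    return synth_tissue_layout(
        table, "random", (130.0, 130.0), seed=1, min_spacing_um=10.0
    )


@pytest.fixture(scope="session")
def rendered_identity(small_scene):
    """Identity-transform render: 11 rounds plus the ground-truth mask."""
    return render_round_images(small_scene, seed=3)


@pytest.fixture(scope="session")
def rendered_planted(small_scene):
    """Same scene with a known similarity distortion planted on round 2."""
    transforms = [SimilarityTransform() for _ in range(11)]
    transforms[2] = PLANTED
    rounds, truth = render_round_images(
        small_scene, round_transforms=transforms, seed=3
    )
    return rounds, truth, transforms


@pytest.fixture(scope="session")
def registered_planted(rendered_planted):
    """Rounds 0-2 of the planted-transform render, co-registered once."""
    from mihckit.registration import register_stack

    rounds, _, transforms = rendered_planted
    return register_stack(rounds[:3], reference_round=0), transforms
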