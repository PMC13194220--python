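"""Shared fixtures: one standard synthetic case, standardized and landmarked,
with the initial placement and the optimized placement computed once per
session (they back several test modules)."""

import numpy as np
import pytest

from plateplan import (
    ObjectiveWeights,
    detect_osteotomy_planes,
    initial_place,
    make_bone,
    make_plate,
    optimize_pose,
    plate_landmarks,
    standardize_bone,
    standardize_plate,
)
from plateplan.landmarks import extract_bone_landmarks
from plateplan.synthetic import SyntheticBoneSpec, SyntheticPlateSpec


@pytest.fixture(scope="session")
def bone_case():
    mesh, gt = make_bone(SyntheticBoneSpec(seed=0))
    return mesh, gt


@pytest.fixture(scope="session")
def plate_case():
    mesh, gt = make_plate(SyntheticPlateSpec(seed=0))
    return mesh, gt


@pytest.fixture(scope="session")
def standard_case(bone_case, plate_case):
    """Standardized bone/plate with landmarks for the default seed."""
    bone, bone_gt = bone_case
    plate, plate_gt = plate_case
    planes = detect_osteotomy_planes(bone)
    bone_fr = standardize_bone(bone, planes, "left")
    plate_fr = standardize_plate(plate)
    bone_std = bone_fr.standardized_mesh
    plate_std = plate_fr.standardized_mesh
    return {
        "bone": bone,
        "plate": plate,
        "bone_gt": bone_gt,
        "plate_gt": plate_gt,
        "bone_std": bone_std,
        "plate_std": plate_std,
        "bone_frame": bone_fr,
        "plate_frame": plate_fr,
        "bone_lm": extract_bone_landmarks(bone_std),
        "plate_lm": plate_landmarks(plate_std),
    }


@pytest.fixture(scope="session")
def initial_fixture(standard_case):
    sc = standard_case
    return initial_place(sc["bone_lm"], sc["plate_lm"], sc["bone_std"], sc["plate_std"])


@pytest.fixture(scope="session")
def optimized_fixture(standard_case, initial_fixture):
    sc = standard_case
    return optimize_pose(
        initial_fixture,
        sc["plate_std"],
        sc["plate_lm"],
        sc["bone_std"],
        sc["bone_lm"],
        ObjectiveWeights(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
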