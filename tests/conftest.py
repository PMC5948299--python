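"""Shared fixtures: small synthetic geometries built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from femload.image import VoxelImage
from femload.image_pipeline import (
    LABEL_BONE,
    AnatomicalFrame,
    SegmentedModel,
    align_crop_cartilage,
)
from femload.pipeline import PipelineConfig
from femload.synthetic_data import RemodellingParams, generate_adapted_structure


def digital_sphere_image(radius: float = 22.1, voxel: float = 0.6, n: int = 96) -> tuple[VoxelImage, AnatomicalFrame]:
    """Solid digital sphere with its exact frame (identity axes)."""
    g = np.stack(np.meshgrid(*[voxel * np.arange(n)] * 3, indexing="ij"), axis=-1)
    c = np.full(3, n * voxel / 2)
    img = VoxelImage((np.linalg.norm(g - c, axis=-1) <= radius).astype(np.uint8), voxel)
    frame = AnatomicalFrame(c, radius, c - [0, 0, radius], np.eye(3))
    return img, frame


def solid_block_model(nx: int, ny: int, nz: int, h: float = 1.0) -> SegmentedModel:
    """All-bone rectangular block (distal face = low-z crop face)."""
    labels = np.full((nx, ny, nz), LABEL_BONE, dtype=np.uint8)
    frame = AnatomicalFrame(np.zeros(3), 1.0, [0.0, 0.0, -1.0], np.eye(3))
    return SegmentedModel(VoxelImage(labels, h), frame, cartilage_thickness=1.0)


def top_traction_case(nx: int, ny: int, nz: int, sigma: float = 1.0, h: float = 1.0):
    """Consistent nodal loads for a uniform traction on the top (z) face."""
    from femload.unit_loads import LoadCase, LoadPatchSpec

    nodes, forces = [], []
    for i in range(nx + 1):
        for j in range(ny + 1):
            w = (0.5 if i in (0, nx) else 1.0) * (0.5 if j in (0, ny) else 1.0)
            nodes.append((i, j, nz))
            forces.append((0.0, 0.0, -sigma * h * h * w))
    return LoadCase(
        id=0, spec=LoadPatchSpec(0.0), nodes=np.array(nodes), forces=np.array(forces),
        resultant=np.array([0.0, 0.0, -sigma * h * h * nx * ny]),
        direction=np.array([0.0, 0.0, 1.0]), patch_area=float(nx * ny * h * h),
    )


SYNTH_CONFIG = PipelineConfig(
    threshold=0.5, filter_sigma=0.0, resample_factor=2, shaft_section_mm=10.0
)


@pytest.fixture(scope="session")
def sphere_segmented():
    """Cartilage-capped ideal sphere head (articular radius 24.3 mm)."""
    img, frame = digital_sphere_image()
    return align_crop_cartilage(img, frame, crop_factor=1.0, cartilage_thickness=2.2)


@pytest.fixture(scope="session")
def adapted_specimen():
    """One forward-remodelled mini-joint specimen (fixed seed, 40^3 voxels)."""
    return generate_adapted_structure(
        domain_shape=(40, 40, 40), params=RemodellingParams(seed=3)
    )


@pytest.fixture(scope="session")
def adapted_pipeline_result(adapted_specimen):
    from femload.pipeline import run_pipeline

    return run_pipeline(
        adapted_specimen.binary_structure, SYNTH_CONFIG, frame=adapted_specimen.frame
    )


@pytest.fixture(scope="session")
def grey_specimen(adapted_specimen):
    from femload.synthetic_data import synthesize_grayscale

    grey = synthesize_grayscale(adapted_specimen.binary_structure, 6000.0, 1000.0,
                                blur_sigma=0.8, noise_sd=150.0, seed=3)
    return grey, adapted_specimen.frame


@pytest.fixture(scope="session")
def sensitivity_report(grey_specimen):
    import warnings

    from femload.sensitivity import default_design, run_sensitivity

    grey, frame = grey_specimen
    cfg = PipelineConfig(shaft_section_mm=8.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return run_sensitivity(grey, default_design(), cfg, frame=frame)
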