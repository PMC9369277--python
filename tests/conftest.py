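"""Shared fixtures: small synthetic fields reused across the suite.

Unit tests run on 0.45 x 0.35 mm fields at 1 µm/px; the acceptance tests
use the full 0.9 x 0.7 mm study field where the check demands it.
"""
from __future__ import annotations

import numpy as np
import pytest

from adenoquant.config import NoiseConfig, PipelineConfig, SpecimenConfig
from adenoquant.pipeline import quantify_field, segment_field
from adenoquant.synthetic import generate_field


def make_specimen(**kw) -> SpecimenConfig:
    base = dict(
        specimen_id="S1",
        group="control",
        tissue_type="control_endometrium",
        cycle_phase="proliferative",
        n_fields=1,
        field_mm=(0.45, 0.35),
        pixel_um=1.0,
        planted_bvd=30.0,
        planted_lvd=10.0,
        planted_mature_fraction=0.5,
        noise=NoiseConfig.none(),
        seed=11,
    )
    base.update(kw)
    return SpecimenConfig(**base)


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def eutopic_field():
    """Noise-free endometrial field: stroma + glands, mixed-maturity vessels."""
    return generate_field(make_specimen(), 0)


@pytest.fixture(scope="session")
def ectopic_field():
    """Noise-free ectopic field: CD10 islands inside aSMA myometrium."""
    cfg = make_specimen(specimen_id="S2", group="adenomyosis",
                        tissue_type="ectopic_endometrium", planted_bvd=44.0,
                        planted_lvd=8.0, lesion_depth_mm=4.0, seed=21)
    return generate_field(cfg, 0)


@pytest.fixture(scope="session")
def myometrium_field():
    """Noise-free pure-myometrium field."""
    cfg = make_specimen(specimen_id="S3", tissue_type="myometrium",
                        planted_bvd=14.0, planted_lvd=3.0, seed=31)
    return generate_field(cfg, 0)


@pytest.fixture(scope="session")
def segmented_eutopic(eutopic_field, pipeline_config):
    stack, _ = eutopic_field
    return segment_field(stack, pipeline_config.segmentation)


@pytest.fixture(scope="session")
def segmented_ectopic(ectopic_field, pipeline_config):
    stack, _ = ectopic_field
    return segment_field(stack, pipeline_config.segmentation)


@pytest.fixture(scope="session")
def segmented_myometrium(myometrium_field, pipeline_config):
    stack, _ = myometrium_field
    return segment_field(stack, pipeline_config.segmentation)


@pytest.fixture(scope="session")
def quantified_eutopic(eutopic_field, segmented_eutopic, pipeline_config):
    stack, _ = eutopic_field
    return quantify_field(stack, segmented_eutopic, pipeline_config.quantification)
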