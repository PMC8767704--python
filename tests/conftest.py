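"""Shared fixtures: handcrafted toy manifests and a session-scoped synthetic
dataset (all generated at test time; nothing binary ships with the repo)."""

from __future__ import annotations

import numpy as np
import pytest

from leafhair.manifest import ImageRecord, Manifest, parse_score_label
from leafhair.synth import SynthConfig, generate_dataset, specs_for_all_classes


def make_record(
    image_id: str,
    leaf_id: str,
    *,
    genotype: str = "Pink",
    score: str = "3",
    leaf_number: int = 3,
    year: str = "Y1",
    environment: str = "GH",
    site: str = "N",
    vein_index: int = 1,
    position_index: int = 1,
    is_first: bool = False,
    image_path: str = "",
    extras: tuple = (),
) -> ImageRecord:
    return ImageRecord(
        image_id=image_id,
        leaf_id=leaf_id,
        genotype=genotype,
        score=parse_score_label(score),
        leaf_number=leaf_number,
        year=year,
        environment=environment,
        site=site,
        vein_index=vein_index,
        position_index=position_index,
        is_first=is_first,
        image_path=image_path,
        extras=extras,
    )


def make_leaf(
    leaf_id: str, n_images: int, *, score: str = "3", **kwargs
) -> list[ImageRecord]:
    """A consistent leaf group with exactly one is_first record."""
    records = []
    for i in range(n_images):
        records.append(
            make_record(
                f"{leaf_id}-img{i:02d}",
                leaf_id,
                score=score,
                vein_index=i % 3 + 1,
                position_index=i // 3 + 1,
                is_first=(i == 0),
                **kwargs,
            )
        )
    return records


@pytest.fixture
def toy_manifest() -> Manifest:
    """Four leaves, two genotypes, both years/environments/leaf numbers."""
    records = (
        make_leaf("leafA", 3, score="3", genotype="Pink", year="Y1", environment="GH")
        + make_leaf("leafB", 4, score="3", genotype="Pink", year="Y2",
                    environment="FD", leaf_number=4)
        + make_leaf("leafC", 3, score="5+", genotype="Black", year="Y1", environment="FD")
        + make_leaf("leafD", 5, score="5+", genotype="Black", year="Y2",
                    environment="GH", leaf_number=4)
    )
    return Manifest(tuple(records))


@pytest.fixture(scope="session")
def synth_dataset(tmp_path_factory) -> tuple:
    """Small desk-scale synthetic dataset shared across the session."""
    out = tmp_path_factory.mktemp("synthds")
    config = SynthConfig.desk_scale(plants_per_genotype=1, seed=7)
    specs = specs_for_all_classes(years=("Y1",), environments=("GH", "FD"))
    manifest = generate_dataset(specs, config, str(out))
    return manifest, str(out), config


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
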