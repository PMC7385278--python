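"""Shared fixtures: phantoms are expensive, so the full-resolution ones
are built once per session and reused read-only."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import fibroct as fc


@pytest.fixture(scope="session")
def spec128() -> fc.PhantomSpec:
    return fc.PhantomSpec(rng_seed=1)


@pytest.fixture(scope="session")
def geometry128(spec128) -> fc.PhantomTruth:
    return fc.build_lung_geometry(spec128)


@pytest.fixture(scope="session")
def lesioned128(geometry128) -> fc.PhantomTruth:
    return fc.place_lesions(geometry128, 0.2, clustering=0.0, rng_seed=1)


@pytest.fixture(scope="session")
def ct128(lesioned128, spec128) -> fc.CTVolume:
    return fc.synthesize_ct(lesioned128, spec128)


@pytest.fixture(scope="session")
def seg128(ct128) -> fc.SegmentationResult:
    return fc.segment(ct128)


@pytest.fixture(scope="session")
def noise_free_spec128(spec128) -> fc.PhantomSpec:
    return dataclasses.replace(
        spec128,
        hu_parenchyma_sd=0.0,
        hu_lesion_sd=0.0,
        blur_sigma_vox=0.0,
        noise_sd_hu=0.0,
    )


@pytest.fixture(scope="session")
def ct128_noise_free(lesioned128, noise_free_spec128) -> fc.CTVolume:
    return fc.synthesize_ct(lesioned128, noise_free_spec128)


@pytest.fixture(scope="session")
def spec64() -> fc.PhantomSpec:
    return fc.PhantomSpec(grid_shape=(64, 64, 64), rng_seed=0)


@pytest.fixture(scope="session")
def geometry64(spec64) -> fc.PhantomTruth:
    return fc.build_lung_geometry(spec64)
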