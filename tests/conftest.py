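"""Shared fixtures: tracked tube phantoms reused across the DTI test set."""

from dataclasses import dataclass

import numpy as np
import pytest

from motornet import dti, synth


@dataclass
class PhantomPack:
    phantom: synth.PhantomDataset
    tensors: dti.TensorField
    famap: dti.FAMap
    streamlines: list
    tract: dti.Tract
    profile: dti.FAProfile


def _build(spec: synth.PhantomSpec) -> PhantomPack:
    phantom = synth.make_tract_phantom(spec)
    tensors = dti.fit_tensor_loglinear(phantom.dwi)
    famap = dti.fa_map(tensors)
    streamlines = dti.fact_track(tensors, famap, dti.TrackingParams())
    tract = dti.select_tract_by_rois(streamlines, phantom.masks["cortex"],
                                     phantom.masks["brainstem"], famap.affine,
                                     label="CST")
    profile = dti.tract_fa_profile(tract, famap, 100)
    return PhantomPack(phantom, tensors, famap, streamlines, tract, profile)


@pytest.fixture(scope="session")
def flat_phantom() -> PhantomPack:
    """Straight tube, constant planted FA 0.7, noise-free."""
    return _build(synth.PhantomSpec(fa_profile=0.7, seed=1))


@pytest.fixture(scope="session")
def ramp_phantom() -> PhantomPack:
    """Straight tube with the rostral FA deficit: 0.5 at the cortex end (t=0)
    rising linearly to 0.7 at the brainstem end."""
    return _build(synth.PhantomSpec(fa_profile=lambda t: 0.7 - 0.2 * (1 - t),
                                    seed=2))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
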