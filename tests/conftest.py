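"""Shared fixtures: generated specimen sets and pair loaders."""

from pathlib import Path

import numpy as np
import pytest

from femfit.fixtures import Case, FixtureRecipe, generate_case
from femfit.io import read_dat, read_model
from femfit.objective import Observation


def load_pairs(directory):
    """(ForwardModel, Observation) pairs from a generated fixture directory."""
    pairs = []
    for mf in sorted(Path(directory).glob("*.model")):
        model = read_model(mf)
        obs = Observation(mf.stem, read_dat(mf.with_suffix(".dat")))
        pairs.append((model, obs))
    return pairs


@pytest.fixture(scope="session")
def bone_noiseless(tmp_path_factory):
    out = tmp_path_factory.mktemp("bone0")
    manifest = generate_case(
        FixtureRecipe(Case.BONE_GREYSCALE, noise_cov=0.0, seed=11), out
    )
    return out, manifest


@pytest.fixture(scope="session")
def bone_noisy(tmp_path_factory):
    """The 22-specimen high-variance condition (CoV 0.47), fixed seed."""
    out = tmp_path_factory.mktemp("bone47")
    manifest = generate_case(FixtureRecipe(Case.BONE_GREYSCALE, seed=1), out)
    return out, manifest


@pytest.fixture(scope="session")
def goh_noiseless(tmp_path_factory):
    out = tmp_path_factory.mktemp("goh0")
    manifest = generate_case(
        FixtureRecipe(Case.OSTEODISC_GOH, noise_cov=0.0, seed=11), out
    )
    return out, manifest


@pytest.fixture(scope="session")
def interface_noiseless(tmp_path_factory):
    out = tmp_path_factory.mktemp("ifc0")
    manifest = generate_case(
        FixtureRecipe(Case.INTERFACE_SLICE, noise_cov=0.0, seed=11), out
    )
    return out, manifest
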