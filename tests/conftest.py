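"""Shared fixtures: small noise-free movies and segmentation helpers.

All fixture data is generated programmatically; session scope keeps the
renders to one per suite run.
"""

from __future__ import annotations

import numpy as np
import pytest

import abscission as ab


def segment_histone(movie, params):
    """Per-frame nucleus sets with a fixed threshold between bridge and nucleus peaks."""
    thr = params.background_offset + (params.bridge_peak + params.nucleus_peak) / 2.0
    return [
        ab.label_nuclei(ab.threshold_positive(movie.frame(f, "histone"), thr), frame_index=f)
        for f in range(movie.n_frames)
    ]


def actin_threshold(params):
    """Fixed actin positivity threshold: half the cytoplasmic level above background."""
    return params.background_offset + params.cytoplasm_peak / 2.0


def bridge_threshold(params):
    return params.background_offset + params.bridge_peak / 2.0


@pytest.fixture(scope="session")
def hela_scene():
    params = ab.SceneParams(read_noise_sd=0.0, poisson_noise=False)
    movie, truth = ab.generate_division_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def yeast_scene():
    params = ab.SceneParams.yeast(read_noise_sd=0.0, poisson_noise=False)
    movie, truth = ab.generate_division_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def hela_nuclei(hela_scene):
    params, movie, _ = hela_scene
    return segment_histone(movie, params)
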