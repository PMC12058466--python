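"""Shared fixtures: small deterministic datasets built in memory."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from protnorm.dataset import ProteomicsDataset, SampleMetadata, Scale


def make_dataset(
    X: np.ndarray,
    scale: Scale = Scale.LOG2,
    conditions: list[str] | None = None,
    batches: list[str] | None = None,
    ids: list[str] | None = None,
    annotations: pd.DataFrame | None = None,
) -> ProteomicsDataset:
    """Wrap a numpy array into a ProteomicsDataset (log2 by default)."""
    n, m = X.shape
    conditions = conditions or ["A"] * m
    ids = ids or [f"p{i:05d}" for i in range(n)]
    cols = [f"s{j}" for j in range(m)]
    samples = [
        SampleMetadata(
            cols[j], conditions[j], batch=None if batches is None else batches[j]
        )
        for j in range(m)
    ]
    mat = pd.DataFrame(
        X if scale is Scale.LOG2 else np.asarray(X, dtype=float),
        index=pd.Index(ids, name="protein"),
        columns=cols,
    )
    if annotations is not None:
        annotations = annotations.set_axis(mat.index)
    return ProteomicsDataset(mat, samples, scale=scale, annotations=annotations)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_log2(rng):
    """120 proteins x 6 samples, two conditions, shift bias + noise, ~3%
    missing values (never leaving a column with <2 observations)."""
    mu = rng.uniform(20, 30, 120)
    shifts = np.array([0.4, -0.3, 0.1, -0.2, 0.3, -0.3])
    X = mu[:, None] + shifts[None, :] + rng.normal(0, 0.25, (120, 6))
    mask = rng.random((120, 6)) < 0.03
    X[mask] = np.nan
    return make_dataset(X, conditions=["A", "A", "A", "B", "B", "B"])


@pytest.fixture
def small_raw(small_log2):
    return small_log2.with_matrix(2.0 ** small_log2.intensities, scale=Scale.RAW)
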