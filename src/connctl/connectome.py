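"""Functional connectome construction from blocked task time series.

For each subject and working-memory load, the four 20-volume task blocks are
concatenated into an 80-volume matrix, node-pairwise Pearson correlations
are computed, and the correlation matrix is Fisher z transformed with the
diagonal zeroed.  The result is the symmetric weighted adjacency used as the
dynamical substrate for the controllability metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import LOADS, N_BLOCKS, VOLUMES_PER_BLOCK

DEFAULT_CLIP = 0.999999


@dataclass(frozen=True)
class BlockTimeSeries:
    """Per-subject, per-load stack of task blocks: (4 blocks, 20 volumes, N nodes)."""

    subject_id: str
    load: str
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, float)
        if data.ndim != 3 or data.shape[:2] != (N_BLOCKS, VOLUMES_PER_BLOCK):
            raise ValueError(
                f"expected data of shape ({N_BLOCKS}, {VOLUMES_PER_BLOCK}, N), got {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("time series contain non-finite values")
        if self.load not in LOADS:
            raise ValueError(f"unknown load {self.load!r}")
        object.__setattr__(self, "data", data)

    @property
    def n_nodes(self) -> int:
        return self.data.shape[2]

    def write(self, path) -> None:
        """Plain-text matrix, rows = 80 volumes (block-major), columns = nodes."""
        np.savetxt(path, concatenate_blocks(self), fmt="%.10g")

    @classmethod
    def read(cls, path, subject_id: str, load: str) -> "BlockTimeSeries":
        flat = np.loadtxt(path, ndmin=2)
        if flat.shape[0] != N_BLOCKS * VOLUMES_PER_BLOCK:
            raise ValueError(
                f"expected {N_BLOCKS * VOLUMES_PER_BLOCK} rows, got {flat.shape[0]}"
            )
        data = flat.reshape(N_BLOCKS, VOLUMES_PER_BLOCK, flat.shape[1])
        return cls(subject_id=subject_id, load=load, data=data)


@dataclass(frozen=True)
class FunctionalConnectome:
    """Fisher-z correlation matrix: symmetric, zero diagonal, finite."""

    subject_id: str
    load: str
    z: np.ndarray
    clip: float = DEFAULT_CLIP

    def __post_init__(self) -> None:
        z = np.asarray(self.z, float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if not np.all(np.isfinite(z)):
            raise ValueError("z contains non-finite values")
        if np.max(np.abs(z - z.T), initial=0.0) > 1e-12:
            raise ValueError("z must be symmetric to 1e-12")
        if np.any(np.diag(z) != 0):
            raise ValueError("z diagonal must be exactly 0")
        object.__setattr__(self, "z", z)

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def write(self, path) -> None:
        path = Path(path)
        np.savetxt(path, self.z, fmt="%.12g")
        sidecar = {
            "subject_id": self.subject_id,
            "load": self.load,
            "n_nodes": self.n_nodes,
            "clip": self.clip,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, path) -> "FunctionalConnectome":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        z = np.loadtxt(path, ndmin=2)
        return cls(subject_id=meta["subject_id"], load=meta["load"], z=z, clip=meta["clip"])


def concatenate_blocks(ts: BlockTimeSeries) -> np.ndarray:
    """Stack the four 20-volume blocks into an 80 x N matrix (block-major)."""
    data = np.asarray(ts.data, float)
    if data.ndim != 3 or data.shape[:2] != (N_BLOCKS, VOLUMES_PER_BLOCK):
        raise ValueError(
            f"expected shape ({N_BLOCKS}, {VOLUMES_PER_BLOCK}, N), got {data.shape}"
        )
    return data.reshape(N_BLOCKS * VOLUMES_PER_BLOCK, data.shape[2])


def pearson_matrix(x: np.ndarray) -> np.ndarray:
    """Node-pairwise Pearson correlation of a volumes x nodes matrix."""
    x = np.asarray(x, float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (volumes x nodes)")
    dead = np.flatnonzero(np.ptp(x, axis=0) == 0)
    if dead.size:
        raise ValueError(f"zero-variance time series at node(s) {dead.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    # guard against tiny numerical overshoot before atanh downstream
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def fisher_z(r: np.ndarray, clip: float = DEFAULT_CLIP) -> np.ndarray:
    """Fisher z (atanh) transform with magnitude clipping and zeroed diagonal.

    Correlations are clipped to ``|r| <= clip`` before atanh so perfectly
    correlated pairs stay finite; the diagonal (self-correlation) is set to
    zero, treating the matrix as a weighted adjacency.
    """
    if not 0 < clip < 1:
        raise ValueError("clip must lie strictly between 0 and 1 (atanh diverges at 1)")
    r = np.asarray(r, float)
    if np.max(np.abs(r), initial=0.0) > 1.0:
        raise ValueError("|r| must be <= 1")
    z = np.arctanh(np.clip(r, -clip, clip))
    if z.ndim == 2 and z.shape[0] == z.shape[1]:
        np.fill_diagonal(z, 0.0)
    return z


def build_connectome(ts: BlockTimeSeries, clip: float = DEFAULT_CLIP) -> FunctionalConnectome:
    """Concatenate blocks, correlate, Fisher-z: the full construction."""
    z = fisher_z(pearson_matrix(concatenate_blocks(ts)), clip=clip)
    return FunctionalConnectome(subject_id=ts.subject_id, load=ts.load, z=z, clip=clip)


class ConnectomeTransformer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: block time series -> Fisher-z connectomes.

    Parameters
    ----------
    clip : float, default 0.999999
        Magnitude bound applied to correlations before the atanh transform.

    ``transform`` accepts an array of shape (n_subjects, 4, 20, N) and
    returns the stacked z matrices, shape (n_subjects, N, N).
    """

    def __init__(self, clip: float = DEFAULT_CLIP):
        self.clip = clip

    def fit(self, X, y=None):
        X = np.asarray(X, float)
        if X.ndim != 4 or X.shape[1:3] != (N_BLOCKS, VOLUMES_PER_BLOCK):
            raise ValueError(
                f"expected (n_subjects, {N_BLOCKS}, {VOLUMES_PER_BLOCK}, N), got {X.shape}"
            )
        self.n_nodes_ = X.shape[3]
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "n_nodes_"):
            self.fit(X)
        X = np.asarray(X, float)
        out = np.empty((X.shape[0], X.shape[3], X.shape[3]))
        for i, stack in enumerate(X):
            ts = BlockTimeSeries(subject_id=f"s{i}", load="0back", data=stack)
            out[i] = build_connectome(ts, clip=self.clip).z
        return out


__all__ = [
    "DEFAULT_CLIP",
    "BlockTimeSeries",
    "ConnectomeTransformer",
    "FunctionalConnectome",
    "build_connectome",
    "concatenate_blocks",
    "fisher_z",
    "pearson_matrix",
]
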