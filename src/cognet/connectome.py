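"""Weighted structural connectomes: construction, thresholding, subnetworks.

A connectome here is a symmetric nonnegative 90x90 matrix whose edge value is
the mean fractional anisotropy (FA) of the white-matter connection multiplied
by the streamline count of that connection, so large tracts carry more weight
than small ones. Edge weights are removed ("thresholded") with reference to
the healthy-control distribution of each edge: an edge survives at level t
when its weight is at least mu_ij - t * sigma_ij, where mu and sigma are the
control mean and standard deviation of that edge (zeros for absent
connections included). Ten levels, 0.5 to 5.0 SD units in steps of 0.5, are
evaluated; 2.5 is the conventional reporting level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_LEVELS: tuple[float, ...] = tuple(np.arange(1, 11) * 0.5)
DEFAULT_LEVEL: float = 2.5


@dataclass
class Connectome:
    """Symmetric weighted adjacency matrix with node labels."""

    node_labels: Sequence[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.node_labels)
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} != ({n}, {n})")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass
class SubnetworkDefinition:
    """Named node-membership list inducing a subgraph."""

    name: str
    members: Sequence[str]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError("subnetwork must have at least one member")

    def indices(self, node_labels: Sequence[str]) -> np.ndarray:
        pos = {label: i for i, label in enumerate(node_labels)}
        missing = [m for m in self.members if m not in pos]
        if missing:
            raise KeyError(f"members not found in connectome: {missing}")
        return np.array([pos[m] for m in self.members], dtype=int)


def mean_fa_per_connection(
    fa_volume: np.ndarray,
    masks: Mapping[tuple[int, int], np.ndarray],
) -> dict[tuple[int, int], float]:
    """Mean skeleton FA inside each binary connection mask.

    For each connection mask, averages the FA values at voxels where the mask
    is nonzero and FA > 0 (the skeleton). Connections whose mask has no such
    overlap get 0, matching the zero-fill convention for absent connections.

    Parameters
    ----------
    fa_volume : ndarray
        Scalar FA volume (any dimensionality, typically 3-D).
    masks : mapping of (i, j) -> ndarray
        Binary masks, one per connection, with the same shape as ``fa_volume``.
    """
    fa_volume = np.asarray(fa_volume, dtype=float)
    out: dict[tuple[int, int], float] = {}
    for key, mask in masks.items():
        mask = np.asarray(mask)
        if mask.shape != fa_volume.shape:
            raise ValueError(
                f"mask {key} shape {mask.shape} does not match FA volume "
                f"shape {fa_volume.shape}"
            )
        sel = (mask != 0) & (fa_volume > 0)
        out[key] = float(fa_volume[sel].mean()) if np.any(sel) else 0.0
    return out


def build_connectome(
    per_connection_fa: Mapping[tuple[int, int], float] | np.ndarray,
    streamlines: np.ndarray,
    node_labels: Sequence[str] | None = None,
) -> Connectome:
    """Streamline-weighted connectome: w_ij = mean FA_ij * streamlines_ij.

    ``per_connection_fa`` may be a dense FA matrix or a mapping keyed by node
    index pairs; connections with zero streamlines always get weight zero.
    """
    streamlines = np.asarray(streamlines, dtype=float)
    n = streamlines.shape[0]
    if node_labels is None:
        node_labels = [f"node{i}" for i in range(n)]
    if np.any(streamlines < 0):
        raise ValueError("streamline counts must be nonnegative")
    if isinstance(per_connection_fa, Mapping):
        fa = np.zeros((n, n))
        for (i, j), value in per_connection_fa.items():
            fa[i, j] = fa[j, i] = value
    else:
        fa = np.asarray(per_connection_fa, dtype=float)
    if np.any(fa < 0):
        raise ValueError("FA values must be nonnegative")
    return Connectome(node_labels=list(node_labels), weights=fa * streamlines)


@dataclass
class ThresholdScheme:
    """Per-edge control mean/SD and the ordered SD-unit threshold levels."""

    ctrl_mean: np.ndarray
    ctrl_sd: np.ndarray
    levels: tuple[float, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        self.ctrl_mean = np.asarray(self.ctrl_mean, dtype=float)
        self.ctrl_sd = np.asarray(self.ctrl_sd, dtype=float)
        if self.ctrl_mean.shape != self.ctrl_sd.shape:
            raise ValueError("ctrl_mean and ctrl_sd shapes differ")
        if np.any(self.ctrl_sd < 0):
            raise ValueError("ctrl_sd must be nonnegative")
        levels = tuple(float(t) for t in self.levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("levels must be strictly increasing")
        self.levels = levels

    def cutoff(self, t: float) -> np.ndarray:
        """Edge-wise survival cutoff mu - t * sigma at level ``t``."""
        return self.ctrl_mean - t * self.ctrl_sd


class ControlReferencedThreshold(TransformerMixin, BaseEstimator):
    """Control-referenced edge thresholding as a transformer.

    ``fit`` learns the per-edge control mean and SD from a stack of control
    weight matrices; ``transform`` zeroes, in any subject's matrix, every edge
    whose weight falls strictly below mu - level * sigma. Because the cutoff
    *decreases* with the level, larger levels are more liberal: the edge set
    kept at 0.5 SD units is a subset of the set kept at 5.0.

    Parameters
    ----------
    levels : sequence of float
        The full grid of SD-unit levels (default 0.5 ... 5.0 by 0.5).
    level : float
        Level used by :meth:`transform` when none is passed (default 2.5).
    ddof : int
        Delta degrees of freedom of the control SD (0 = population, default).
    """

    def __init__(
        self,
        levels: Sequence[float] = DEFAULT_LEVELS,
        level: float = DEFAULT_LEVEL,
        ddof: int = 0,
    ) -> None:
        self.levels = levels
        self.level = level
        self.ddof = ddof

    def fit(self, X: np.ndarray, y=None) -> "ControlReferencedThreshold":
        """Learn mu and sigma from ``X`` of shape (n_controls, n, n)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be a (n_controls, n_nodes, n_nodes) stack")
        if X.shape[0] < 2:
            raise ValueError("at least two control connectomes are required")
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=self.ddof)
        self.levels_ = tuple(float(t) for t in self.levels)
        self.n_features_in_ = X.shape[1]
        return self

    def scheme_(self) -> ThresholdScheme:
        return ThresholdScheme(self.mean_, self.sd_, self.levels_)

    def transform(self, X: np.ndarray, level: float | None = None) -> np.ndarray:
        """Apply the cutoff at ``level`` (default: the reporting level)."""
        t = self.level if level is None else level
        X = np.asarray(X, dtype=float)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1:] != self.mean_.shape:
            raise ValueError(
                f"connectome shape {X.shape[1:]} does not match fitted "
                f"shape {self.mean_.shape}"
            )
        cut = self.mean_ - t * self.sd_
        out = np.where(X >= cut, X, 0.0)
        return out[0] if single else out


def fit_threshold_scheme(
    control_connectomes: Iterable[Connectome] | np.ndarray,
    levels: Sequence[float] = DEFAULT_LEVELS,
    ddof: int = 0,
) -> ThresholdScheme:
    """Per-edge control mean/SD (zeros included) and the level grid."""
    if isinstance(control_connectomes, np.ndarray):
        stack = control_connectomes
    else:
        stack = np.stack([c.weights for c in control_connectomes])
    est = ControlReferencedThreshold(levels=levels, ddof=ddof).fit(stack)
    return est.scheme_()


def apply_threshold(c: Connectome, scheme: ThresholdScheme, t: float) -> Connectome:
    """Keep edges with w_ij >= mu_ij - t * sigma_ij, zero the rest."""
    if c.weights.shape != scheme.ctrl_mean.shape:
        raise ValueError(
            f"connectome shape {c.weights.shape} does not match scheme "
            f"shape {scheme.ctrl_mean.shape}"
        )
    cut = scheme.cutoff(t)
    kept = np.where(c.weights >= cut, c.weights, 0.0)
    return Connectome(node_labels=c.node_labels, weights=kept)


def extract_subnetwork(c: Connectome, d: SubnetworkDefinition) -> Connectome:
    """Induced subgraph on the subnetwork members, weights preserved."""
    idx = d.indices(c.node_labels)
    return Connectome(
        node_labels=[c.node_labels[i] for i in idx],
        weights=c.weights[np.ix_(idx, idx)],
    )
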