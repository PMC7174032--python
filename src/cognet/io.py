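"""Plain-text serialization of fixtures, cohorts and matrices."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import AtlasFixture
from .connectome import ThresholdScheme


def save_fixture(fixture: AtlasFixture, directory: str | Path) -> None:
    """Write node labels, memberships and the streamline matrix as TSV/CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "label": fixture.node_labels,
            "wm": [int(l in set(fixture.wm_members)) for l in fixture.node_labels],
            "rsn": [int(l in set(fixture.rsn_members)) for l in fixture.node_labels],
        }
    ).to_csv(directory / "nodes.tsv", sep="\t", index=False)
    pd.DataFrame(
        fixture.streamlines, index=fixture.node_labels, columns=fixture.node_labels
    ).to_csv(directory / "streamlines.csv")


def load_fixture(directory: str | Path) -> AtlasFixture:
    directory = Path(directory)
    nodes = pd.read_csv(directory / "nodes.tsv", sep="\t")
    streamlines = pd.read_csv(directory / "streamlines.csv", index_col=0)
    labels = nodes["label"].tolist()
    return AtlasFixture(
        node_labels=labels,
        streamlines=streamlines.to_numpy(dtype=np.int64),
        wm_members=nodes.loc[nodes["wm"] == 1, "label"].tolist(),
        rsn_members=nodes.loc[nodes["rsn"] == 1, "label"].tolist(),
    )


def matrices_to_long(weights: np.ndarray, subject_ids: list[str]) -> pd.DataFrame:
    """Stack of symmetric matrices -> long edge table (upper triangle only)."""
    n = weights.shape[1]
    iu = np.triu_indices(n, k=1)
    frames = []
    for sid, w in zip(subject_ids, weights):
        frames.append(
            pd.DataFrame({"subject_id": sid, "i": iu[0], "j": iu[1], "weight": w[iu]})
        )
    return pd.concat(frames, ignore_index=True)


def long_to_matrices(table: pd.DataFrame, n_nodes: int) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for sid, sub in table.groupby("subject_id", sort=False):
        w = np.zeros((n_nodes, n_nodes))
        w[sub["i"], sub["j"]] = sub["weight"]
        out[sid] = w + w.T
    return out


def save_scheme(scheme: ThresholdScheme, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "ctrl_mean.csv", scheme.ctrl_mean, delimiter=",")
    np.savetxt(directory / "ctrl_sd.csv", scheme.ctrl_sd, delimiter=",")
    np.savetxt(directory / "levels.csv", np.asarray(scheme.levels), delimiter=",")


def load_scheme(directory: str | Path) -> ThresholdScheme:
    directory = Path(directory)
    return ThresholdScheme(
        ctrl_mean=np.loadtxt(directory / "ctrl_mean.csv", delimiter=","),
        ctrl_sd=np.loadtxt(directory / "ctrl_sd.csv", delimiter=","),
        levels=tuple(np.atleast_1d(np.loadtxt(directory / "levels.csv", delimiter=","))),
    )


def load_nifti_volume(path: str | Path) -> np.ndarray:
    """Read a NIfTI scalar volume (requires the optional nibabel dependency)."""
    try:
        import nibabel as nib
    except ImportError as err:  # pragma: no cover
        raise ImportError(
            "reading NIfTI volumes requires nibabel (install the 'nifti' extra)"
        ) from err
    return np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
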