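"""Grey-matter atlas fixture: node labels, subnetwork memberships, streamlines.

The analysis operates on a 90-region parcellation (Desikan-Killiany cortical
labels plus subcortical structures) with two functionally defined subnetworks:
a 31-node working-memory network and a 26-node reasoning network sharing 9
nodes. The shared nodes and the hub regions are fixed by the study design; the
remaining memberships and the streamline-count matrix are a synthetic fixture
convention so that the pipeline can run without the tractography archive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_DK_CORTICAL = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

_SUBCORTICAL = [
    "thalamus", "caudate", "putamen", "pallidum", "hippocampus", "amygdala",
    "accumbens", "ventraldc", "cerebellum", "hypothalamus", "substantianigra",
]

#: The nine regions belonging to both subnetworks, as printed in the study.
SHARED_MEMBERS = [
    "lh-lateralorbitofrontal",
    "lh-precentral",
    "lh-rostralmiddlefrontal",
    "lh-superiorfrontal",
    "rh-caudalmiddlefrontal",
    "rh-precentral",
    "rh-rostralmiddlefrontal",
    "rh-superiorfrontal",
    "rh-superiorparietal",
]

# Working-memory-only members (22). The first block are the regions named in
# the study (hubs and model-weight nodes); the rest are fixture fills.
_WM_ONLY = [
    "lh-caudate", "rh-pallidum", "lh-insula", "rh-insula", "rh-precuneus",
    "rh-paracentral", "rh-supramarginal", "lh-caudalanteriorcingulate",
    "rh-rostralanteriorcingulate",
    "lh-supramarginal", "lh-pallidum", "rh-caudate", "lh-putamen",
    "rh-putamen", "lh-thalamus", "rh-thalamus", "lh-precuneus",
    "lh-paracentral", "rh-caudalanteriorcingulate",
    "lh-rostralanteriorcingulate", "lh-postcentral", "rh-postcentral",
]

# Reasoning-only members (17), same convention.
_RSN_ONLY = [
    "lh-superiorparietal", "rh-inferiorparietal", "lh-lateraloccipital",
    "rh-cuneus", "rh-inferiortemporal", "rh-lingual", "rh-pericalcarine",
    "lh-parsopercularis",
    "lh-inferiorparietal", "rh-lateraloccipital", "lh-cuneus", "lh-lingual",
    "lh-pericalcarine", "rh-parsopercularis", "lh-parstriangularis",
    "rh-parstriangularis", "lh-inferiortemporal",
]


def node_labels() -> list[str]:
    """The 90 region labels: 34 cortical + 11 subcortical per hemisphere."""
    labels = [f"{h}-{r}" for h in ("lh", "rh") for r in _DK_CORTICAL]
    labels += [f"{h}-{r}" for h in ("lh", "rh") for r in _SUBCORTICAL]
    return labels


@dataclass
class AtlasFixture:
    """90-node atlas with streamline counts and subnetwork memberships.

    Attributes
    ----------
    node_labels : list of str
        90 region names.
    streamlines : ndarray of shape (90, 90)
        Symmetric nonnegative integer streamline counts, zero diagonal.
        A zero entry means no anatomical connection exists between regions.
    wm_members, rsn_members : list of str
        Working-memory (31) and reasoning (26) subnetwork memberships,
        sharing exactly nine labels.
    """

    node_labels: list[str]
    streamlines: np.ndarray
    wm_members: list[str] = field(default_factory=list)
    rsn_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.streamlines = np.asarray(self.streamlines)
        n = len(self.node_labels)
        if self.streamlines.shape != (n, n):
            raise ValueError(
                f"streamlines shape {self.streamlines.shape} does not match "
                f"{n} node labels"
            )
        if not np.array_equal(self.streamlines, self.streamlines.T):
            raise ValueError("streamline matrix must be symmetric")
        if np.any(np.diag(self.streamlines) != 0):
            raise ValueError("streamline matrix must have a zero diagonal")
        if np.any(self.streamlines < 0):
            raise ValueError("streamline counts must be nonnegative")
        known = set(self.node_labels)
        for name, members in (("wm", self.wm_members), ("rsn", self.rsn_members)):
            unknown = [m for m in members if m not in known]
            if unknown:
                raise ValueError(f"{name} members not in atlas: {unknown}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


def make_atlas_fixture(seed: int = 0, edge_density: float = 0.3) -> AtlasFixture:
    """Build the deterministic 90-node atlas fixture.

    Streamline counts are drawn once from a seeded generator: a connection
    exists between a fraction ``edge_density`` of region pairs, and present
    connections get a log-normal-ish integer count in the tens-to-hundreds
    range, mimicking probabilistic-tractography output.

    Parameters
    ----------
    seed : int
        Seed for the streamline draw. Identical seeds give identical fixtures.
    edge_density : float
        Fraction of the 4005 region pairs that carry a connection.
    """
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must be in (0, 1]")
    labels = node_labels()
    n = len(labels)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    present = rng.random(iu[0].size) < edge_density
    counts = np.zeros(iu[0].size, dtype=np.int64)
    counts[present] = np.maximum(
        1, np.round(rng.lognormal(mean=3.0, sigma=0.8, size=present.sum()))
    ).astype(np.int64)
    streamlines = np.zeros((n, n), dtype=np.int64)
    streamlines[iu] = counts
    streamlines += streamlines.T
    return AtlasFixture(
        node_labels=labels,
        streamlines=streamlines,
        wm_members=SHARED_MEMBERS + _WM_ONLY,
        rsn_members=SHARED_MEMBERS + _RSN_ONLY,
    )
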