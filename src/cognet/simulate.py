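"""Synthetic cohorts with a planted connectome-cognition dissociation.

The generator emulates the statistical structure the analysis assumes:

* controls draw each present edge's fractional anisotropy from a normal
  distribution truncated to (0, 1) — FA is a bounded physical quantity;
* patients receive a global FA reduction (diffuse injury) plus a
  subject-specific degradation of the working-memory and reasoning
  subnetworks (half-normal severities, independent across subnetworks);
  edges belonging to both subnetworks receive only the global deficit, so
  the two subnetwork severities stay independent;
* each subject's subnetwork "integrity" is the mean edge FA over the induced
  subgraph, standardized against the control distribution;
* two latent abilities are linear in the integrities. The default preset is
  asymmetric: working-memory integrity drives both abilities while reasoning
  integrity drives reasoning only (coupling_rsn_to_wm = 0);
* six task scores load on the abilities (MKL/PAL/SOS on working memory,
  FTM/OOO/HTT on reasoning) with a polynomial age trend and residual noise.

Everything is driven by one seed in the configuration; identical seeds give
identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import AtlasFixture, make_atlas_fixture
from .behaviour import RSN_TASKS, TASKS, WM_TASKS


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Couplings are standardized effects of subnetwork integrity on the latent
    abilities; the default preset plants the asymmetric (one-way) structure.
    ``subnet_deficit_sd`` scales the per-patient half-normal subnetwork
    degradation, in control-SD units of edge FA.
    """

    n_controls: int = 105
    n_patients: int = 92
    edge_density: float = 0.3
    fa_mean: float = 0.5
    fa_sd: float = 0.1
    patient_global_deficit: float = 1.0
    subnet_deficit_sd: float = 0.7
    coupling_wm_to_wm: float = 0.8
    coupling_wm_to_rsn: float = 0.45
    coupling_rsn_to_rsn: float = 0.8
    coupling_rsn_to_wm: float = 0.0
    age_beta1: float = -0.30
    age_beta2: float = -0.10
    age_beta3: float = 0.02
    noise_sd: float = 0.4
    loadings: tuple[float, float, float] = (0.75, 0.70, 0.65)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fa_sd <= 0:
            raise ValueError("fa_sd must be positive")
        if self.noise_sd < 0 or self.subnet_deficit_sd < 0:
            raise ValueError("noise and deficit SDs must be nonnegative")
        couplings = (
            self.coupling_wm_to_wm, self.coupling_wm_to_rsn,
            self.coupling_rsn_to_rsn, self.coupling_rsn_to_wm,
        )
        if not np.all(np.isfinite(couplings)):
            raise ValueError("couplings must be finite")


@dataclass
class SimulatedConnectomes:
    """Per-subject FA matrices with subnetwork integrity scalars."""

    fa: np.ndarray  # (n_subjects, 90, 90)
    groups: np.ndarray  # 'control' / 'patient'
    integrity: pd.DataFrame  # columns wm, rsn (standardized vs controls)
    fixture: AtlasFixture = field(repr=False, default=None)


def _edge_indices(fixture: AtlasFixture) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(fixture.n_nodes, k=1)
    present = fixture.streamlines[iu] > 0
    return iu[0][present], iu[1][present]


def _membership_masks(
    fixture: AtlasFixture, ei: np.ndarray, ej: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-edge membership of the WM and RSN induced subgraphs."""
    pos = {label: k for k, label in enumerate(fixture.node_labels)}
    wm = np.zeros(fixture.n_nodes, dtype=bool)
    wm[[pos[m] for m in fixture.wm_members]] = True
    rsn = np.zeros(fixture.n_nodes, dtype=bool)
    rsn[[pos[m] for m in fixture.rsn_members]] = True
    return wm[ei] & wm[ej], rsn[ei] & rsn[ej]


def simulate_connectomes(
    fixture: AtlasFixture, cfg: GeneratorConfig
) -> SimulatedConnectomes:
    """Draw per-subject edge FA matrices and subnetwork integrity scalars.

    Control edges are truncated-normal(fa_mean, fa_sd) on (0, 1). Patient
    edge means are lowered by ``patient_global_deficit`` control SDs plus
    the subject's subnetwork degradation where the edge belongs to a
    subnetwork; the truncated support keeps FA physical. Matrices are
    symmetric, zero-diagonal, and zero wherever the atlas has no streamlines.
    """
    rng = np.random.default_rng([0, cfg.seed])
    ei, ej = _edge_indices(fixture)
    n_edges = ei.size
    n = cfg.n_controls + cfg.n_patients
    groups = np.array(["control"] * cfg.n_controls + ["patient"] * cfg.n_patients)

    in_wm, in_rsn = _membership_masks(fixture, ei, ej)
    # only subnetwork-exclusive edges carry the subject-specific factor;
    # shared edges get the global deficit alone, keeping the two integrity
    # scalars independent across patients despite the nine shared nodes
    w_wm = (in_wm & ~in_rsn).astype(float)
    w_rsn = (in_rsn & ~in_wm).astype(float)
    shift = np.zeros((n, n_edges))
    if cfg.n_patients:
        d_wm = np.abs(rng.normal(0.0, cfg.subnet_deficit_sd, cfg.n_patients)) \
            if cfg.subnet_deficit_sd > 0 else np.zeros(cfg.n_patients)
        d_rsn = np.abs(rng.normal(0.0, cfg.subnet_deficit_sd, cfg.n_patients)) \
            if cfg.subnet_deficit_sd > 0 else np.zeros(cfg.n_patients)
        pat = shift[cfg.n_controls:]
        pat += cfg.patient_global_deficit
        pat += np.outer(d_wm, w_wm) + np.outer(d_rsn, w_rsn)

    loc = cfg.fa_mean - cfg.fa_sd * shift
    a = (0.0 - loc) / cfg.fa_sd
    b = (1.0 - loc) / cfg.fa_sd
    edge_fa = stats.truncnorm.rvs(a, b, loc=loc, scale=cfg.fa_sd, random_state=rng)

    fa = np.zeros((n, fixture.n_nodes, fixture.n_nodes))
    fa[:, ei, ej] = edge_fa
    fa[:, ej, ei] = edge_fa

    integ = {}
    for name, mask in (("wm", in_wm), ("rsn", in_rsn)):
        raw = edge_fa[:, mask].mean(axis=1)
        ctrl = raw[: cfg.n_controls]
        mu, sd = ctrl.mean(), ctrl.std(ddof=1)
        integ[name] = (raw - mu) / sd if sd > 0 else raw - mu
    integrity = pd.DataFrame(integ)
    integrity["group"] = groups
    return SimulatedConnectomes(fa=fa, groups=groups, integrity=integrity, fixture=fixture)


def simulate_task_scores(
    integrity: pd.DataFrame, cfg: GeneratorConfig
) -> pd.DataFrame:
    """Cohort table of six task scores from subnetwork integrities.

    Latent abilities are linear in the (standardized) integrities with the
    configured couplings, then standardized against the *patient*
    distribution (falling back to the whole cohort when there are no
    patients) before being mapped to tasks by the within-factor loadings,
    plus a cubic age trend (age centred at 50 years, scaled by 15) and
    residual noise. Patient-referenced scaling matters: the analyses that
    consume these scores run within the patient group, and scaling the
    noise against cohort-wide variance (dominated by the control-patient
    gap) would dilute the planted loadings there.
    """
    rng = np.random.default_rng([1, cfg.seed])
    n = len(integrity)
    group = (
        integrity["group"].to_numpy()
        if "group" in integrity
        else np.array(["patient"] * n)
    )
    ref = group == "patient"
    if not ref.any():
        ref = np.ones(n, dtype=bool)

    def _std(x):
        x = np.asarray(x, dtype=float)
        s = np.std(x[ref])
        x = x - np.mean(x[ref])
        return x / s if s > 0 else x

    # couplings are standardized effects: rescale each integrity to unit
    # variance in the reference (patient) group, otherwise the two
    # subnetworks' different edge counts would distort the planted
    # correlation between the abilities
    wm_i = _std(integrity["wm"].to_numpy(float))
    rsn_i = _std(integrity["rsn"].to_numpy(float))
    noise = lambda: rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0

    wm_ability = _std(
        cfg.coupling_wm_to_wm * wm_i + cfg.coupling_rsn_to_wm * rsn_i + noise()
    )
    rsn_ability = _std(
        cfg.coupling_wm_to_rsn * wm_i + cfg.coupling_rsn_to_rsn * rsn_i + noise()
    )

    age = rng.uniform(20.0, 80.0, n)
    za = (age - 50.0) / 15.0
    trend = cfg.age_beta1 * za + cfg.age_beta2 * za**2 + cfg.age_beta3 * za**3

    data = {}
    for tasks, ability in ((WM_TASKS, wm_ability), (RSN_TASKS, rsn_ability)):
        for task, lam in zip(tasks, cfg.loadings):
            data[task] = lam * ability + trend + noise()

    counts = {"control": 0, "patient": 0}
    sids = []
    for g in group:
        sids.append(f"{g[:4]}{counts[g]:03d}")
        counts[g] += 1
    table = pd.DataFrame({"subject_id": sids, "group": group, "age": age})
    for t in TASKS:
        table[t] = data[t]
    return table


@dataclass
class SimulatedCohort:
    """Everything the downstream pipeline consumes."""

    fixture: AtlasFixture
    connectomes: SimulatedConnectomes
    cohort: pd.DataFrame  # subject_id, group, age, six task scores

    @property
    def fa(self) -> np.ndarray:
        return self.connectomes.fa

    @property
    def groups(self) -> np.ndarray:
        return self.connectomes.groups


def generate_cohort(
    cfg: GeneratorConfig | None = None, fixture: AtlasFixture | None = None
) -> SimulatedCohort:
    """Generate the full synthetic study: connectomes plus task scores."""
    cfg = cfg or GeneratorConfig()
    if fixture is None:
        fixture = make_atlas_fixture(seed=cfg.seed, edge_density=cfg.edge_density)
    conn = simulate_connectomes(fixture, cfg)
    cohort = simulate_task_scores(conn.integrity, cfg)
    return SimulatedCohort(fixture=fixture, connectomes=conn, cohort=cohort)
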