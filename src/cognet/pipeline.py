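"""End-to-end study driver on a synthetic cohort.

Wires the stages together the way the analysis is meant to be run: generate
(or accept) a cohort, streamline-weight and threshold the connectivity
matrices against the control reference, derive subnetwork graph measures and
hubs, reduce behaviour to rotated components, and run the three inferential
stages (univariate associations with FDR, permutation CCA on whole-brain
degree, nested-CV kernel ridge prediction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association, behaviour, cca, metrics, prediction
from .connectome import ControlReferencedThreshold, SubnetworkDefinition
from .simulate import GeneratorConfig, SimulatedCohort, generate_cohort

NETWORKS = ("wm", "rsn")
COMPONENTS = ("wm", "rsn")


def network_indices(fixture) -> dict[str, np.ndarray]:
    pos = {label: i for i, label in enumerate(fixture.node_labels)}
    return {
        "wm": np.array([pos[m] for m in fixture.wm_members]),
        "rsn": np.array([pos[m] for m in fixture.rsn_members]),
    }


def run_study(
    seed: int = 0,
    cfg: GeneratorConfig | None = None,
    cohort: SimulatedCohort | None = None,
    threshold: float = 2.5,
    nodal_metrics: tuple[str, ...] = metrics.NODAL_METRICS,
    n_perm_cca: int = 10_000,
    n_perm_krr: int = 1000,
    subsample_iters: int = 1000,
    compute_subsample: bool = True,
) -> dict:
    """Run the full pipeline and return a results bundle.

    Parameters mirror the study's reported settings (threshold 2.5 SD units,
    10,000 CCA permutations, 1000 prediction permutations); lower the
    permutation counts for quick runs.
    """
    if cohort is None:
        cfg = cfg or GeneratorConfig(seed=seed)
        cohort = generate_cohort(cfg)
    fixture = cohort.fixture
    groups = cohort.groups
    is_pat = groups == "patient"
    is_ctl = ~is_pat

    # --- connectome construction and thresholding -------------------------
    weighted = cohort.fa * fixture.streamlines[None, :, :]
    thresholder = ControlReferencedThreshold(level=threshold).fit(weighted[is_ctl])
    thresholded = thresholder.transform(weighted)

    nets = network_indices(fixture)
    net_labels = {"wm": list(fixture.wm_members), "rsn": list(fixture.rsn_members)}
    defs = {
        name: SubnetworkDefinition(name=name, members=net_labels[name])
        for name in NETWORKS
    }
    hubs = {
        name: metrics.identify_hubs(
            list(thresholded[is_ctl]), defs[name], node_labels=fixture.node_labels
        )
        for name in NETWORKS
    }

    # --- graph measures ---------------------------------------------------
    sids = cohort.cohort["subject_id"].tolist()
    subject_weights = {sid: w for sid, w in zip(sids, thresholded)}
    group_map = dict(zip(sids, groups))
    table = metrics.metric_table(
        subject_weights, nets, net_labels, threshold, groups=group_map
    )

    # --- behaviour: patient-only rotated PCA ------------------------------
    pat_tbl = cohort.cohort.loc[is_pat].set_index("subject_id")
    pre = behaviour.preprocess_scores(
        pat_tbl[list(behaviour.TASKS)], pat_tbl["age"].to_numpy()
    )
    pca = behaviour.VarimaxPCA().fit(pre)
    if pca.n_components_ < 2:
        # the downstream analyses are defined on the two-component
        # (working-memory vs reasoning) solution; take it directly when
        # the Kaiser rule retains fewer
        pca = behaviour.VarimaxPCA(kaiser=False, n_components=2).fit(pre)
    comp_map = behaviour.label_components(pca.loadings_)
    comp_scores = pd.DataFrame(
        {
            "wm": pca.component_scores_[:, comp_map["wm"]],
            "rsn": pca.component_scores_[:, comp_map["rsn"]],
        },
        index=pre.index,
    )

    # --- univariate association -------------------------------------------
    comparisons = association.group_compare(table)
    pat_table = table.loc[table["group"] == "patient"]
    correlations = association.correlate_metrics_components(pat_table, comp_scores)

    # --- whole-connectome CCA on degree -----------------------------------
    pat_degrees = (thresholded[is_pat] > 0).sum(axis=2).astype(float)
    degree_scores, degree_pca = cca.reduce_degrees(pat_degrees)
    cca_model = cca.PermutationCCA(
        n_permutations=n_perm_cca, random_state=seed
    ).fit(comp_scores.to_numpy(), degree_scores)
    loadings = cca.back_project(cca_model, pre.to_numpy(), pat_degrees)
    curves = (
        cca.subsample_generalization(
            comp_scores.to_numpy(), degree_scores,
            n_iter=subsample_iters, seed=seed,
        )
        if compute_subsample
        else None
    )

    # --- kernel ridge prediction ------------------------------------------
    pat_ids = comp_scores.index
    nodal = pat_table.loc[pat_table["scope"] == "node"]
    pred_results = {}
    for net in NETWORKS:
        for metric in nodal_metrics:
            feats = (
                nodal.loc[(nodal["network"] == net) & (nodal["metric"] == metric)]
                .pivot(index="subject_id", columns="node", values="value")
                .loc[pat_ids, net_labels[net]]
                .to_numpy(float)
            )
            for comp in COMPONENTS:
                p, model, _ = prediction.permutation_pvalue(
                    feats, comp_scores[comp].to_numpy(),
                    n_perm=n_perm_krr, seed=seed,
                )
                pred_results[(net, metric, comp)] = {
                    "r": model.r_,
                    "r2": model.r2_,
                    "mse": model.mse_,
                    "norm_mse": model.norm_mse_,
                    "p": p,
                    "weights": model.weights_,
                }

    return {
        "cohort": cohort,
        "thresholder": thresholder,
        "hubs": hubs,
        "metric_table": table,
        "behaviour_pca": pca,
        "component_map": comp_map,
        "component_scores": comp_scores,
        "group_comparisons": comparisons,
        "correlations": correlations,
        "degree_pca": degree_pca,
        "cca": cca_model,
        "cca_loadings": loadings,
        "cca_curves": curves,
        "prediction": pred_results,
    }


#: Direction in which each measure is declared related to performance:
#: more surviving connections (degree, global efficiency) go with better
#: scores; pathological increases in segregation (local efficiency,
#: clustering) go with worse scores.
EXPECTED_DIRECTION = {
    "degree": 1, "avg_degree": 1,
    "global_efficiency": 1,
    "local_efficiency": -1, "avg_local_efficiency": -1,
    "clustering": -1,
}


def dissociation_pattern(
    correlations: pd.DataFrame,
    alpha: float = 0.05,
    scope: str = "node",
    directional: bool = True,
) -> dict[tuple[str, str], bool]:
    """Which (network, component) cells show a significant relationship.

    A cell is declared when any of its measures is FDR-significant in the
    expected direction for that measure (``directional=False`` ignores the
    sign). The nodal scope is the sharper probe of the dissociation: nodal
    FDR families contain no anchor tests, so a cell with no real signal
    rarely passes step-up correction.
    """
    out = {}
    sub = correlations.loc[correlations["scope"] == scope]
    for net in NETWORKS:
        for comp in COMPONENTS:
            cell = sub.loc[(sub["network"] == net) & (sub["component"] == comp)]
            hit = cell["q"] < alpha
            if directional:
                expected = cell["metric"].map(EXPECTED_DIRECTION).fillna(0)
                hit = hit & (np.sign(cell["statistic"]) == expected)
            out[(net, comp)] = bool(hit.any())
    return out
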