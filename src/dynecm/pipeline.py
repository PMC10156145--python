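"""End-to-end orchestration of the static + dynamic centrality analysis.

Stages, in order: phenotype classification and motion QC; per-subject static
ECM; voxel-wise group GLM with permutation/TFCE correction (both contrast
directions); significant-cluster extraction; per-subject dynamic ECM;
within-cluster variability; dual regression onto network templates; network
variability; scalar variability models; amyloid x cognition interaction
models.  Works either fully in memory on a synthetic study or from
NIfTI/TSV files via the CLI.

Every result bundle carries the analysis parameters and seed used, so a
rerun with the same configuration reproduces the numbers exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .clusters import (
    ClusterMaskSet,
    cluster_timeseries,
    cluster_variability,
    label_significant_clusters,
)
from .dualreg import (
    TemplateSet,
    dual_regression_stage1,
    network_variability,
    template_mean_timecourses,
)
from .dynamic import build_window_scheme, dynamic_ecm
from .ecm import static_ecm
from .inference import (
    VoxelwiseResult,
    fit_cognition_interaction,
    fit_variability_model,
    make_design,
    permutation_fwe,
)
from .io_volumes import AnalysisMask, MaskedSeries
from .phenotypes import classify_amyloid_tau, fd_qc

__all__ = ["AnalysisParams", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable analysis parameters (validated up front, stored with results)."""

    window_length: int = 100
    n_windows: int = 100
    ecm_tol: float = 1e-9
    ecm_max_iter: int = 1000
    n_permutations: int = 500
    seed: int = 0
    alpha: float = 0.05
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    min_cluster_size: int = 10
    include_at_plus: bool = False  # keep A-T+ in the A+/A- contrast
    variability_source: str = "stage1"  # or "mask-mean"
    cognition_scores: tuple[str, ...] = ("rbans_delayed_memory",)

    def __post_init__(self) -> None:
        if self.variability_source not in ("stage1", "mask-mean"):
            raise ValueError("variability_source must be 'stage1' or 'mask-mean'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Everything the analysis produces, with provenance."""

    params: AnalysisParams
    cohort: pd.DataFrame  # analysis subset, with variability outcomes appended
    mask: AnalysisMask
    static_maps: np.ndarray  # subjects x voxels
    voxelwise: dict[str, VoxelwiseResult]  # contrast name -> result
    clusters: ClusterMaskSet
    cluster_variability: pd.DataFrame  # subject x cluster sd/range (long)
    network_variability: pd.DataFrame  # subject x network sd/range (long)
    variability_models: pd.DataFrame
    interaction_models: pd.DataFrame
    interaction_details: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        lines = [f"analysis n = {len(self.cohort)}"]
        for name, res in self.voxelwise.items():
            n_sig = int((res.fwe_p < self.params.alpha).sum())
            lines.append(
                f"contrast {name}: {n_sig} voxels FWE p < {self.params.alpha}, "
                f"min p = {res.fwe_p.min():.4f}"
            )
        lines.append(f"clusters: {self.clusters.cluster_ids}")
        return "\n".join(lines)


def _analysis_subset(cohort: pd.DataFrame, include_at_plus: bool) -> pd.DataFrame:
    df = fd_qc(classify_amyloid_tau(cohort)) if "qc_pass" not in cohort else cohort
    keep = df["qc_pass"] & ~df["unclassifiable"]
    if not include_at_plus:
        keep &= ~df["at_excluded"]
    return df[keep].reset_index(drop=True)


def run_pipeline(
    cohort: pd.DataFrame,
    series_provider: Callable[[int], MaskedSeries],
    mask: AnalysisMask,
    templates: TemplateSet,
    params: AnalysisParams = AnalysisParams(),
    progress: Callable[[str], None] | None = None,
) -> PipelineResult:
    """Run the full analysis.

    ``series_provider`` maps a row position of the *input* cohort table to
    that subject's raw MaskedSeries (lazily, so large cohorts never hold all
    series in memory).  The cohort is classified and QC'd here; excluded
    subjects are never simulated/loaded.
    """
    log = progress or (lambda msg: None)
    full = fd_qc(classify_amyloid_tau(cohort))
    full["_row"] = np.arange(len(full))
    sub = _analysis_subset(full, params.include_at_plus)
    if len(sub) < 10:
        raise ValueError(f"analysis subset too small (n={len(sub)})")
    T = None

    scheme = None
    static = np.empty((len(sub), mask.n_voxels))
    net_rows: list[dict] = []
    dyn_store: list[np.ndarray] = []
    for i, row in sub.iterrows():
        series = series_provider(int(row["_row"]))
        if T is None:
            T = series.n_timepoints
            scheme = build_window_scheme(T, params.window_length, params.n_windows)
        ec = static_ecm(series, tol=params.ecm_tol, max_iter=params.ecm_max_iter)
        static[i] = ec.values
        dyn = dynamic_ecm(
            series, scheme, tol=params.ecm_tol, max_iter=params.ecm_max_iter
        )
        if params.variability_source == "stage1":
            tcs = dual_regression_stage1(dyn, templates)
        else:
            tcs = template_mean_timecourses(dyn, templates)
        nv = network_variability(tcs)
        for _, r in nv.iterrows():
            net_rows.append(
                {
                    "subject_id": row["subject_id"],
                    "network": r["network"],
                    "sd": r["sd"],
                    "range": r["range"],
                }
            )
        dyn_store.append(dyn.values)
        log(f"subject {row['subject_id']}: static iter={ec.iterations}")

    # voxel-wise group inference, both directions
    design = make_design(sub, ["amyloid_pos", "age", "sex"])
    voxelwise: dict[str, VoxelwiseResult] = {}
    for name, sign in (("A+gtA-", +1.0), ("A-gtA+", -1.0)):
        contrast = design.contrast({"amyloid_pos": sign})
        voxelwise[name] = permutation_fwe(
            static,
            design,
            contrast,
            mask,
            n_permutations=params.n_permutations,
            seed=params.seed,
            alpha=params.alpha,
            E=params.tfce_E,
            H=params.tfce_H,
        )
        log(f"contrast {name}: min FWE p {voxelwise[name].fwe_p.min():.4f}")

    # clusters from the union of both corrected directions
    fwe_min = np.minimum(voxelwise["A+gtA-"].fwe_p, voxelwise["A-gtA+"].fwe_p)
    clusters = label_significant_clusters(
        fwe_min, mask, alpha=params.alpha, min_size=params.min_cluster_size
    )

    clus_rows: list[dict] = []
    if clusters.cluster_ids:
        for i, row in sub.iterrows():
            dyn = _rewrap_dyn(dyn_store[i], mask, scheme)
            series_by_cluster = cluster_timeseries(dyn, clusters)
            cv = cluster_variability(series_by_cluster)
            for _, r in cv.iterrows():
                clus_rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "cluster": r["cluster"],
                        "sd": r["sd"],
                        "range": r["range"],
                    }
                )
    net_var = pd.DataFrame(net_rows)
    clus_var = pd.DataFrame(clus_rows)

    # scalar models: group effects on variability, per network/cluster
    model_rows: list[dict] = []
    table = sub.copy()
    for frame, unit in ((net_var, "network"), (clus_var, "cluster")):
        if frame.empty:
            continue
        for name in frame[unit].unique():
            for measure in ("sd", "range"):
                wide = frame[frame[unit] == name].set_index("subject_id")[measure]
                col = f"{unit}:{name}:{measure}"
                table[col] = table["subject_id"].map(wide)
                res = fit_variability_model(table, col, "amyloid_pos")
                t = res.term("amyloid_pos")
                model_rows.append(
                    {
                        "unit": unit,
                        "name": name,
                        "measure": measure,
                        "beta": t["estimate"],
                        "se": t["se"],
                        "p": t["p"],
                        "n": res.n_obs,
                    }
                )
    variability_models = pd.DataFrame(model_rows)

    # amyloid x cognition interactions on network variability
    inter_rows: list[dict] = []
    inter_details: dict = {}
    if not net_var.empty:
        for name in net_var["network"].unique():
            col = f"network:{name}:sd"
            for score in params.cognition_scores:
                res = fit_cognition_interaction(table, col, score)
                t = res.term("score:amyloid")
                inter_rows.append(
                    {
                        "network": name,
                        "score": score,
                        "interaction_beta": t["estimate"],
                        "interaction_p": t["p"],
                        "slope_aminus": res.simple_slopes.iloc[0]["estimate"],
                        "slope_aplus": res.simple_slopes.iloc[1]["estimate"],
                        "slope_aplus_p": res.simple_slopes.iloc[1]["p"],
                    }
                )
                inter_details[(name, score)] = res
    interaction_models = pd.DataFrame(inter_rows)

    return PipelineResult(
        params=params,
        cohort=table,
        mask=mask,
        static_maps=static,
        voxelwise=voxelwise,
        clusters=clusters,
        cluster_variability=clus_var,
        network_variability=net_var,
        variability_models=variability_models,
        interaction_models=interaction_models,
        interaction_details=inter_details,
    )


def _rewrap_dyn(values: np.ndarray, mask: AnalysisMask, scheme):
    from .dynamic import DynamicCentralitySeries

    return DynamicCentralitySeries(mask=mask, values=values, scheme=scheme)
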