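"""End-to-end orchestration: layers in, survival model and reports out.

The full run is: standardize each layer -> cluster variables into blocks
-> extract one component per block (sparse PC by default) -> column-bind
components across layers -> stepwise-AIC Cox -> cumulative/dynamic ROC,
AUC and Harrell's C at the Kaplan-Meier median (or an explicit time) ->
polar chart of the selected model.  Two comparison variants replace the
component step: ``pca_blocks`` keeps the clustering but uses the dense
first PC of each block; ``pca_noclust`` skips clustering and uses the
first K ordinary PCs of the whole layer (K matching the block count, so
model sizes are comparable).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coxmodel import CoxFit, report_table, stepwise_aic
from .evaluation import cd_roc, harrell_c, median_survival_time, risk_marker
from .integrate import IntegratedDataset, merge_components
from .io import (OmicsMatrix, SurvivalOutcome, align_samples, load_omics_matrix,
                 load_survival, standardize)
from .mpchart import build_mpchart_spec, render_mpchart
from .spca import DEFAULT_FRACTION, DEFAULT_RIDGE, SparseComponent, extract_all, loadings_table
from .varclust import agglomerate, cut_tree, suggest_block_count

__all__ = ["LayerSpec", "PipelineConfig", "PipelineResult", "run"]

VARIANTS = ("bspc", "pca_blocks", "pca_noclust")


@dataclass
class LayerSpec:
    path: str | None
    label: str
    k: int | str = "auto"  # block count or "auto" for the scree rule


@dataclass
class PipelineConfig:
    layers: list[LayerSpec]
    survival_path: str | None = None
    variant: str = "bspc"
    fraction: float = DEFAULT_FRACTION
    ridge: float = DEFAULT_RIDGE
    eval_time: float | str = "km_median"
    direction: str = "both"
    ties: str = "efron"
    k_max: int = 20
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("at least one omics layer is required")
        if not 0 < self.fraction <= 1:
            raise ValueError("sparsity fraction must be in (0, 1]")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        layers = [LayerSpec(**spec) for spec in raw.pop("layers")]
        return cls(layers=layers, **raw)


@dataclass
class PipelineResult:
    fit: CoxFit
    selected: list[str]
    data: IntegratedDataset
    metrics: dict
    block_counts: dict[str, int]
    artifacts: dict[str, Path] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)


def _dense_first_pc(block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm first eigenvector of the block correlation matrix and scores."""
    n = block.shape[0]
    S = block.T @ block / (n - 1)
    vals, vecs = np.linalg.eigh(S)
    v = vecs[:, -1]
    j = int(np.argmax(np.abs(v)))
    if v[j] < 0:
        v = -v
    return v, block @ v


def _layer_components(
    m: OmicsMatrix, spec: LayerSpec, cfg: PipelineConfig, log: list[str]
) -> tuple[list[SparseComponent], int]:
    """Blocks and one component per block for a single standardized layer."""
    tree = agglomerate(m)
    if spec.k == "auto":
        sug = suggest_block_count(tree, min(cfg.k_max, m.n_variables - 1))
        k = sug.k
        log.append(
            f"layer {m.layer_id}: auto block count K={k}"
            + (" (low confidence: flat scree)" if sug.low_confidence else "")
        )
    else:
        k = int(spec.k)
        log.append(f"layer {m.layer_id}: explicit block count K={k}")

    if cfg.variant == "pca_noclust":
        # first K ordinary PCs of the whole layer
        X = m.values
        n = X.shape[0]
        S = X.T @ X / (n - 1)
        vals, vecs = np.linalg.eigh(S)
        comps = []
        for i in range(k):
            v = vecs[:, -(i + 1)]
            j = int(np.argmax(np.abs(v)))
            if v[j] < 0:
                v = -v
            comps.append(
                SparseComponent(
                    layer_id=m.layer_id, block_index=i + 1,
                    label=f"{m.layer_id}{i + 1}",
                    variable_names=m.variable_names, loadings=v,
                    scores=pd.Series(X @ v, index=m.data.index),
                    k=m.n_variables, ridge=0.0,
                )
            )
        log.append(f"layer {m.layer_id}: variant pca_noclust, first {k} PCs of all "
                   f"{m.n_variables} variables")
        return comps, k

    partition = cut_tree(tree, k, m)
    if cfg.variant == "bspc":
        comps = extract_all(partition, m, fraction=cfg.fraction, ridge=cfg.ridge)
        log.append(f"layer {m.layer_id}: sparse PCs, fraction={cfg.fraction}")
    else:  # pca_blocks
        comps = []
        for bi, block_names in enumerate(partition.blocks, start=1):
            v, scores = _dense_first_pc(m.data[block_names].to_numpy())
            comps.append(
                SparseComponent(
                    layer_id=m.layer_id, block_index=bi, label=f"{m.layer_id}{bi}",
                    variable_names=list(block_names), loadings=v,
                    scores=pd.Series(scores, index=m.data.index),
                    k=len(block_names), ridge=0.0,
                )
            )
        log.append(f"layer {m.layer_id}: dense first PC per block")
    return comps, k


def run(
    cfg: PipelineConfig,
    layers: list[OmicsMatrix] | None = None,
    survival: SurvivalOutcome | None = None,
) -> PipelineResult:
    """Execute the full pipeline; write artifacts when ``cfg.out_dir`` is set.

    ``layers`` and ``survival`` may be passed in-memory; otherwise they
    are loaded from the paths in the config.
    """
    log: list[str] = [
        f"blocksurv {__version__}, numpy {np.__version__}, python {platform.python_version()}",
        f"variant={cfg.variant} seed={cfg.seed} fraction={cfg.fraction} "
        f"ridge={cfg.ridge} direction={cfg.direction} ties={cfg.ties}",
    ]
    if layers is None:
        layers = [load_omics_matrix(spec.path, spec.label) for spec in cfg.layers]
    if survival is None:
        if cfg.survival_path is None:
            raise ValueError("no survival table: set survival_path or pass survival=")
        survival = load_survival(cfg.survival_path)
    if len(layers) != len(cfg.layers):
        raise ValueError("layers do not match the configured layer specs")

    try:
        layers, survival = align_samples(layers, survival)
        log.append(f"aligned samples: n={len(survival.sample_ids)}, "
                   f"events={survival.n_events}")
        layers = [standardize(m) for m in layers]
    except ValueError as exc:
        raise RuntimeError(f"[input] {exc}") from exc

    per_layer: list[list[SparseComponent]] = []
    block_counts: dict[str, int] = {}
    for m, spec in zip(layers, cfg.layers):
        try:
            comps, k = _layer_components(m, spec, cfg, log)
        except ValueError as exc:
            raise RuntimeError(f"[clustering/components, layer {m.layer_id}] {exc}") from exc
        per_layer.append(comps)
        block_counts[m.layer_id] = k

    try:
        data = merge_components(per_layer, survival)
        log.append(f"integrated dataset: {data.n_components} components")
    except ValueError as exc:
        raise RuntimeError(f"[integration] {exc}") from exc

    try:
        selected, fit = stepwise_aic(data, survival, direction=cfg.direction, ties=cfg.ties)
        log.append(f"stepwise AIC ({cfg.direction}, from full): selected "
                   f"{len(selected)}/{data.n_components} components, AIC={fit.aic:.2f}")
    except ValueError as exc:
        raise RuntimeError(f"[cox] {exc}") from exc

    try:
        t_eval = (median_survival_time(survival) if cfg.eval_time == "km_median"
                  else float(cfg.eval_time))
        marker = risk_marker(fit, data)
        if fit.labels:
            roc = cd_roc(marker, survival, t_eval)
            auc = roc.auc
            cindex = harrell_c(marker, survival)
        else:
            roc, auc, cindex = None, float("nan"), float("nan")
        log.append(f"evaluation at t={t_eval:.4g}: AUC={auc:.4f}, C-index={cindex:.4f}")
    except ValueError as exc:
        raise RuntimeError(f"[evaluation] {exc}") from exc

    metrics = {
        "variant": cfg.variant,
        "auc": auc,
        "c_index": cindex,
        "t_eval": t_eval,
        "aic": fit.aic,
        "selected": selected,
        "n_components": data.n_components,
        "n_variables_used": int(sum(len(data.provenance[l].support) for l in selected)),
    }

    result = PipelineResult(fit=fit, selected=selected, data=data, metrics=metrics,
                            block_counts=block_counts, log=log)

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        blocks = pd.DataFrame(
            [(c.layer_id, nm, c.block_index)
             for comps in per_layer for c in comps for nm in c.variable_names],
            columns=["layer", "variable", "block"],
        )
        blocks.to_csv(out / "blocks.tsv", sep="\t", index=False)
        loadings_table([c for comps in per_layer for c in comps]).to_csv(
            out / "loadings.tsv", sep="\t", index=False
        )
        report_table(fit, data.provenance).to_csv(out / "cox_table.tsv", sep="\t", index=False)
        (out / "metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
        data.scores.rename_axis("sample").to_csv(out / "integrated.tsv", sep="\t",
                                                 float_format="%.17g")
        model = {
            "labels": fit.labels,
            "coefficients": fit.coef.tolist(),
            "se": fit.se.tolist(),
            "aic": fit.aic,
            "log_likelihood": fit.log_likelihood,
        }
        (out / "model.json").write_text(json.dumps(model, indent=2) + "\n")
        if roc is not None:
            pd.DataFrame(
                {"threshold": roc.thresholds, "sensitivity": roc.sensitivity,
                 "one_minus_specificity": 1.0 - roc.specificity}
            ).to_csv(out / "roc.tsv", sep="\t", index=False)
        if cfg.variant == "bspc" and selected:
            spec = build_mpchart_spec(fit, data.provenance, seed=cfg.seed)
            render_mpchart(spec, out / "mpchart.svg")
            (out / "mpchart.json").write_text(spec.to_json() + "\n")
            result.artifacts["mpchart"] = out / "mpchart.svg"
        (out / "run.log").write_text("\n".join(log) + "\n")
        for nm in ("blocks.tsv", "loadings.tsv", "cox_table.tsv", "metrics.json",
                   "integrated.tsv", "model.json", "run.log"):
            result.artifacts[nm] = out / nm

    return result
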