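"""End-to-end orchestration: normalize -> screen -> latent -> multiblock -> network.

The pipeline reads the features/metadata/blocks CSV dialects (see
:mod:`metabloc.synthdata` for the fixture writers), validates their
cross-references, and executes the full analysis with a single seeded
configuration.  Stage outputs are written as CSV/JSON under a run
directory together with a manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import BlockAnnotation, FeatureMatrix, require_two_groups
from .latent import cross_validate_q2, fit_plsda, permutation_test, vip_table
from .multiblock import (
    assign_blocks,
    block_superscores,
    random_forest_importance,
    validate_blocked_model,
)
from .network import (
    betweenness_centrality,
    differential_network,
    full_network,
    minimal_network,
    select_hub_blocks,
)
from .preprocess import autoscale, pqn_normalize
from .univariate import univariate_table, volcano_table

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "read_features",
    "read_metadata",
    "read_blocks",
    "validate_inputs",
    "analyze",
    "run_pipeline",
    "subgroup_models",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Seeded configuration of a full run (YAML-serializable)."""

    features: str = "features.csv"
    metadata: str = "metadata.csv"
    blocks: str = "blocks.csv"
    output_dir: str = "run"
    reference_group: str = "Term"
    alpha: float = 0.05
    fc_threshold: float = 0.6
    n_components: int = 2
    n_folds: int = 7
    n_permutations: int = 200
    vip_threshold: float | None = None  # None = normality-plot ("auto")
    rf_trees: int = 500
    rf_threshold: float | None = None
    hub_threshold: float | None = None
    weighting: str = "sqrt"
    minimal_criterion: str = "coverage"
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "fc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("seed must be set explicitly (no silent nondeterminism)")
        if self.weighting not in ("sqrt", "linear"):
            raise ValueError("weighting must be 'sqrt' or 'linear'")
        if self.minimal_criterion not in ("coverage", "connectivity"):
            raise ValueError("minimal_criterion must be 'coverage' or 'connectivity'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of a pipeline run."""

    config: dict
    config_hash: str
    seed: int
    version: str
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def read_features(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return FeatureMatrix(df, state="raw")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    if "group" not in df.columns:
        raise ValueError("metadata must have a 'group' column")
    return df


def read_blocks(path: str | Path) -> BlockAnnotation:
    return BlockAnnotation.from_frame(pd.read_csv(path))


def validate_inputs(
    features: FeatureMatrix, metadata: pd.DataFrame, annotation: BlockAnnotation
) -> None:
    """Cross-reference inputs; raise an itemized report on any mismatch."""
    problems: list[str] = []
    missing_meta = [s for s in features.samples if s not in metadata.index]
    if missing_meta:
        problems.append(f"samples without metadata: {missing_meta}")
    groups = metadata.loc[[s for s in features.samples if s in metadata.index], "group"]
    levels = sorted(pd.unique(groups.dropna()))
    if len(levels) != 2:
        problems.append(f"group labels must be binary, got {levels}")
    if not annotation.mapping:
        problems.append("block annotation is empty")
    if problems:
        raise ValueError("input validation failed:\n- " + "\n- ".join(problems))


def analyze(
    features: FeatureMatrix,
    metadata: pd.DataFrame,
    annotation: BlockAnnotation,
    config: PipelineConfig | None = None,
) -> dict:
    """Run every analysis stage in memory; returns a dict of stage outputs."""
    config = config or PipelineConfig()
    config.validate()
    validate_inputs(features, metadata, annotation)
    groups = metadata.loc[features.samples, "group"]
    require_two_groups(groups)
    y = (groups != config.reference_group).astype(int).to_numpy()
    rng = np.random.default_rng(config.seed)

    # preprocess
    pqn = pqn_normalize(features)
    scaled, scaler = autoscale(pqn.normalized)

    # univariate screen
    uva = univariate_table(
        pqn.normalized,
        groups,
        alpha=config.alpha,
        fc_threshold=config.fc_threshold,
        reference=config.reference_group,
    )
    volcano, counts = volcano_table(uva, config.alpha, config.fc_threshold)

    # latent global model
    plsda = fit_plsda(scaled.data, y, n_components=config.n_components)
    perm = permutation_test(
        pqn.normalized.data,
        y,
        n_components=config.n_components,
        n_permutations=config.n_permutations,
        seed=int(rng.integers(2**31)),
        n_folds=config.n_folds,
    )
    vips, vip_thr = vip_table(plsda, threshold=config.vip_threshold)

    # multiblock
    blocks = assign_blocks(annotation, scaled.metabolites)
    superscores = block_superscores(scaled, y, blocks, weighting=config.weighting)
    blocked_report = validate_blocked_model(
        scaled,
        y,
        superscores,
        n_components=config.n_components,
        n_permutations=config.n_permutations,
        seed=int(rng.integers(2**31)),
    )
    importance, rf_thr = random_forest_importance(
        superscores,
        y,
        n_trees=config.rf_trees,
        seed=int(rng.integers(2**31)),
        threshold=config.rf_threshold,
    )

    # group networks
    levels = sorted(pd.unique(groups))
    (ref, other) = (
        (config.reference_group, [l for l in levels if l != config.reference_group][0])
    )
    nets = {}
    for level in (other, ref):
        sub = superscores.scores.loc[groups == level]
        nets[level] = minimal_network(
            full_network(sub), criterion=config.minimal_criterion
        )
    diff = differential_network(nets[other], nets[ref])
    bc = diff.betweenness
    hubs, hub_thr = select_hub_blocks(bc, threshold=config.hub_threshold)

    return {
        "groups": groups,
        "pqn": pqn,
        "autoscaled": scaled,
        "scaler": scaler,
        "univariate": volcano,
        "volcano_counts": counts,
        "plsda": plsda,
        "permutation": perm,
        "vip": vips,
        "vip_threshold": vip_thr,
        "blocks": blocks,
        "superscores": superscores,
        "blocked_report": blocked_report,
        "importance": importance,
        "rf_threshold": rf_thr,
        "minimal_networks": nets,
        "differential_network": diff,
        "betweenness": bc,
        "hubs": hubs,
        "hub_threshold": hub_thr,
    }


def _summary(result: dict, config: PipelineConfig) -> dict:
    counts = result["volcano_counts"]
    perm = result["permutation"]
    return {
        "univariate": {
            "n_up": counts.up,
            "n_down": counts.down,
            "n_ns": counts.ns,
            "n_significant": counts.up + counts.down,
        },
        "plsda": {
            "r2y": result["plsda"].r2y,
            "q2y": perm.observed_q2y,
            "p_r2y": perm.p_r2y,
            "p_q2y": perm.p_q2y,
            "n_components": config.n_components,
        },
        "vip": {
            "threshold": result["vip_threshold"],
            "n_selected": int(result["vip"]["selected"].sum()),
        },
        "multiblock": {
            "n_blocks": len(result["blocks"]),
            "blocked_vs_unblocked": result["blocked_report"],
            "rf_threshold": result["rf_threshold"],
            "rf_selected": list(
                result["importance"].index[result["importance"]["selected"]]
            ),
        },
        "network": {
            "hub_threshold": result["hub_threshold"],
            "hub_blocks": result["hubs"],
            "n_differential_edges": int(len(result["differential_network"].edges)),
        },
    }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis from files and write the output tree."""
    config.validate()
    features = read_features(config.features)
    metadata = read_metadata(config.metadata)
    annotation = read_blocks(config.blocks)
    validate_inputs(features, metadata, annotation)

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        result = analyze(features, metadata, annotation, config)
        caught = [str(w.message) for w in wrec]

    out = Path(config.output_dir)
    manifest = RunManifest(
        config=asdict(config),
        config_hash=config.digest(),
        seed=config.seed,
        version=__version__,
        warnings=caught,
    )

    def _write(relpath: str, writer) -> None:
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        manifest.outputs.append(relpath)

    fmt = "%.17g"
    _write("preprocess/normalized.csv", lambda p: result["pqn"].normalized.data.to_csv(p, float_format=fmt))
    _write("preprocess/dilution_coefficients.csv", lambda p: result["pqn"].dilution_coefficients.to_csv(p, float_format=fmt))
    _write("univariate/univariate.csv", lambda p: result["univariate"].to_csv(p, float_format=fmt))
    _write("latent/scores.csv", lambda p: pd.DataFrame(
        result["plsda"].scores,
        index=result["plsda"].sample_names,
        columns=[f"t{a+1}" for a in range(result["plsda"].n_predictive)],
    ).to_csv(p, float_format=fmt))
    _write("latent/vip.csv", lambda p: result["vip"].to_csv(p, float_format=fmt))
    _write("latent/model_summary.json", lambda p: p.write_text(
        json.dumps(_summary(result, config)["plsda"], indent=1, sort_keys=True)
    ))
    _write("multiblock/block_scores.csv", lambda p: result["superscores"].scores.to_csv(p, float_format=fmt))
    _write("multiblock/block_importance.csv", lambda p: result["importance"].to_csv(p, float_format=fmt))
    _write("multiblock/blocked_model_summary.json", lambda p: p.write_text(
        json.dumps(result["blocked_report"], indent=1, sort_keys=True)
    ))
    for level, net in result["minimal_networks"].items():
        _write(f"network/{level}_minimal_edges.csv", lambda p, n=net: n.edges.to_csv(p, index=False, float_format=fmt))
    _write("network/differential_edges.csv", lambda p: result["differential_network"].edges.to_csv(p, index=False, float_format=fmt))
    _write("network/betweenness.csv", lambda p: result["betweenness"].to_csv(p, float_format=fmt))
    _write("report.json", lambda p: p.write_text(
        json.dumps(_summary(result, config), indent=1, sort_keys=True)
    ))
    manifest.write(out / "manifest.json")
    return manifest


def subgroup_models(
    features: FeatureMatrix,
    metadata: pd.DataFrame,
    stratify_by: str,
    config: PipelineConfig | None = None,
    min_per_class: int = 5,
) -> pd.DataFrame:
    """Confounder check: refit the PLS-DA contrast within covariate strata.

    For each level of the covariate, samples with that level are kept and
    the Prem-vs-Term model is refit; strata missing a class or with fewer
    than ``min_per_class`` samples in either class are skipped with a
    warning.  Returns one summary row (R2Y, Q2Y, permutation p) per
    usable stratum.
    """
    config = config or PipelineConfig()
    if stratify_by not in metadata.columns:
        raise ValueError(f"covariate {stratify_by!r} not present in metadata")
    groups = metadata.loc[features.samples, "group"]
    pqn = pqn_normalize(features)
    rng = np.random.default_rng(config.seed)
    rows = []
    for level in sorted(pd.unique(metadata[stratify_by].dropna())):
        keep = metadata.loc[features.samples, stratify_by] == level
        sub_groups = groups[keep]
        class_counts = sub_groups.value_counts()
        if len(class_counts) < 2 or class_counts.min() < min_per_class:
            warnings.warn(
                f"stratum {stratify_by}={level!r} skipped "
                f"(class counts: {class_counts.to_dict()})",
                UserWarning,
            )
            continue
        x = pqn.normalized.data.loc[keep]
        y = (sub_groups != config.reference_group).astype(int).to_numpy()
        ncomp = min(config.n_components, len(x) - 1, x.shape[1])
        perm = permutation_test(
            x,
            y,
            n_components=ncomp,
            n_permutations=config.n_permutations,
            seed=int(rng.integers(2**31)),
            n_folds=min(config.n_folds, int(class_counts.min())),
        )
        rows.append(
            {
                "stratum": level,
                "n": int(keep.sum()),
                "r2y": perm.observed_r2y,
                "q2y": perm.observed_q2y,
                "p_r2y": perm.p_r2y,
                "p_q2y": perm.p_q2y,
            }
        )
    if not rows:
        raise ValueError(f"no usable stratum for covariate {stratify_by!r}")
    return pd.DataFrame(rows).set_index("stratum")
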