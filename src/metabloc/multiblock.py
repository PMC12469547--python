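"""Hierarchical multiblock model over functional metabolite blocks.

Metabolites are grouped into biological-function blocks (a metabolite
may carry up to three functions); blocks with fewer than three members
are discarded.  Each block gets its own OPLS-DA model (one predictive +
one orthogonal component by default) and the per-sample predictive
score t1 summarizes the block.  Superscores are weighted by block size
(sqrt(n_k) / sqrt(sum n_m), so the squared weights sum to 1) and
assembled into a samples x blocks matrix.  A PLS-DA refit on that
matrix checks the blocking did not distort the sample mapping, and a
random-forest Gini importance with a normality-plot threshold selects
the blocks most dysregulated between the groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import BlockAnnotation, FeatureMatrix
from .latent import (
    cross_validate_q2,
    fit_oplsda,
    fit_plsda,
    normality_threshold,
    permutation_test,
)

__all__ = [
    "assign_blocks",
    "BlockScoreMatrix",
    "block_superscores",
    "validate_blocked_model",
    "random_forest_importance",
]

logger = logging.getLogger(__name__)

MIN_BLOCK_MEMBERS = 3


def assign_blocks(
    annotation: BlockAnnotation,
    metabolites_present,
    min_members: int = MIN_BLOCK_MEMBERS,
) -> dict[str, list[str]]:
    """Invert the annotation into block -> member metabolites.

    Restricted to metabolites present in the feature matrix; blocks with
    fewer than ``min_members`` members are discarded (and logged).
    Unannotated metabolites belong to no block.
    """
    present = [str(m) for m in metabolites_present]
    present_set = set(present)
    blocks: dict[str, list[str]] = {}
    for met in present:
        for label in annotation.labels_for(met):
            blocks.setdefault(label, []).append(met)
    discarded = {b: v for b, v in blocks.items() if len(v) < min_members}
    if discarded:
        logger.info(
            "discarding %d block(s) with < %d members: %s",
            len(discarded),
            min_members,
            sorted(discarded),
        )
    kept = {b: v for b, v in sorted(blocks.items()) if len(v) >= min_members}
    if not kept:
        raise ValueError("no block retains the minimum number of members")
    unused = present_set - {m for v in kept.values() for m in v}
    if unused:
        logger.info("%d metabolite(s) belong to no retained block", len(unused))
    return kept


@dataclass
class BlockScoreMatrix:
    """Samples x blocks matrix of weighted per-block OPLS-DA t1 superscores."""

    scores: pd.DataFrame
    weights: pd.Series
    sizes: pd.Series

    @property
    def blocks(self) -> list[str]:
        return list(self.scores.columns)


def _block_weights(sizes: pd.Series, weighting: str) -> pd.Series:
    if weighting == "sqrt":
        w = np.sqrt(sizes.astype(float)) / np.sqrt(float(sizes.sum()))
    elif weighting == "linear":
        w = sizes.astype(float) / np.sqrt(float((sizes**2).sum()))
    else:
        raise ValueError("weighting must be 'sqrt' or 'linear'")
    return w.rename("weight")


def block_superscores(
    X: FeatureMatrix | pd.DataFrame,
    y,
    blocks: dict[str, list[str]],
    n_orthogonal: int = 1,
    weighting: str = "sqrt",
) -> BlockScoreMatrix:
    """Per-block OPLS-DA t1 scores, sd-normalized, then size-weighted.

    Each block's t1 is scaled to unit sample sd before the weight is
    applied, so the block-size weight (not the raw score norm) carries
    the size information.  Degenerate blocks (rank < 2) fall back to a
    one-component PLS-DA score with a warning.
    """
    data = X.data if isinstance(X, FeatureMatrix) else X
    missing = {m for members in blocks.values() for m in members} - set(data.columns)
    if missing:
        raise ValueError(f"block members absent from the matrix: {sorted(missing)[:5]}")
    sizes = pd.Series({b: len(m) for b, m in blocks.items()}, name="n_k")
    weights = _block_weights(sizes, weighting)
    cols = {}
    for b, members in blocks.items():
        sub = data[members]
        try:
            t1 = fit_oplsda(sub, y, n_orthogonal=n_orthogonal).t1
        except ValueError:
            warnings.warn(
                f"block {b!r} is rank-deficient for OPLS; falling back to PLS-DA t1",
                UserWarning,
                stacklevel=2,
            )
            t1 = fit_plsda(sub, y, n_components=1).t1
        sd = t1.std(ddof=1)
        if sd > 0:
            t1 = t1 / sd
        cols[b] = weights[b] * t1
    scores = pd.DataFrame(cols, index=data.index)
    return BlockScoreMatrix(scores=scores, weights=weights, sizes=sizes)


def validate_blocked_model(
    X: FeatureMatrix | pd.DataFrame,
    y,
    block_scores: BlockScoreMatrix,
    n_components: int = 2,
    n_permutations: int = 200,
    seed: int = 0,
    r_threshold: float = 0.7,
) -> dict:
    """Compare the blocked PLS-DA against the unblocked one.

    Reports |Pearson r| between the two (sign-aligned) first predictive
    scores, both models' R2Y / Q2Y / permutation p-values, and a verdict
    ("similar mapping" unless |r| < r_threshold).
    """
    data = X.data if isinstance(X, FeatureMatrix) else X
    ncomp_blocked = min(n_components, block_scores.scores.shape[1])

    unblocked = fit_plsda(data, y, n_components=n_components)
    blocked = fit_plsda(block_scores.scores, y, n_components=ncomp_blocked)
    r = float(np.corrcoef(unblocked.t1, blocked.t1)[0, 1])

    perm_unblocked = permutation_test(
        data, y, n_components, n_permutations=n_permutations, seed=seed
    )
    perm_blocked = permutation_test(
        block_scores.scores,
        y,
        ncomp_blocked,
        n_permutations=n_permutations,
        seed=seed + 1,
    )
    report = {
        "t1_abs_correlation": abs(r),
        "distorted": abs(r) < r_threshold,
        "verdict": "similar mapping" if abs(r) >= r_threshold else "distorted",
        "unblocked": {
            "r2y": unblocked.r2y,
            "q2y": perm_unblocked.observed_q2y,
            "p_r2y": perm_unblocked.p_r2y,
            "p_q2y": perm_unblocked.p_q2y,
        },
        "blocked": {
            "r2y": blocked.r2y,
            "q2y": perm_blocked.observed_q2y,
            "p_r2y": perm_blocked.p_r2y,
            "p_q2y": perm_blocked.p_q2y,
        },
    }
    return report


def random_forest_importance(
    block_scores: BlockScoreMatrix,
    y,
    n_trees: int = 500,
    seed: int = 0,
    threshold: float | None = None,
    k_sd: float = 2.0,
) -> tuple[pd.DataFrame, float]:
    """Mean-decrease-Gini block importance with a normality-plot threshold.

    Returns the importance table sorted descending (columns: importance,
    selected) and the threshold used (on the raw importance scale);
    blocks at or above the threshold are the candidate dysregulated
    functions.  Null Gini importances are positive and right-skewed, so
    the normality plot is drawn on log-importances — without the
    transform the top block would be flagged far too often on
    label-permuted data.
    """
    if n_trees < 50:
        warnings.warn("fewer than 50 trees gives unstable importances", UserWarning)
    y_arr = np.asarray(pd.Series(y).loc[block_scores.scores.index] if isinstance(y, pd.Series) else y)
    if len(pd.unique(y_arr)) != 2:
        raise ValueError("two classes required for the forest")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(block_scores.scores.to_numpy(), y_arr)
    imp = pd.Series(
        forest.feature_importances_, index=block_scores.scores.columns, name="importance"
    )
    table = pd.DataFrame({"importance": imp})
    if threshold is None:
        vals = imp.to_numpy()
        floor = vals[vals > 0].min() * 1e-3 if (vals > 0).any() else 1e-12
        logged = np.log(vals + floor)
        logged = logged - logged.min()
        log_thr = normality_threshold(logged, k_sd=k_sd)
        selected = logged >= log_thr
        thr = float(vals[selected].min()) if selected.any() else float("inf")
        table["selected"] = selected
    else:
        thr = float(threshold)
        table["selected"] = table["importance"] >= thr
    return table.sort_values("importance", ascending=False), thr
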