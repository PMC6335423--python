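"""PPARgamma activation score: signature refinement and per-sample scoring.

A seed signature (genes known to respond to PPARgamma activity) is refined
against an expression matrix by a quartile contrast: samples are ranked by
the anchor gene's expression (PPARG itself) and each seed gene is tested
for higher expression in the top quartile than in the bottom quartile with
a one-sided Wilcoxon rank-sum test under Benjamini-Hochberg FDR control.
The activation score of a sample is then the mean of the centered (per
gene, across samples) expression of the retained genes.

Expression values are assumed to be on a log scale already; no
normalization is applied here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignatureDefinition",
    "SignatureScoreResult",
    "validate_expression",
    "refine_signature",
    "score_samples",
    "classify_activation",
    "sort_by_score",
]


class ValidationError(ValueError):
    pass


def validate_expression(expr: pd.DataFrame, min_samples: int = 8) -> pd.DataFrame:
    """Check an expression matrix (genes x samples, log scale)."""
    if expr.index.has_duplicates:
        raise ValidationError("duplicate gene identifiers in expression matrix")
    if expr.columns.has_duplicates:
        raise ValidationError("duplicate sample identifiers in expression matrix")
    if expr.shape[1] < min_samples:
        raise ValidationError(
            f"need at least {min_samples} samples, got {expr.shape[1]}"
        )
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValidationError("expression matrix contains non-finite values")
    return expr


@dataclass(frozen=True)
class SignatureDefinition:
    """A refined signature and the refinement settings that produced it."""

    seed_genes: frozenset
    refined_genes: frozenset
    quartile: float
    alpha: float
    test_name: str
    missing_genes: frozenset = frozenset()
    adjusted_p: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SignatureScoreResult:
    scores: pd.Series  # sample -> activation score
    signature: SignatureDefinition
    centering: Literal["gene_mean", "gene_median"]
    classification: pd.Series | None = None  # sample -> bool, set by classify


def _quartile_bins(expr: pd.DataFrame, anchor_gene: str, quartile: float):
    anchor = expr.loc[anchor_gene]
    if float(anchor.max() - anchor.min()) == 0.0:
        raise ValidationError("anchor gene is constant; ranking undefined")
    n = expr.shape[1]
    m = math.ceil(quartile * n)
    if m < 2:
        raise ValidationError(
            f"quartile bins would hold {m} sample(s); need at least 2"
        )
    # Stable ordering: anchor expression descending, ties broken by sample id.
    order = sorted(expr.columns, key=lambda s: (-anchor[s], s))
    return order[:m], order[-m:]


def refine_signature(
    expr: pd.DataFrame,
    anchor_gene: str,
    seed_genes: Iterable[str],
    quartile: float = 0.25,
    alpha: float = 0.05,
    test: Literal["ranksum", "welch"] = "ranksum",
) -> SignatureDefinition:
    """Retain seed genes over-expressed in anchor-high vs anchor-low samples.

    Seed genes absent from the matrix are excluded silently but recorded in
    the returned definition.
    """
    validate_expression(expr)
    if not (0.0 < quartile <= 0.5):
        raise ValidationError("quartile must lie in (0, 0.5]")
    if anchor_gene not in expr.index:
        raise ValidationError(f"anchor gene {anchor_gene!r} not in matrix")
    seed = sorted(set(seed_genes))
    present = [g for g in seed if g in expr.index]
    missing = frozenset(set(seed) - set(present))
    if not present:
        raise ValidationError("no seed genes present in the expression matrix")
    top, bottom = _quartile_bins(expr, anchor_gene, quartile)

    pvals = []
    for g in present:
        x = expr.loc[g, top].to_numpy(dtype=float)
        y = expr.loc[g, bottom].to_numpy(dtype=float)
        if test == "ranksum":
            p = sps.mannwhitneyu(x, y, alternative="greater").pvalue
        elif test == "welch":
            p = sps.ttest_ind(x, y, equal_var=False, alternative="greater").pvalue
        else:
            raise ValidationError(f"unknown contrast test {test!r}")
        pvals.append(float(p))
    reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    refined = frozenset(g for g, r in zip(present, reject) if r)
    return SignatureDefinition(
        seed_genes=frozenset(seed),
        refined_genes=refined,
        quartile=quartile,
        alpha=alpha,
        test_name=test,
        missing_genes=missing,
        adjusted_p=dict(zip(present, (float(v) for v in p_adj))),
    )


def score_samples(
    expr: pd.DataFrame,
    signature: SignatureDefinition,
    centering: Literal["gene_mean", "gene_median"] = "gene_mean",
) -> SignatureScoreResult:
    """Activation score: mean over signature genes of centered expression.

    Centering subtracts each gene's across-sample mean (or median), so with
    gene-mean centering the scores sum to zero over samples.
    """
    genes = sorted(signature.refined_genes)
    if not genes:
        raise ValidationError("refined signature is empty; nothing to score")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise ValidationError(f"signature genes absent from matrix: {missing}")
    sub = expr.loc[genes].astype(float)
    if centering == "gene_mean":
        centered = sub.sub(sub.mean(axis=1), axis=0)
    elif centering == "gene_median":
        centered = sub.sub(sub.median(axis=1), axis=0)
    else:
        raise ValidationError(f"unknown centering {centering!r}")
    scores = centered.mean(axis=0)
    scores.name = "activation_score"
    return SignatureScoreResult(scores=scores, signature=signature,
                                centering=centering)


def classify_activation(
    result: SignatureScoreResult,
    rule: str = "positive",
    cutoff: float | None = None,
) -> pd.Series:
    """Binarize scores into an activation-high indicator.

    Rules: ``"positive"`` (score > 0, the default), ``"top_quartile"``
    (highest 25% of samples, ties broken by sample id), or ``"fixed"``
    with an explicit ``cutoff``.
    """
    scores = result.scores
    if rule == "positive":
        high = scores > 0.0
    elif rule == "top_quartile":
        k = math.ceil(0.25 * len(scores))
        order = sorted(scores.index, key=lambda s: (-scores[s], s))
        chosen = set(order[:k])
        high = pd.Series([s in chosen for s in scores.index], index=scores.index)
    elif rule == "fixed":
        if cutoff is None:
            raise ValidationError("rule 'fixed' requires a cutoff")
        high = scores > cutoff
    else:
        raise ValidationError(f"unknown threshold rule {rule!r}")
    high.name = "activation_high"
    return high


def sort_by_score(result: SignatureScoreResult) -> list[str]:
    """Samples in descending score order; ties break by sample identifier."""
    return sorted(result.scores.index, key=lambda s: (-result.scores[s], s))
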