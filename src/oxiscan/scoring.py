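"""Signature-based hypoxia scoring of bulk expression cohorts.

A sample's score for a gene signature is the sum of per-gene votes: +1 when
the sample's abundance of the gene is strictly above the cohort median for
that gene, -1 otherwise (ties at the median vote -1; signed genes multiply
the vote by their sign). Scores are therefore integers in [-n, +n] with the
same parity as n, the number of signature genes found in the matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._spearman import SpearmanResult, spearman_as89
from .errors import (
    CohortSizeError,
    DegenerateDataError,
    SignatureCoverageError,
    ValidationError,
)

log = logging.getLogger(__name__)

DEFAULT_MIN_NORMALS = 15


@dataclass(frozen=True)
class SignatureGeneSet:
    """A named gene list with optional per-gene signs (+1 up, -1 down)."""

    name: str
    genes: tuple[str, ...]
    signs: tuple[int, ...] | None = None

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"signature {self.name!r} has duplicate genes")
        if self.signs is not None:
            if len(self.signs) != len(self.genes):
                raise ValidationError(
                    f"signature {self.name!r}: signs/genes length mismatch")
            if any(s not in (-1, 1) for s in self.signs):
                raise ValidationError(
                    f"signature {self.name!r}: signs must be +1 or -1")

    @classmethod
    def from_genes(cls, name: str, genes, signs=None) -> "SignatureGeneSet":
        return cls(name=name, genes=tuple(genes),
                   signs=None if signs is None else tuple(signs))


@dataclass
class ScoreSummary:
    cancer_type: str
    n: int
    median: float
    iqr: float
    fraction_positive: float


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix (genes x samples): unique ids, finite, >= 0."""
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
    if expr.columns.has_duplicates:
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValidationError("expression matrix contains negative abundances")
    return expr


def compute_hypoxia_scores(
    expr: pd.DataFrame, signature: SignatureGeneSet
) -> pd.DataFrame:
    """Score every sample against one signature.

    Parameters
    ----------
    expr
        Genes x samples abundance matrix (non-negative, finite).
    signature
        Gene list; genes absent from ``expr`` are skipped (and logged).

    Returns
    -------
    DataFrame with columns ``sample``, ``signature``, ``score``,
    ``n_genes_used``.
    """
    validate_expression(expr)
    if expr.shape[1] < 2:
        raise CohortSizeError(
            f"scoring needs >= 2 samples, got {expr.shape[1]}")

    present_mask = [g in expr.index for g in signature.genes]
    present = [g for g, m in zip(signature.genes, present_mask) if m]
    if not present:
        raise SignatureCoverageError(
            f"no gene of signature {signature.name!r} found in the matrix")
    n_missing = len(signature.genes) - len(present)
    if n_missing:
        log.warning(
            "signature %s: %d/%d genes absent from the matrix and skipped",
            signature.name, n_missing, len(signature.genes))

    sub = expr.loc[present].to_numpy(dtype=float)
    medians = np.median(sub, axis=1, keepdims=True)
    votes = np.where(sub > medians, 1, -1)
    if signature.signs is not None:
        signs = np.array(
            [s for s, m in zip(signature.signs, present_mask) if m])
        votes = votes * signs[:, None]
    scores = votes.sum(axis=0)

    return pd.DataFrame({
        "sample": expr.columns,
        "signature": signature.name,
        "score": scores.astype(int),
        "n_genes_used": len(present),
    })


def scale_median_scores(medians: dict[str, float]) -> dict[str, float]:
    """Affinely rescale per-type median scores so min -> -1 and max -> +1."""
    if len(medians) < 2:
        raise CohortSizeError("need >= 2 cancer types to rescale")
    values = np.array(list(medians.values()), dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateDataError("all medians identical; range is degenerate")
    return {k: float(2.0 * (v - lo) / (hi - lo) - 1.0)
            for k, v in medians.items()}


def cross_signature_concordance(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame
) -> SpearmanResult:
    """Spearman concordance of two score tables on their shared samples."""
    a = scores_a.set_index("sample")["score"]
    b = scores_b.set_index("sample")["score"]
    shared = a.index.intersection(b.index)
    if len(shared) < 4:
        raise CohortSizeError(
            f"need >= 4 shared samples, got {len(shared)}")
    return spearman_as89(a.loc[shared].to_numpy(), b.loc[shared].to_numpy())


def tumour_vs_normal_test(tumour_scores, normal_scores) -> float:
    """Two-sided Mann-Whitney U p-value comparing tumour vs normal scores."""
    t = np.asarray(tumour_scores, dtype=float)
    n = np.asarray(normal_scores, dtype=float)
    if t.size == 0 or n.size == 0:
        raise CohortSizeError("both groups must be non-empty")
    res = stats.mannwhitneyu(t, n, alternative="two-sided", method="auto")
    return float(res.pvalue)


def tumour_vs_normal_by_tissue(
    tumour: pd.DataFrame,
    normal: pd.DataFrame,
    min_normals: int = DEFAULT_MIN_NORMALS,
) -> pd.DataFrame:
    """Run the tumour-vs-normal comparison per tissue type.

    Both inputs need columns ``tissue`` and ``score``. Tissues with fewer
    than ``min_normals`` normal samples are skipped with a logged reason.
    """
    rows = []
    for tissue, t_grp in tumour.groupby("tissue"):
        n_grp = normal.loc[normal["tissue"] == tissue, "score"]
        if len(n_grp) < min_normals:
            log.info("tissue %s skipped: %d normals < %d required",
                     tissue, len(n_grp), min_normals)
            continue
        p = tumour_vs_normal_test(t_grp["score"].to_numpy(), n_grp.to_numpy())
        rows.append({"tissue": tissue, "n_tumour": len(t_grp),
                     "n_normal": len(n_grp), "p": p})
    return pd.DataFrame(rows, columns=["tissue", "n_tumour", "n_normal", "p"])


def within_type_variance_fraction(scores, cancer_labels) -> float:
    """Within-group sum of squares as a fraction of total sum of squares."""
    y = np.asarray(scores, dtype=float)
    labels = np.asarray(cancer_labels)
    if y.size < 2:
        raise CohortSizeError("need >= 2 samples")
    if len(np.unique(labels)) < 2:
        raise CohortSizeError("need >= 2 groups")
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if total_ss == 0:
        raise DegenerateDataError("total variance is zero")
    within_ss = 0.0
    for g in np.unique(labels):
        grp = y[labels == g]
        within_ss += float(np.sum((grp - grp.mean()) ** 2))
    return within_ss / total_ss


def summarize_scores(scores, cancer_labels) -> list[ScoreSummary]:
    """Per-type median, IQR (linear-interpolation quantiles), fraction > 0."""
    df = pd.DataFrame({"score": np.asarray(scores, dtype=float),
                       "type": np.asarray(cancer_labels)})
    out = []
    for cancer_type, grp in df.groupby("type", sort=True):
        v = grp["score"].to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        out.append(ScoreSummary(
            cancer_type=str(cancer_type),
            n=v.size,
            median=float(med),
            iqr=float(q3 - q1),
            fraction_positive=float((v > 0).mean()),
        ))
    out.sort(key=lambda s: s.median, reverse=True)
    return out


def dichotomize_scores(scores: pd.Series) -> pd.Series:
    """Median-dichotomize scores: above the cohort median -> ``hypoxic``.

    Values at or below the median are ``normoxic``. Constant input yields
    all-normoxic with a warning.
    """
    s = pd.Series(scores, dtype=float)
    if s.size < 2:
        raise CohortSizeError("need >= 2 samples to dichotomize")
    med = float(s.median())
    labels = pd.Series(
        np.where(s.to_numpy() > med, "hypoxic", "normoxic"), index=s.index)
    counts = labels.value_counts()
    if counts.get("hypoxic", 0) == 0:
        log.warning("all scores at or below the median; every sample normoxic")
    log.info("dichotomized: %d hypoxic, %d normoxic (median %.3g)",
             counts.get("hypoxic", 0), counts.get("normoxic", 0), med)
    return labels
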