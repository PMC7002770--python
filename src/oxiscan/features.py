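"""Analysis-ready per-sample feature construction.

Collapses long driver-event records to one status per (sample, gene),
converts signature exposure counts to per-sample proportions, classifies
clonal architecture, and joins everything (with covariates and hypoxia
scores) into one modelling table.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import JoinError, ValidationError

log = logging.getLogger(__name__)

EVENT_CLASSES = ("SNV", "CNA", "SV")
STATUS_WILDTYPE = "wildtype"
STATUS_COMPOUND = "compound"


def summarize_driver_status(events: pd.DataFrame, samples, genes
                            ) -> pd.DataFrame:
    """One status per (sample, gene) over the full grid.

    A pair with no events is ``wildtype``; exactly one distinct event class
    keeps that class's name; more than one distinct class is ``compound``.
    Duplicate (sample, gene, class) records collapse to one.
    """
    required = {"sample", "gene", "event_class"}
    if not required <= set(events.columns):
        raise ValidationError(
            f"driver events need columns {sorted(required)}")
    bad = set(events["event_class"].unique()) - set(EVENT_CLASSES)
    if bad:
        raise ValidationError(
            f"unknown event class token(s): {sorted(bad)}")

    dedup = events.drop_duplicates(["sample", "gene", "event_class"])
    grouped = dedup.groupby(["sample", "gene"])["event_class"].agg(
        lambda s: s.iloc[0] if len(s) == 1 else STATUS_COMPOUND)

    idx = pd.MultiIndex.from_product([list(samples), list(genes)],
                                     names=["sample", "gene"])
    status = grouped.reindex(idx).fillna(STATUS_WILDTYPE)
    out = status.rename("status").reset_index()
    return out


def driver_indicator_matrix(status: pd.DataFrame) -> pd.DataFrame:
    """Binary mutated/wildtype matrix (samples x genes) from a status table."""
    wide = status.pivot(index="sample", columns="gene", values="status")
    return (wide != STATUS_WILDTYPE).astype(int)


def compute_signature_proportions(exposures: pd.DataFrame) -> pd.DataFrame:
    """Per-sample exposure proportions (samples x signatures).

    Samples whose total attributed mutation count is zero are excluded
    with a log entry rather than producing NaN rows.
    """
    required = {"sample", "signature", "mutations"}
    if not required <= set(exposures.columns):
        raise ValidationError(f"exposures need columns {sorted(required)}")
    if (exposures["mutations"] < 0).any():
        raise ValidationError("exposure counts must be >= 0")
    wide = exposures.pivot_table(index="sample", columns="signature",
                                 values="mutations", aggfunc="sum",
                                 fill_value=0)
    totals = wide.sum(axis=1)
    zero = totals[totals == 0].index.tolist()
    if zero:
        log.info("excluding %d sample(s) with zero total mutations: %s",
                 len(zero), zero[:5])
        wide = wide.drop(index=zero)
        totals = totals.drop(index=zero)
    return wide.div(totals, axis=0)


def classify_clonality(subclonality: pd.DataFrame) -> pd.Series:
    """monoclonal iff exactly one cluster of cells was identified."""
    if "n_clusters" not in subclonality.columns:
        raise ValidationError("subclonality table needs column 'n_clusters'")
    n = subclonality["n_clusters"]
    if (n < 1).any():
        raise ValidationError("n_clusters must be >= 1 for every sample")
    return pd.Series(np.where(n == 1, "monoclonal", "polyclonal"),
                     index=subclonality.index, name="clonality")


def assemble_feature_table(
    covariates: pd.DataFrame,
    scores: pd.DataFrame,
    density: pd.DataFrame | None = None,
    driver_status: pd.DataFrame | None = None,
    proportions: pd.DataFrame | None = None,
    subclonality: pd.DataFrame | None = None,
    signature: str | None = None,
) -> pd.DataFrame:
    """Inner-join all per-sample tables into one modelling frame.

    ``scores`` is a long score table; when several signatures are present,
    ``signature`` selects the one used as the ``hypoxia_score`` column.
    Driver indicators are binary (mutated vs wildtype). Samples missing
    from any provided table are dropped and reported.
    """
    sc = scores
    if signature is not None:
        sc = sc[sc["signature"] == signature]
    elif sc["signature"].nunique() > 1:
        raise ValidationError(
            "several signatures in the score table; pass signature=...")
    base = covariates.merge(
        sc[["sample", "score"]].rename(columns={"score": "hypoxia_score"}),
        on="sample", how="inner")

    pieces: list[tuple[str, pd.DataFrame]] = []
    if density is not None:
        pieces.append(("density", density))
    if driver_status is not None:
        ind = driver_indicator_matrix(driver_status)
        ind.columns = [f"driver_{g}" for g in ind.columns]
        pieces.append(("drivers", ind.reset_index()))
    if proportions is not None:
        prop = proportions.copy()
        prop.columns = [f"prop_{s}" for s in prop.columns]
        pieces.append(("exposures", prop.reset_index()))
    if subclonality is not None:
        sub = subclonality.copy()
        if "clonality" not in sub.columns:
            sub["clonality"] = classify_clonality(sub)
        sub["polyclonal"] = (sub["clonality"] == "polyclonal").astype(int)
        sub["n_subclones"] = sub["n_clusters"]
        pieces.append(("subclonality",
                       sub[["sample", "n_subclones", "n_clonal",
                            "n_subclonal", "polyclonal"]]))

    merged = base
    for name, piece in pieces:
        before = set(merged["sample"])
        incoming = set(piece["sample"])
        dropped = before - incoming
        if dropped:
            log.info("join with %s table drops %d sample(s): %s",
                     name, len(dropped), sorted(dropped)[:5])
        merged = merged.merge(piece, on="sample", how="inner")
        if merged.empty:
            raise JoinError(
                f"empty intersection joining {name} table "
                f"({len(before)} x {len(incoming)} samples)")
    if merged.empty:
        raise JoinError("no samples shared between covariates and scores")

    n_missing = merged.isna().sum()
    for col, cnt in n_missing[n_missing > 0].items():
        log.info("feature %s: %d missing values", col, cnt)
    return merged.reset_index(drop=True)
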