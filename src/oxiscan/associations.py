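"""Association scans of per-sample features against hypoxia scores.

Each feature is tested with a likelihood-ratio comparison of nested
mixed models (full: response ~ feature + adjusters + (1|group); null drops
the feature), both fitted by ML on identical rows. Families of tests are
corrected with Bonferroni when fewer than 20 tests were run and
Benjamini-Hochberg otherwise, unless a correction is forced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    CohortSizeError,
    DegenerateDataError,
    FitError,
    ValidationError,
)
from .lmm import (
    LmmFit,
    ModelSpec,
    adjust_pvalues,
    fit_lmm,
    lrt_compare,
    nakagawa_r2,
)

log = logging.getLogger(__name__)

DEFAULT_ADJUSTERS = ("purity", "age", "sex")
SMALL_FAMILY_MAX = 20  # below this many tests, Bonferroni; else BH FDR


@dataclass(frozen=True)
class ScanConfig:
    features: tuple[str, ...]
    response: str = "hypoxia_score"
    adjusters: tuple[str, ...] = DEFAULT_ADJUSTERS
    group: str = "cancer_type"
    min_samples_per_type: int = 15
    min_mutated: int = 5           # binary features with fewer carriers skip
    correction: str | None = None  # None -> automatic by family size

    def __post_init__(self):
        if self.min_samples_per_type < 1:
            raise ValidationError("min_samples_per_type must be >= 1")
        if self.correction not in (None, "bonferroni", "bh_fdr"):
            raise ValidationError(f"unknown correction {self.correction!r}")


def apply_min_samples_filter(data: pd.DataFrame, group: str,
                             k: int) -> pd.DataFrame:
    """Drop all rows of groups with fewer than ``k`` samples."""
    if group not in data.columns:
        raise ValidationError(f"grouping column {group!r} absent")
    sizes = data[group].value_counts()
    keep = sizes[sizes >= k].index
    removed = sizes[sizes < k]
    if len(removed):
        log.info("min-samples filter (k=%d) removes %d group(s), %d row(s)",
                 k, len(removed), int(removed.sum()))
    if not len(keep):
        raise CohortSizeError(
            f"no group reaches {k} samples; largest has {sizes.max()}")
    return data[data[group].isin(keep)].reset_index(drop=True)


def _choose_correction(n_tests: int, forced: str | None) -> str:
    if forced is not None:
        return forced
    return "bonferroni" if n_tests < SMALL_FAMILY_MAX else "bh_fdr"


def _is_binary(values: pd.Series) -> bool:
    u = pd.unique(values.dropna())
    return len(u) <= 2 and set(np.asarray(u, dtype=float)) <= {0.0, 1.0}


def test_feature(data: pd.DataFrame, feature: str,
                 config: ScanConfig) -> dict:
    """Full-vs-null LRT for one feature; returns one scan record."""
    record = {"feature": feature, "n": 0, "n_groups": 0,
              "p": np.nan, "r2_marginal": np.nan, "r2_conditional": np.nan,
              "direction": 0, "note": ""}
    if feature not in data.columns:
        record["note"] = "skipped: column absent"
        log.warning("feature %s absent from the data", feature)
        return record
    spec = ModelSpec(response=config.response,
                     terms=(feature, *config.adjusters),
                     group=config.group)
    rows = data.dropna(subset=list(dict.fromkeys(spec.columns)))
    record["n"] = len(rows)
    record["n_groups"] = rows[config.group].nunique() if len(rows) else 0
    if len(rows) and _is_binary(rows[feature]):
        n_carriers = int(rows[feature].astype(float).sum())
        if n_carriers < config.min_mutated:
            record["note"] = f"skipped: {n_carriers} carriers < " \
                             f"{config.min_mutated}"
            log.info("feature %s %s", feature, record["note"])
            return record
    try:
        full = fit_lmm(rows, spec, method="ML")
        null = fit_lmm(rows, spec.drop_terms(feature), method="ML")
        record["p"] = lrt_compare(full, null)
        r2 = nakagawa_r2(full)
        record["r2_marginal"] = r2.marginal
        record["r2_conditional"] = r2.conditional
        record["direction"] = int(np.sign(full.params[feature]))
    except (FitError, ValidationError, CohortSizeError) as exc:
        record["note"] = f"fit failed: {exc}"
        log.warning("feature %s fit failed: %s", feature, exc)
    return record


def run_association_scan(data: pd.DataFrame,
                         config: ScanConfig) -> pd.DataFrame:
    """Scan every configured feature; returns records sorted by adjusted p."""
    if not config.features:
        return pd.DataFrame(columns=[
            "feature", "p", "p_adjusted", "r2_marginal", "r2_conditional",
            "direction", "n", "n_groups", "correction", "note"])
    filtered = apply_min_samples_filter(data, config.group,
                                        config.min_samples_per_type)
    records = [test_feature(filtered, f, config) for f in config.features]
    out = pd.DataFrame(records)

    tested = out["p"].notna()
    correction = _choose_correction(int(tested.sum()), config.correction)
    out["p_adjusted"] = np.nan
    if tested.any():
        out.loc[tested, "p_adjusted"] = adjust_pvalues(
            out.loc[tested, "p"].to_numpy(), correction)
    out["correction"] = correction
    out = out.sort_values("p_adjusted", kind="stable",
                          na_position="last").reset_index(drop=True)
    cols = ["feature", "p", "p_adjusted", "r2_marginal", "r2_conditional",
            "direction", "n", "n_groups", "correction", "note"]
    return out[cols]


def run_independence_test(data: pd.DataFrame, feature: str,
                          adjust_for_extra: str,
                          config: ScanConfig) -> float:
    """LRT p for a feature with an extra adjuster in both nested models."""
    if feature == adjust_for_extra:
        raise ValidationError(
            "feature and extra adjuster must be distinct columns")
    filtered = apply_min_samples_filter(data, config.group,
                                        config.min_samples_per_type)
    spec = ModelSpec(response=config.response,
                     terms=(feature, *config.adjusters, adjust_for_extra),
                     group=config.group)
    rows = filtered.dropna(subset=list(dict.fromkeys(spec.columns)))
    full = fit_lmm(rows, spec, method="ML")
    null = fit_lmm(rows, spec.drop_terms(feature), method="ML")
    return lrt_compare(full, null)


def run_interaction_test(data: pd.DataFrame, factor_a: str, factor_b: str,
                         response: str, config: ScanConfig
                         ) -> tuple[float, LmmFit, LmmFit]:
    """Interaction-vs-additive LRT (df = 1) for two binary factors.

    Both models carry the adjusters and the random intercept; the response
    is a 0/1 indicator fitted with the Gaussian machinery (linear
    probability model).
    """
    filtered = apply_min_samples_filter(data, config.group,
                                        config.min_samples_per_type)
    inter_spec = ModelSpec(response=response,
                           terms=(factor_a, factor_b, *config.adjusters),
                           group=config.group,
                           interactions=((factor_a, factor_b),))
    rows = filtered.dropna(subset=list(dict.fromkeys(inter_spec.columns)))
    for name in (factor_a, factor_b):
        if rows[name].nunique() < 2:
            raise DegenerateDataError(
                f"factor {name!r} has a single level after filtering")
    if rows[response].nunique() < 2:
        raise DegenerateDataError(f"response {response!r} is constant")
    full = fit_lmm(rows, inter_spec, method="ML")
    additive = fit_lmm(rows, inter_spec.drop_interactions(), method="ML")
    return lrt_compare(full, additive), full, additive


def stratified_abundance_summary(data: pd.DataFrame, abundance: str,
                                 driver: str, hypoxia_class: str,
                                 config: ScanConfig):
    """Median/quartile abundance by (driver status x hypoxia class).

    Also reports a joint LRT p dropping both factors (df = 2) from the
    adjusted mixed model of abundance, unless a stratum is empty.
    """
    rows = data.dropna(subset=[abundance, driver, hypoxia_class])
    strata = []
    empty = False
    for d in sorted(rows[driver].unique()):
        for hcls in sorted(rows[hypoxia_class].unique()):
            grp = rows[(rows[driver] == d) & (rows[hypoxia_class] == hcls)]
            if grp.empty:
                empty = True
                strata.append({driver: d, hypoxia_class: hcls, "n": 0,
                               "median": np.nan, "q1": np.nan, "q3": np.nan})
                continue
            q1, med, q3 = np.percentile(grp[abundance], [25, 50, 75])
            strata.append({driver: d, hypoxia_class: hcls, "n": len(grp),
                           "median": float(med), "q1": float(q1),
                           "q3": float(q3)})
    summary = pd.DataFrame(strata)
    if empty or rows[driver].nunique() < 2 or rows[hypoxia_class].nunique() < 2:
        log.info("empty stratum; no p-value computed")
        return summary, None
    spec = ModelSpec(response=abundance,
                     terms=(driver, hypoxia_class, *config.adjusters),
                     group=config.group)
    model_rows = rows.dropna(subset=list(dict.fromkeys(spec.columns)))
    full = fit_lmm(model_rows, spec, method="ML")
    null = fit_lmm(model_rows, spec.drop_terms(driver, hypoxia_class),
                   method="ML")
    return summary, lrt_compare(full, null)
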