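"""Synthetic multi-cancer cohort generator with known ground truth.

Every sample carries a latent hypoxia value h ~ N(0, latent_hypoxia_sd).
Signature-gene expression shifts with h so the downstream scorer can
recover it; continuous features, driver mutation probabilities, exposure
counts and clonality are generated with planted links to h (and a planted
hypoxia x PTEN interaction on polyclonality), all recorded in a truth
side-table. Randomness is split into fixed per-table substreams of one
global seed, so adding a table never perturbs the ones before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .scoring import SignatureGeneSet

# fixed substream offsets (order is part of the determinism contract)
_STREAMS = {"covariates": 1, "latent": 2, "expression": 3, "features": 4,
            "drivers": 5, "exposures": 6, "subclonality": 7}

DEFAULT_DENSITY_FEATURES = (
    "snvs_per_mb", "indels_per_mb", "sv_count", "total_deletions",
    "total_duplications", "total_inversions", "total_translocations",
    "pga", "pga_gain", "pga_loss", "snv_count", "indel_count",
    "mnv_count", "kataegis_events", "chromothripsis_score",
)

DEFAULT_DRIVER_GENES = ("PTEN", "TP53", "MYC", "VHL", "CDKN2A",
                        "KRAS", "BRCA2", "RB1")

DEFAULT_EXPOSURE_SIGNATURES = ("SBS1", "SBS3", "SBS5", "SBS13", "SBS17b",
                               "ID1", "ID2", "ID8")

_EVENT_CLASSES = ("SNV", "CNA", "SV")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort. All effects are per unit latent h."""

    n_cancer_types: int = 10
    samples_per_type: int | tuple[int, ...] = 40
    signature_names: tuple[str, ...] = ("buffa", "winter", "ragnum")
    n_signature_genes: int = 20
    n_background_genes: int = 50
    random_intercept_sd: float = 1.0      # tau: per-type baseline SD
    residual_sd: float = 1.0
    latent_hypoxia_sd: float = 1.0
    expression_effect: float = 1.0        # log2-abundance shift per unit h
    expression_noise_sd: float = 0.5
    feature_names: tuple[str, ...] = DEFAULT_DENSITY_FEATURES
    feature_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"total_deletions": 0.6, "snvs_per_mb": 0.4})
    purity_feature_effect: float = 0.5
    age_feature_effect: float = 0.01
    sex_feature_effect: float = 0.1
    driver_genes: tuple[str, ...] = DEFAULT_DRIVER_GENES
    driver_logit_slopes: Mapping[str, float] = field(
        default_factory=lambda: {"PTEN": 1.0, "TP53": 0.7})
    driver_logit_intercept: float = -1.0
    compound_event_prob: float = 0.15
    exposure_signatures: tuple[str, ...] = DEFAULT_EXPOSURE_SIGNATURES
    exposure_dirichlet_alpha: float = 1.0
    mean_mutation_count: float = 100.0
    exposure_hypoxia_slopes: Mapping[str, float] = field(default_factory=dict)
    clonality_base_logit: float = -0.5
    clonality_hypoxia_slope: float = 0.3
    clonality_driver_slope: float = 0.3
    clonality_interaction_effect: float = 1.5
    interaction_driver_gene: str = "PTEN"
    purity_beta_a: float = 8.0
    purity_beta_b: float = 3.0
    age_range: tuple[int, int] = (20, 90)
    sex_bernoulli_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        def bad(name, why):
            raise ConfigError(f"invalid SimConfig.{name}: {why}")
        if self.n_cancer_types < 1:
            bad("n_cancer_types", "must be >= 1")
        spt = self.samples_per_type
        if isinstance(spt, int):
            if spt < 2:
                bad("samples_per_type", "must be >= 2")
        else:
            if len(spt) != self.n_cancer_types:
                bad("samples_per_type",
                    f"vector length {len(spt)} != n_cancer_types")
            if any(s < 2 for s in spt):
                bad("samples_per_type", "every entry must be >= 2")
        if self.n_signature_genes < 1:
            bad("n_signature_genes", "must be >= 1")
        if self.n_background_genes < 0:
            bad("n_background_genes", "must be >= 0")
        for name in ("random_intercept_sd", "residual_sd",
                     "latent_hypoxia_sd", "expression_noise_sd"):
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        if not 0 <= self.sex_bernoulli_p <= 1:
            bad("sex_bernoulli_p", "must lie in [0, 1]")
        if not 0 <= self.compound_event_prob <= 1:
            bad("compound_event_prob", "must lie in [0, 1]")
        if min(self.purity_beta_a, self.purity_beta_b) <= 0:
            bad("purity_beta_a/b", "Beta parameters must be > 0")
        if self.age_range[0] > self.age_range[1]:
            bad("age_range", "lower bound exceeds upper bound")
        unknown = set(self.feature_slopes) - set(self.feature_names)
        if unknown:
            bad("feature_slopes", f"unknown features {sorted(unknown)}")
        unknown = set(self.driver_logit_slopes) - set(self.driver_genes)
        if unknown:
            bad("driver_logit_slopes", f"unknown genes {sorted(unknown)}")
        if self.interaction_driver_gene not in self.driver_genes:
            bad("interaction_driver_gene", "not among driver_genes")

    @property
    def group_sizes(self) -> tuple[int, ...]:
        spt = self.samples_per_type
        if isinstance(spt, int):
            return (spt,) * self.n_cancer_types
        return tuple(spt)

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes)


@dataclass
class CohortBundle:
    expression: pd.DataFrame          # genes x samples
    covariates: pd.DataFrame          # sample, cancer_type, purity, age, sex
    features: pd.DataFrame            # sample + continuous features
    driver_events: pd.DataFrame       # sample, gene, event_class (long)
    exposures: pd.DataFrame           # sample, signature, mutations (long)
    subclonality: pd.DataFrame
    signatures: dict[str, SignatureGeneSet]
    truth: dict


def _stream(config: SimConfig, name: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[name]])


def _sample_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    ids, types = [], []
    for t, size in enumerate(config.group_sizes):
        label = f"type{t + 1:02d}"
        for k in range(size):
            ids.append(f"S{len(ids) + 1:05d}")
            types.append(label)
    return ids, types


def signature_gene_names(config: SimConfig, name: str) -> list[str]:
    return [f"{name.upper()}_G{i + 1:03d}"
            for i in range(config.n_signature_genes)]


def generate_expression(h: np.ndarray, config: SimConfig,
                        rng: np.random.Generator | None = None,
                        sample_ids: Sequence[str] | None = None
                        ) -> pd.DataFrame:
    """Genes x samples abundance matrix with signature genes tracking h."""
    rng = rng if rng is not None else _stream(config, "expression")
    h = np.asarray(h, dtype=float)
    if not np.isfinite(h).all():
        raise ConfigError("latent hypoxia vector must be finite")
    n = h.size
    if sample_ids is None:
        sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    rows, names = [], []
    for sig in config.signature_names:
        for gene in signature_gene_names(config, sig):
            baseline = rng.uniform(2.0, 8.0)
            log_ab = baseline + config.expression_effect * h \
                + rng.normal(0.0, config.expression_noise_sd, n)
            rows.append(np.exp2(log_ab))
            names.append(gene)
    for i in range(config.n_background_genes):
        baseline = rng.uniform(2.0, 8.0)
        log_ab = baseline + rng.normal(0.0, config.expression_noise_sd, n)
        rows.append(np.exp2(log_ab))
        names.append(f"BG_G{i + 1:04d}")
    return pd.DataFrame(np.vstack(rows), index=pd.Index(names, name="gene"),
                        columns=list(sample_ids))


def generate_covariates(config: SimConfig) -> pd.DataFrame:
    rng = _stream(config, "covariates")
    ids, types = _sample_ids(config)
    purity = rng.beta(config.purity_beta_a, config.purity_beta_b,
                      len(ids)).clip(1e-6, 1.0)
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, len(ids))
    sex = rng.binomial(1, config.sex_bernoulli_p, len(ids))
    return pd.DataFrame({"sample": ids, "cancer_type": types,
                         "purity": purity, "age": age, "sex": sex})


def generate_outcomes(h: np.ndarray, covariates: pd.DataFrame,
                      config: SimConfig):
    """Feature, driver-event, exposure and subclonality tables given h."""
    h = np.asarray(h, dtype=float)
    if h.size != len(covariates):
        raise ConfigError("latent vector and covariates are not aligned")
    ids = covariates["sample"].tolist()
    types, type_labels = pd.factorize(covariates["cancer_type"], sort=True)
    purity = covariates["purity"].to_numpy(dtype=float)
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    n = len(ids)

    # continuous features: type intercept + planted slope + covariate effects
    rng = _stream(config, "features")
    feat = {"sample": ids}
    intercepts = {}
    for name in config.feature_names:
        alpha_c = rng.normal(0.0, config.random_intercept_sd,
                             len(type_labels))
        beta = float(config.feature_slopes.get(name, 0.0))
        feat[name] = (alpha_c[types] + beta * h
                      + config.purity_feature_effect * purity
                      + config.age_feature_effect * age
                      + config.sex_feature_effect * sex
                      + rng.normal(0.0, config.residual_sd, n))
        intercepts[name] = alpha_c.tolist()
    features = pd.DataFrame(feat)

    # driver events: Bernoulli-logit on h; mutated samples get 1 event
    # class, or 2 distinct classes (a compound event) with fixed probability
    rng = _stream(config, "drivers")
    records = []
    mutated = {}
    for gene in config.driver_genes:
        slope = float(config.driver_logit_slopes.get(gene, 0.0))
        logit = config.driver_logit_intercept + slope * h
        is_mut = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
        mutated[gene] = is_mut
        for i in np.flatnonzero(is_mut):
            k = 2 if rng.random() < config.compound_event_prob else 1
            classes = rng.choice(_EVENT_CLASSES, size=k, replace=False)
            for cls in classes:
                records.append((ids[i], gene, cls))
    driver_events = pd.DataFrame(records,
                                 columns=["sample", "gene", "event_class"])

    # exposures: total ~ 1 + Poisson, split multinomially with Dirichlet
    # weights tilted by h (conservation: counts sum to the total exactly)
    rng = _stream(config, "exposures")
    sigs = config.exposure_signatures
    alpha = np.full(len(sigs), float(config.exposure_dirichlet_alpha))
    exp_records = []
    totals = np.zeros(n, dtype=int)
    for i in range(n):
        total = 1 + rng.poisson(config.mean_mutation_count)
        w = rng.dirichlet(alpha)
        tilt = np.array([config.exposure_hypoxia_slopes.get(s, 0.0)
                         for s in sigs])
        w = w * np.exp(tilt * h[i])
        w = w / w.sum()
        counts = rng.multinomial(total, w)
        totals[i] = total
        for s, c in zip(sigs, counts):
            exp_records.append((ids[i], s, int(c)))
    exposures = pd.DataFrame(exp_records,
                             columns=["sample", "signature", "mutations"])

    # subclonality: polyclonality logit carries the planted interaction
    rng = _stream(config, "subclonality")
    driver = mutated[config.interaction_driver_gene].astype(float)
    hyp = (h > np.median(h)).astype(float)
    logit = (config.clonality_base_logit
             + config.clonality_hypoxia_slope * h
             + config.clonality_driver_slope * driver
             + config.clonality_interaction_effect * hyp * driver)
    poly = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    n_clusters = np.where(poly, 2 + rng.poisson(0.7, n), 1)
    n_clonal = 1 + rng.poisson(50.0, n)
    n_subclonal = np.where(poly, 1 + rng.poisson(30.0, n), 0)
    subclonality = pd.DataFrame({
        "sample": ids, "n_clusters": n_clusters,
        "n_clonal": n_clonal, "n_subclonal": n_subclonal,
        "clonality": np.where(n_clusters == 1, "monoclonal", "polyclonal"),
    })

    truth_extra = {
        "feature_intercepts": intercepts,
        "mutated": {g: m.astype(int).tolist() for g, m in mutated.items()},
        "mutation_totals": totals.tolist(),
        "polyclonal": poly.astype(int).tolist(),
    }
    return features, driver_events, exposures, subclonality, truth_extra


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Generate the full cohort bundle; deterministic given config.seed."""
    covariates = generate_covariates(config)
    rng_h = _stream(config, "latent")
    h = rng_h.normal(0.0, config.latent_hypoxia_sd, config.n_samples)
    expression = generate_expression(
        h, config, sample_ids=covariates["sample"].tolist())
    features, driver_events, exposures, subclonality, truth_extra = \
        generate_outcomes(h, covariates, config)

    signatures = {
        name: SignatureGeneSet.from_genes(
            name, signature_gene_names(config, name))
        for name in config.signature_names
    }
    cfg_dict = asdict(config)
    cfg_dict["feature_slopes"] = dict(config.feature_slopes)
    cfg_dict["driver_logit_slopes"] = dict(config.driver_logit_slopes)
    cfg_dict["exposure_hypoxia_slopes"] = dict(config.exposure_hypoxia_slopes)
    truth = {"config": cfg_dict,
             "latent_hypoxia": h.tolist(),
             "samples": covariates["sample"].tolist(),
             **truth_extra}
    return CohortBundle(expression=expression, covariates=covariates,
                        features=features, driver_events=driver_events,
                        exposures=exposures, subclonality=subclonality,
                        signatures=signatures, truth=truth)
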