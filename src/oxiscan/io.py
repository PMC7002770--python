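"""Table readers/writers and cohort directory round-tripping.

Canonical on-disk formats: tab-delimited UTF-8 tables with a header row,
GMT for gene sets, JSON for truth/manifest sidecars, YAML for run
configuration. Readers validate schemas and normalise sample identifiers
(whitespace trimmed, case preserved).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .scoring import SignatureGeneSet, validate_expression
from .simulate import CohortBundle

log = logging.getLogger(__name__)

TABLE_SCHEMAS = {
    "covariates": ["sample", "cancer_type", "purity", "age", "sex"],
    "features": ["sample"],
    "driver_events": ["sample", "gene", "event_class"],
    "exposures": ["sample", "signature", "mutations"],
    "subclonality": ["sample", "n_clusters", "n_clonal", "n_subclonal"],
    "scores": ["sample", "signature", "score", "n_genes_used"],
}

COHORT_FILES = {
    "expression": "expression.tsv",
    "covariates": "covariates.tsv",
    "features": "features.tsv",
    "driver_events": "driver_events.tsv",
    "exposures": "exposures.tsv",
    "subclonality": "subclonality.tsv",
    "signatures": "signatures.gmt",
    "truth": "truth.json",
}


def _normalize_samples(df: pd.DataFrame) -> pd.DataFrame:
    if "sample" in df.columns:
        df["sample"] = df["sample"].astype(str).str.strip()
    return df


def read_table(path, kind: str) -> pd.DataFrame:
    """Read and schema-check one of the canonical per-sample tables."""
    if kind not in TABLE_SCHEMAS:
        raise ValidationError(f"unknown table kind {kind!r}")
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE_SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    df = _normalize_samples(df)
    if kind in ("covariates", "features", "subclonality"):
        dup = df.loc[df["sample"].duplicated(), "sample"].unique().tolist()
        if dup:
            raise SchemaError(f"{path}: duplicated sample id(s) {dup[:5]}")
    log.info("%s: read %d rows x %d columns from %s",
             kind, len(df), df.shape[1], path)
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_expression(path) -> pd.DataFrame:
    """Genes-as-rows expression TSV; first column is the gene identifier."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    df.columns = [str(c).strip() for c in df.columns]
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise SchemaError(f"{path}: duplicated gene row(s) {dup[:5]}")
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    expr.rename_axis("gene").to_csv(path, sep="\t")
    return path


def read_gmt(path) -> dict[str, SignatureGeneSet]:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise SchemaError(
                f"{path}:{ln}: GMT line needs name, description and >= 1 gene")
        name, genes = parts[0], [g for g in parts[2:] if g]
        sets[name] = SignatureGeneSet.from_genes(name, genes)
    if not sets:
        raise SchemaError(f"{path}: no gene sets found")
    return sets


def write_gmt(signatures: dict[str, SignatureGeneSet], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["\t".join([sig.name, "na", *sig.genes])
             for sig in signatures.values()]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_cohort(bundle: CohortBundle, out_dir) -> dict[str, str]:
    """Write every cohort table (plus truth sidecar); returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    write_expression(bundle.expression, out / COHORT_FILES["expression"])
    written["expression"] = str(out / COHORT_FILES["expression"])
    write_table(bundle.covariates, out / COHORT_FILES["covariates"])
    written["covariates"] = str(out / COHORT_FILES["covariates"])
    for kind in ("features", "driver_events", "exposures", "subclonality"):
        table = getattr(bundle, kind)
        if table is not None:
            write_table(table, out / COHORT_FILES[kind])
            written[kind] = str(out / COHORT_FILES[kind])
    write_gmt(bundle.signatures, out / COHORT_FILES["signatures"])
    written["signatures"] = str(out / COHORT_FILES["signatures"])
    (out / COHORT_FILES["truth"]).write_text(
        json.dumps(bundle.truth, indent=1, sort_keys=True))
    written["truth"] = str(out / COHORT_FILES["truth"])
    return written


def read_cohort(in_dir) -> CohortBundle:
    """Load a cohort directory written by :func:`write_cohort`."""
    d = Path(in_dir)
    truth_path = d / COHORT_FILES["truth"]
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}

    def optional(kind: str) -> pd.DataFrame | None:
        path = d / COHORT_FILES[kind]
        if not path.exists():
            log.info("cohort table %s absent (%s); downstream consumers "
                     "will skip it", kind, path.name)
            return None
        return read_table(path, kind)

    bundle = CohortBundle(
        expression=read_expression(d / COHORT_FILES["expression"]),
        covariates=read_table(d / COHORT_FILES["covariates"], "covariates"),
        features=optional("features"),
        driver_events=optional("driver_events"),
        exposures=optional("exposures"),
        subclonality=optional("subclonality"),
        signatures=read_gmt(d / COHORT_FILES["signatures"]),
        truth=truth,
    )
    sample_sets = {
        "covariates": set(bundle.covariates["sample"]),
        "expression": set(bundle.expression.columns),
    }
    if sample_sets["covariates"] != sample_sets["expression"]:
        raise SchemaError("expression and covariate sample sets differ")
    return bundle


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return cfg


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(out_dir, files: list[str], config: dict,
                   seed: int) -> Path:
    from . import __version__
    out = Path(out_dir)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "files": sorted(str(Path(f).relative_to(out)) for f in files),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
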