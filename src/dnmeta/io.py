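"""Readers and writers for the bundle formats.

A *bundle* is a directory of plain-text files: one expression TSV per
dataset (``<dataset_id>.expr.tsv``, genes as rows), a shared
``metadata.tsv`` (sample, dataset, batch, tissue, condition), an optional
``probe_map.tsv`` and an optional ``truth.json`` carrying the simulation
ground truth. Configuration is YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .datasets import DataError, ExpressionDataset, GroundTruth
from .simulate import DatasetSpec, SimulationConfig

__version__ = "0.1.0"


def write_bundle(datasets, out_dir, truth: GroundTruth | None = None) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metas = []
    for d in datasets:
        d.expr.to_csv(out / f"{d.dataset_id}.expr.tsv", sep="\t",
                      index_label="gene", float_format="%.6f")
        metas.append(d.meta)
    meta = pd.concat(metas)
    meta.to_csv(out / "metadata.tsv", sep="\t", index_label="sample")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth_to_dict(truth), indent=1))
    return out


def read_bundle(bundle_dir) -> list[ExpressionDataset]:
    """Load every dataset of a bundle directory, validating that metadata
    sample ids exactly match the expression columns."""
    bundle = Path(bundle_dir)
    meta_path = bundle / "metadata.tsv"
    if not meta_path.exists():
        raise DataError(f"read_bundle: missing {meta_path}")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    datasets = []
    for path in sorted(bundle.glob("*.expr.tsv")):
        dataset_id = path.name[: -len(".expr.tsv")]
        expr = pd.read_csv(path, sep="\t", index_col="gene")
        non_numeric = expr.columns[
            [not pd.api.types.is_numeric_dtype(expr[c]) for c in expr.columns]
        ]
        if len(non_numeric):
            raise DataError(
                f"{path}: non-numeric values in columns {list(non_numeric)}"
            )
        sub = meta[meta["dataset"] == dataset_id]
        missing = [c for c in expr.columns if c not in sub.index]
        extra = [s for s in sub.index if s not in expr.columns]
        if missing or extra:
            raise DataError(
                f"{path}: sample-id mismatch with metadata "
                f"(expression-only: {missing}; metadata-only: {extra})"
            )
        sub = sub.loc[expr.columns]
        sub.index.name = "sample"
        datasets.append(ExpressionDataset(dataset_id, expr, sub))
    if not datasets:
        raise DataError(f"read_bundle: no *.expr.tsv files in {bundle}")
    return datasets


def read_probe_map(path) -> pd.Series:
    pm = pd.read_csv(path, sep="\t")
    if pm.shape[1] < 2:
        raise DataError(f"{path}: probe map needs two columns (probe, gene)")
    return pm.set_index(pm.columns[0])[pm.columns[1]]


def truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "de_genes_by_compartment": {
            c: dict(sorted(v.items()))
            for c, v in truth.de_genes_by_compartment.items()
        },
        "module_genes": sorted(truth.module_genes),
        "outlier_samples": sorted(truth.outlier_samples),
        "duplicate_pairs": [list(p) for p in truth.duplicate_pairs],
        "batch_params": {k: list(v) for k, v in truth.batch_params.items()},
        "qpcr_effects": dict(truth.qpcr_effects),
    }


def truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        de_genes_by_compartment={
            c: dict(v) for c, v in d.get("de_genes_by_compartment", {}).items()
        },
        module_genes=set(d.get("module_genes", [])),
        outlier_samples=set(d.get("outlier_samples", [])),
        duplicate_pairs=[tuple(p) for p in d.get("duplicate_pairs", [])],
        batch_params={k: tuple(v) for k, v in d.get("batch_params", {}).items()},
        qpcr_effects=dict(d.get("qpcr_effects", {})),
    )


def read_truth(path) -> GroundTruth:
    return truth_from_dict(json.loads(Path(path).read_text()))


def config_from_yaml(path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    specs = raw.pop("dataset_specs", None)
    cfg = SimulationConfig(**raw)
    if specs is not None:
        cfg.dataset_specs = [DatasetSpec(**s) for s in specs]
    return cfg


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping, for output headers."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, config=None, **csv_kw) -> None:
    """TSV with a provenance header comment (version, config hash, seed)."""
    path = Path(path)
    header = (
        f"# dnmeta v{__version__}"
        f" config={config_hash(config or {})}"
        f" seed={seed if seed is not None else 'NA'}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", **csv_kw)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)
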