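"""Core in-memory containers shared by every pipeline stage.

Expression data travel as a pandas DataFrame of log2 intensities with genes
as rows and samples as columns, paired with a per-sample metadata frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TISSUES = ("glomerulus", "tubule", "cortex")
CONDITIONS = ("DN", "control")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


class UsageError(ValueError):
    """A call that violates an operation's contract."""


@dataclass
class ExpressionDataset:
    """One dataset/platform unit: log2 expression plus sample metadata.

    Parameters
    ----------
    dataset_id
        Identifier of the dataset/platform unit (doubles as batch label
        when datasets are merged).
    expr
        Genes x samples log2 expression matrix.
    meta
        Per-sample metadata indexed by sample id with at least
        ``dataset``, ``batch``, ``tissue`` and ``condition`` columns.
    """

    dataset_id: str
    expr: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.meta.index):
            raise DataError(
                f"dataset {self.dataset_id}: metadata sample ids do not match "
                "expression columns"
            )
        bad_tissue = set(self.meta["tissue"]) - set(TISSUES)
        if bad_tissue:
            raise DataError(
                f"dataset {self.dataset_id}: unknown tissue values {sorted(bad_tissue)}"
            )
        bad_cond = set(self.meta["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DataError(
                f"dataset {self.dataset_id}: unknown condition values {sorted(bad_cond)}"
            )

    @property
    def tissue(self) -> str:
        tissues = self.meta["tissue"].unique()
        if len(tissues) != 1:
            raise DataError(f"dataset {self.dataset_id}: mixed tissues {tissues}")
        return str(tissues[0])

    @property
    def genes(self) -> pd.Index:
        return self.expr.index

    @property
    def samples(self) -> pd.Index:
        return self.expr.columns

    def n_per_condition(self) -> dict[str, int]:
        return self.meta["condition"].value_counts().to_dict()

    def drop_samples(self, sample_ids) -> "ExpressionDataset":
        keep = [s for s in self.samples if s not in set(sample_ids)]
        return ExpressionDataset(
            self.dataset_id, self.expr[keep], self.meta.loc[keep]
        )


@dataclass
class GroundTruth:
    """Planted structure of a simulation, for parameter-recovery tests."""

    de_genes_by_compartment: dict[str, dict[str, float]] = field(default_factory=dict)
    module_genes: set = field(default_factory=set)
    outlier_samples: set = field(default_factory=set)
    duplicate_pairs: list = field(default_factory=list)
    batch_params: dict = field(default_factory=dict)
    qpcr_effects: dict = field(default_factory=dict)

    def all_de_genes(self) -> set:
        out: set = set()
        for effects in self.de_genes_by_compartment.values():
            out |= set(effects)
        return out
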