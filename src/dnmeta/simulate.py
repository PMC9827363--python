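"""Synthetic multi-dataset expression bundles and qPCR Ct tables.

The generator emulates the study design the pipeline targets: several
dataset/platform units per renal compartment (glomerulus, tubulointerstitium,
kidney cortex), each with its own additive and multiplicative batch effect,
compartment-specific differential expression between diabetic-nephropathy
(DN) and control samples, one planted co-expressed gene module driven by a
shared latent factor, and a sprinkling of corrupted (outlier) and
near-duplicate arrays for the QC stage to find.

Generative model for gene g, sample i of dataset (batch) b in compartment c:

    x_gi = alpha_g + beta_g * DN_i * [g in DE(c)]
           + lambda_g * f_i * [g in module] + gamma_b + delta_b * eps_gi

with eps_gi ~ N(0, noise_sd^2), latent factor f_i ~ N(0, module_latent_sd^2)
and loadings lambda_g ~ Uniform(0.6, 1.0), all of one sign so the module is a
recoverable dense cluster for the mutual-information network stage.
Glomerulus-planted DE genes are downregulated in DN and tubule-planted genes
upregulated, mirroring the compartment-specific directionality of the disease
signature the pipeline is built to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ConfigError, ExpressionDataset, GroundTruth, TISSUES


@dataclass
class DatasetSpec:
    """Design of one dataset/platform unit."""

    dataset_id: str
    tissue: str
    n_dn: int
    n_control: int
    batch_shift: float = 0.0  # gamma_b, log2 units
    batch_scale: float = 1.0  # delta_b, noise-sd multiplier


def default_study_specs() -> list[DatasetSpec]:
    """Nine dataset/platform units shaped like a typical curated DN cohort:

    five glomerulus units, three tubulointerstitium units and one small
    kidney-cortex unit, with unbalanced group sizes and platform-specific
    batch offsets/scales of the magnitude seen between array generations.
    """
    return [
        DatasetSpec("glom1", "glomerulus", 3, 3, 1.2, 1.10),
        DatasetSpec("glom2", "glomerulus", 8, 13, -0.8, 0.90),
        DatasetSpec("glom3", "glomerulus", 20, 10, 0.5, 1.20),
        DatasetSpec("glom4", "glomerulus", 7, 8, -1.5, 1.00),
        DatasetSpec("glom5", "glomerulus", 7, 18, 0.9, 0.85),
        DatasetSpec("tub1", "tubule", 10, 11, -0.4, 1.15),
        DatasetSpec("tub2", "tubule", 6, 17, 1.0, 0.95),
        DatasetSpec("tub3", "tubule", 10, 3, -0.9, 1.05),
        DatasetSpec("cortex1", "cortex", 4, 3, 0.3, 1.00),
    ]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic multi-dataset bundle.

    Defaults are the study conditions the pipeline assumes: gene-level log2
    microarray intensities with within-group residual SD around 0.5, DE
    effects of +/-2 log2 units (comfortably past the pipeline's 1.5 cutoff),
    and a 20-gene latent-factor module.
    """

    n_genes: int = 2000
    dataset_specs: list[DatasetSpec] = field(default_factory=default_study_specs)
    n_de_genes_per_compartment: int = 100
    de_log2fc: float = 2.0
    module_size: int = 20
    module_latent_sd: float = 1.0
    noise_sd: float = 0.5
    n_outlier_arrays: int = 2
    n_duplicate_pairs: int = 1
    outlier_mode: str = "shuffle"  # or "shift" (+3 log2, exercises Ka)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < self.module_size + 2 * self.n_de_genes_per_compartment:
            raise ConfigError(
                "n_genes must be >= module_size + 2*n_de_genes_per_compartment"
            )
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        for f in ("n_genes", "n_de_genes_per_compartment", "module_size",
                  "n_outlier_arrays", "n_duplicate_pairs"):
            if getattr(self, f) < 0:
                raise ConfigError(f"{f} must be >= 0")
        if self.outlier_mode not in ("shuffle", "shift"):
            raise ConfigError("outlier_mode must be 'shuffle' or 'shift'")
        if not self.dataset_specs:
            raise ConfigError("dataset_specs must be non-empty")
        ids = [s.dataset_id for s in self.dataset_specs]
        if len(set(ids)) != len(ids):
            raise ConfigError("dataset_specs: dataset_id values must be unique")
        for s in self.dataset_specs:
            if s.tissue not in TISSUES:
                raise ConfigError(f"dataset_specs: unknown tissue {s.tissue!r}")
            if not s.batch_scale > 0:
                raise ConfigError("dataset_specs: batch_scale must be > 0")
            if s.n_dn < 0 or s.n_control < 0:
                raise ConfigError("dataset_specs: sample counts must be >= 0")


def generate_multiset(
    config: SimulationConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Simulate one expression bundle plus its ground truth.

    Deterministic for a given config (the seed is part of the config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    k = config.n_de_genes_per_compartment
    glom_de = genes[:k]
    tub_de = genes[k: 2 * k]
    module = genes[2 * k: 2 * k + config.module_size]

    mag = abs(config.de_log2fc)
    truth = GroundTruth(
        de_genes_by_compartment={
            "glomerulus": {g: -mag for g in glom_de},
            "tubule": {g: +mag for g in tub_de},
        },
        module_genes=set(module),
        batch_params={
            s.dataset_id: (s.batch_shift, s.batch_scale) for s in config.dataset_specs
        },
    )

    alpha = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)
    loadings = rng.uniform(0.6, 1.0, config.module_size)
    module_idx = np.arange(2 * k, 2 * k + config.module_size)
    beta = np.zeros(config.n_genes)
    beta[:k] = -mag
    beta[k: 2 * k] = +mag

    datasets: list[ExpressionDataset] = []
    for spec in config.dataset_specs:
        n = spec.n_dn + spec.n_control
        dn_flag = np.r_[np.ones(spec.n_dn), np.zeros(spec.n_control)]
        sample_ids = [
            f"{spec.dataset_id}_{'DN' if d else 'C'}{j:02d}"
            for j, d in enumerate(dn_flag)
        ]
        x = alpha[:, None] + spec.batch_shift + spec.batch_scale * rng.normal(
            0.0, config.noise_sd, (config.n_genes, n)
        )
        if spec.tissue == "glomerulus":
            x[:k] += beta[:k, None] * dn_flag[None, :]
        elif spec.tissue == "tubule":
            x[k: 2 * k] += beta[k: 2 * k, None] * dn_flag[None, :]
        f = rng.normal(0.0, config.module_latent_sd, n)
        x[module_idx] += loadings[:, None] * f[None, :]

        meta = pd.DataFrame(
            {
                "dataset": spec.dataset_id,
                "batch": spec.dataset_id,
                "tissue": spec.tissue,
                "condition": np.where(dn_flag == 1, "DN", "control"),
            },
            index=pd.Index(sample_ids, name="sample"),
        )
        datasets.append(
            ExpressionDataset(
                spec.dataset_id,
                pd.DataFrame(x, index=genes, columns=sample_ids),
                meta,
            )
        )

    _plant_artifacts(datasets, truth, config, rng)
    return datasets, truth


def _plant_artifacts(datasets, truth, config, rng) -> None:
    """Corrupt arrays (outliers) and plant near-duplicate pairs in place.

    Outliers and duplicates are drawn from distinct samples so the QC truth
    sets stay disjoint. Duplicate partners are same-dataset, same-condition
    samples; the second member is overwritten by the first plus tiny jitter.
    """
    flat = [
        (d_i, s_i)
        for d_i, d in enumerate(datasets)
        for s_i in range(len(d.samples))
    ]
    need = config.n_outlier_arrays + 2 * config.n_duplicate_pairs
    if need > len(flat):
        raise ConfigError("n_outlier_arrays/n_duplicate_pairs exceed total samples")
    chosen = rng.choice(len(flat), size=need, replace=False)
    out_pos = [flat[i] for i in chosen[: config.n_outlier_arrays]]

    for d_i, s_i in out_pos:
        d = datasets[d_i]
        col = d.samples[s_i]
        if config.outlier_mode == "shuffle":
            d.expr[col] = rng.permutation(d.expr[col].to_numpy())
        else:
            d.expr[col] = d.expr[col] + 3.0
        truth.outlier_samples.add(col)

    used = set(chosen[: config.n_outlier_arrays])
    # pair each remaining reserved slot with a same-dataset/condition partner
    pool = [i for i in chosen[config.n_outlier_arrays:]]
    for i in pool[: config.n_duplicate_pairs]:
        d_i, s_i = flat[i]
        d = datasets[d_i]
        src = d.samples[s_i]
        cond = d.meta.loc[src, "condition"]
        partners = [
            j for j, s in enumerate(d.samples)
            if j != s_i and d.meta.iloc[j]["condition"] == cond
            and flat.index((d_i, j)) not in used
            and d.samples[j] not in truth.outlier_samples
        ]
        if not partners:
            continue
        tgt = d.samples[partners[0]]
        jitter = rng.normal(0.0, 0.01, len(d.genes))
        d.expr[tgt] = d.expr[src].to_numpy() + jitter
        truth.duplicate_pairs.append((src, tgt))
        used.add(flat.index((d_i, partners[0])))


def generate_qpcr(
    n_replicates_per_group: int,
    true_log2_effects: dict[str, float],
    ct_sd: float = 0.3,
    seed: int = 0,
    reference_gene: str = "eefa1",
    base_ct: float = 24.0,
    reference_ct: float = 20.0,
):
    """Simulate a replicate Ct table for a control vs glucose comparison.

    ``Ct = base - log2(relative expression)``: a gene whose expression halves
    under glucose shows a Ct one cycle higher. The reference gene is
    unaffected by treatment. Returns (CtTable, GroundTruth).
    """
    from .qpcr import CtTable

    if n_replicates_per_group < 2:
        raise ConfigError("n_replicates_per_group must be >= 2")
    if not ct_sd > 0:
        raise ConfigError("ct_sd must be > 0")
    if not true_log2_effects:
        raise ConfigError("true_log2_effects must name at least one target gene")
    if reference_gene in true_log2_effects:
        raise ConfigError(
            f"reference gene {reference_gene!r} cannot carry a treatment effect"
        )

    rng = np.random.default_rng(seed)
    rows = []
    groups = [("control", 0.0), ("glucose", 1.0)]
    for group, treated in groups:
        for rep in range(n_replicates_per_group):
            sample = f"{group}_{rep:02d}"
            for gene, eff in true_log2_effects.items():
                ct = base_ct - treated * eff + rng.normal(0.0, ct_sd)
                rows.append((sample, group, gene, ct))
            rows.append(
                (sample, group, reference_gene,
                 reference_ct + rng.normal(0.0, ct_sd))
            )
    table = pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
    truth = GroundTruth(qpcr_effects=dict(true_log2_effects))
    return CtTable(table, reference_gene=reference_gene), truth
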