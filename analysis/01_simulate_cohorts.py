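"""Generate the synthetic multi-dataset study bundle.

Emulates the curated design: five glomerulus, three tubulointerstitium and
one kidney-cortex dataset/platform units with platform-specific batch
effects, 100 downregulated glomerular and 100 upregulated tubular DE genes
at |log2FC| = 2, a 20-gene latent-factor co-expression module, two corrupted
arrays and one near-duplicate sample pair. Writes the bundle (expression +
metadata TSVs, truth JSON) under results/bundle/.
"""

from pathlib import Path

from dnmeta import SimulationConfig, generate_multiset
from dnmeta import io

SEED = 20230917
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    datasets, truth = generate_multiset(cfg)
    out = OUT / "bundle"
    io.write_bundle(datasets, out, truth)
    n_samples = sum(len(d.samples) for d in datasets)
    print(f"wrote {len(datasets)} datasets ({cfg.n_genes} genes, "
          f"{n_samples} samples) to {out}")
    print(f"planted: {len(truth.all_de_genes())} DE genes, "
          f"{len(truth.module_genes)}-gene module, "
          f"{len(truth.outlier_samples)} outlier arrays, "
          f"{len(truth.duplicate_pairs)} duplicate pair(s)")


if __name__ == "__main__":
    main()
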