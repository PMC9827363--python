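"""Screen every dataset of the bundle for outlier and duplicate arrays.

Reports per-array rank-concordance scores and Ka distribution distances,
ESD/Dixon decisions on the scores, and near-duplicate pairs; writes the QC
report JSON and a per-array score table under results/qc/.
"""

import json
from pathlib import Path

import pandas as pd

from dnmeta import assess_dataset
from dnmeta import io

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    datasets = io.read_bundle(ROOT / "bundle")
    truth = io.read_truth(ROOT / "bundle" / "truth.json")
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)

    reports = [assess_dataset(d) for d in datasets]
    (out / "qc_report.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=1))

    scores = pd.concat(
        [pd.DataFrame({"dataset": r.dataset_id,
                       "concordance": r.concordance, "ka": r.ka})
         for r in reports])
    scores.index.name = "sample"
    io.write_table(scores, out / "array_scores.tsv", float_format="%.4f")

    flagged = set().union(*[r.flagged_outliers for r in reports])
    pairs = {frozenset((a, b)) for r in reports
             for a, b, _ in r.doppelganger_pairs}
    truth_pairs = {frozenset(p) for p in truth.duplicate_pairs}
    print(f"flagged outlier arrays: {sorted(flagged)}")
    print(f"  (planted: {sorted(truth.outlier_samples)})")
    print(f"duplicate pairs found: {[sorted(p) for p in pairs]}")
    print(f"  (planted: {[sorted(p) for p in truth_pairs]})")


if __name__ == "__main__":
    main()
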