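"""Operating-point evaluation and model comparison.

Reads the cross-validated probabilities of the core-only and eight-VOI
models (from 05), picks the Youden-optimal cutoff, reports sensitivity /
specificity / accuracy / PPV / NPV with a 1,000-resample stratified
bootstrap 95% CI of the AUC, and compares the two correlated ROC curves
with the DeLong test; writes results/evaluation.json.
"""

import json
from pathlib import Path

import pandas as pd

from peristas.evaluation import bootstrap_ci, delong_test, youden_threshold

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    df = pd.read_csv(OUT / "cv_probabilities.csv")
    labels = df["label"].to_numpy()
    report = {}
    for model in ("core", "eight-voi"):
        scores = df[model].to_numpy()
        cut, rep = youden_threshold(scores, labels)
        rep.ci_low, rep.ci_high = bootstrap_ci(scores, labels, n_boot=1000, seed=seed)
        rep.n_boot = 1000
        report[model] = {k: round(v, 4) for k, v in rep.to_dict().items()}
        print(f"{model}: AUC {rep.auc:.3f} (95% CI {rep.ci_low:.3f}-{rep.ci_high:.3f}), "
              f"sens {rep.sensitivity:.2f} spec {rep.specificity:.2f} at cutoff {cut:.3f}")
    z, p = delong_test(df["eight-voi"].to_numpy(), df["core"].to_numpy(), labels)
    report["delong_eight_voi_vs_core"] = {"z": round(z, 3), "p": float(f"{p:.3g}")}
    print(f"DeLong eight-VOI vs core: z = {z:.2f}, p = {p:.3g}")
    (OUT / "evaluation.json").write_text(json.dumps(report, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
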