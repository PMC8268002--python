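"""Diagnostic performance of the traditional radiologic signs.

From the published 2x2 counts of five binary CT signs against STAS status
(56 STAS+ / 160 STAS-), computes sensitivity, specificity, accuracy, PPV,
NPV and the single-operating-point AUC = (sens + spec)/2 per sign; writes
results/traditional_signs.csv.  The satellite sign is highly specific
(0.96) but insensitive (0.25); the unclear tumor-lung interface is the
best single sign (AUC 0.677).
"""

from pathlib import Path

import pandas as pd

from peristas.evaluation import STUDY_SIGN_COUNTS, metrics_from_counts

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for sign, counts in STUDY_SIGN_COUNTS.items():
        rep = metrics_from_counts(counts)
        rows.append({
            "sign": sign,
            "auc": round(rep.auc, 3),
            "sensitivity": round(rep.sensitivity, 2),
            "specificity": round(rep.specificity, 2),
            "accuracy": round(rep.accuracy, 2),
            "ppv": round(rep.ppv, 2),
            "npv": round(rep.npv, 2),
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "traditional_signs.csv", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
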