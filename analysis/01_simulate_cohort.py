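"""Generate a demonstration phantom cohort.

Writes a small labeled cohort (NIfTI image + lung/tumor masks per case and
a manifest CSV) under results/cohort.  The full study imbalance is 56:160;
the demo uses a 14:40 subsample at the same ratio so the artifacts stay
small — the cohort-scale experiments in 05 regenerate cases in memory at
full size instead of reading these files.
"""

import sys
from pathlib import Path

from peristas.shells import erode_mm
from peristas.synthetic import PhantomSpec, generate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 1) -> None:
    spec = PhantomSpec()  # 80 mm grid, 1 mm iso, 19.7 +/- 6.2 mm nodules
    cases = generate_cohort(n_pos=14, n_neg=40, spec=spec, seed=seed)
    manifest = write_cohort(cases, OUT / "cohort")
    n_pleural = sum(
        bool((c.core.grid & ~erode_mm(c.lung, 1.0).grid).any()) for c in cases
    )
    print(f"wrote {len(cases)} cases ({sum(c.label for c in cases)} STAS+) -> {manifest}")
    print(f"{n_pleural} case(s) touch the pleural boundary within 1 mm")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
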