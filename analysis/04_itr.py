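#!/usr/bin/env python
"""Information transfer rate at the study's operating points and ours.

Tabulates Wolpaw ITR (N=2 commands, M=9.5238 decisions/min) for the
reference accuracies and for the synthetic session's own CV accuracy;
writes results/itr.tsv.
"""

import pandas as pd
from _shared import RESULTS, make_session

from tactile_p300 import classify, metrics
from tactile_p300.classify import PipelineSpec

REFERENCE_POINTS = [
    ("reference_best", 1.0),
    ("reference_worst", 0.835),
    ("reference_mean_vibration", 0.9488),
    ("reference_mean_electrical", 0.9521),
]


def main() -> None:
    _, _, _, epochs = make_session()
    lr = epochs.select(["left_attended", "right_attended"])
    rep = classify.crossval(lr, PipelineSpec(band=(4.0, 20.0), m=3), k=10, seed=0)

    rows = [
        {"case": name, "P": p, "B_bits": metrics.bits_per_trial(p),
         "itr_bits_per_min": metrics.itr(p)}
        for name, p in REFERENCE_POINTS
    ]
    p_synth = max(rep.mean, 0.5)
    rows.append(
        {"case": "synthetic_session", "P": p_synth,
         "B_bits": metrics.bits_per_trial(p_synth),
         "itr_bits_per_min": metrics.itr(p_synth)}
    )
    table = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "itr.tsv", sep="\t", index=False)

    for _, r in table.iterrows():
        print(f"{r['case']:<26} P={r['P']:.4f}  B={r['B_bits']:.4f} bits  "
              f"ITR={r['itr_bits_per_min']:.2f} bits/min")
    print(f"wrote {RESULTS / 'itr.tsv'}")


if __name__ == "__main__":
    main()
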