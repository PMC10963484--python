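"""Operating characteristics of the consciousness-detection rule.

Runs the full pipeline — simulate, preprocess, classify, decide — on a
small cohort of conscious and unconscious synthetic subjects and tallies
the verdicts.  (The full 20+20 cohort is exercised by the test suite;
this driver uses 6+6 to stay fast for interactive runs.)
"""

import logging
import warnings
from collections import Counter
from pathlib import Path

import pandas as pd

import conscidet as cd

OUT = Path(__file__).resolve().parents[1] / "results"
N_PER_GROUP = 6
SEED = 1


def main() -> None:
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(message)s")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label, factory, seed0 in (
                ("conscious", cd.conscious_profile, SEED),
                ("unconscious", cd.unconscious_profile, SEED + 500)):
            verdicts = cd.cohort_verdicts(N_PER_GROUP, factory, seed=seed0)
            counts = Counter(verdicts)
            for verdict, n in sorted(counts.items()):
                rows.append((label, verdict, n))
    table = pd.DataFrame(rows, columns=["profile", "verdict", "n_subjects"])
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "decision_cohort.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    det = table.query("profile == 'conscious' and "
                      "verdict == 'consciousness_detected'")["n_subjects"].sum()
    fp = table.query("profile == 'unconscious' and "
                     "verdict == 'consciousness_detected'")["n_subjects"].sum()
    print(f"\n{det}/{N_PER_GROUP} conscious subjects detected, "
          f"{fp}/{N_PER_GROUP} unconscious false positives.")


if __name__ == "__main__":
    main()
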