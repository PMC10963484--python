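"""Single-trial classification and trial-averaging curves.

For the conscious demonstration subject: linear-SVM accuracy for the
stimulus contrasts within each mode and the active-vs-breathing mode
contrasts per stimulus type, plus accuracy as a function of the number
of test trials averaged (1-5).  Averaging should help wherever a real
evoked difference exists and do nothing for the breathing-mode stimulus
contrasts.
"""

import warnings
from pathlib import Path

import pandas as pd

import conscidet as cd
from conscidet import io
from conscidet.classify import build_features, trial_averaged_curve

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "subjects"
OUT = ROOT / "results"
SEED = 11

CONTRASTS = [
    ("deviant vs standard (active)",
     dict(contrast="stimulus", positive="deviant", negative="standard",
          mode="active")),
    ("deviant vs standard (breathing)",
     dict(contrast="stimulus", positive="deviant", negative="standard",
          mode="breathing")),
    ("correct vs incorrect novel (active)",
     dict(contrast="stimulus", positive="correct_novel",
          negative="incorrect_novel", mode="active")),
    ("active vs breathing (deviant)",
     dict(contrast="mode", positive="active", negative="breathing",
          stimulus_type="deviant")),
    ("active vs breathing (correct novel)",
     dict(contrast="mode", positive="active", negative="breathing",
          stimulus_type="correct_novel")),
]


def main() -> None:
    ep = io.load_epochs(SCRATCH / "conscious")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, spec in CONTRASTS:
            fs = build_features(ep, **spec)
            curve = trial_averaged_curve(fs, n_repeats=10, seed=SEED)
            accs = {r.n_avg: r.accuracy for r in curve}
            level1 = next(r for r in curve if r.n_avg == 1)
            rows.append((name, *(accs.get(n, float("nan"))
                                 for n in range(1, 6)),
                         accs.get(5, accs[1]) - accs[1],
                         level1.sensitivity, level1.specificity))
    table = pd.DataFrame(rows, columns=["contrast", "acc_navg1", "acc_navg2",
                                        "acc_navg3", "acc_navg4", "acc_navg5",
                                        "gain", "sensitivity", "specificity"])
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "classification.tsv", sep="\t", index=False,
                 float_format="%.3f")
    print(table.to_string(index=False, float_format="%.3f".__mod__))
    best = table.iloc[table["gain"].idxmax()]
    print(f"\nlargest trial-averaging gain: {best['contrast']} "
          f"(+{best['gain']:.3f} from n_avg 1 to 5).")


if __name__ == "__main__":
    main()
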