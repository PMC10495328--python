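#!/usr/bin/env python
"""Measure tooth angulation/inclination for every setup of the cohort.

All setups of a patient are measured against the patient's root
setup-2 occlusal frame (the shared reference).  Output: one row per
patient x jaw x setup x tooth in results/angles.csv.
"""

from pathlib import Path

from rootsetup.pipeline import angles_from_files

DATA = Path("scratch/cohort")
OUT = Path("results/angles.csv")


def main() -> None:
    angles = angles_from_files(DATA)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    angles.to_csv(OUT, index=False)
    print(f"{len(angles)} angle measurements -> {OUT}")
    spread = angles.groupby("setup")["angulation"].std()
    print("angulation dispersion (deg, SD) per setup:")
    print(spread.round(2).to_string())


if __name__ == "__main__":
    main()
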