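#!/usr/bin/env python
"""Interreader agreement between two parameterized automatic readers.

Re-reads the uniform-flow cohort slabs with two readers whose low-signal
criteria differ slightly (low-pixel factor k = 0.55 vs 0.65) and computes
percent agreement and Cohen's kappa over all druse x device OCTA-loss
labels.  The clinical analogue is two masked human graders; disagreement
concentrates on drusen whose shadowing sits near the reader criterion.
Writes the label table to results/run_uniform/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from drusenshadow import io as dsio
from drusenshadow import classification as cls

RUN = Path("results/run_uniform")


def main() -> None:
    if not (RUN / "rois.npy").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    pairs = {dev: dsio.read_enface_pair(RUN / f"enface_{dev}") for dev in ("SD840", "SS1050")}
    rois = [m.astype(bool) for m in np.load(RUN / "rois.npy")]
    readers = {
        "reader_a": cls.ReaderParams(low_pixel_factor=0.55),
        "reader_b": cls.ReaderParams(low_pixel_factor=0.65),
    }
    labels: dict[str, list[bool]] = {name: [] for name in readers}
    rows = []
    for name, reader in readers.items():
        for dev in ("SD840", "SS1050"):
            for i, roi in enumerate(rois):
                a = cls.assess_roi(pairs[dev], roi, reader)
                labels[name].append(a.low_octa)
                rows.append(dict(reader=name, device=dev, druse=i, low_octa=a.low_octa))
    pct, kappa = cls.agreement(labels["reader_a"], labels["reader_b"])
    pd.DataFrame(rows).to_csv(RUN / "reader_labels.csv", index=False)
    n = len(labels["reader_a"])
    print(f"{n} druse x device labels per reader")
    print(f"percent agreement = {pct:.1f}%, Cohen's kappa = {kappa:.3f}")


if __name__ == "__main__":
    main()
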