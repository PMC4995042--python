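#!/usr/bin/env python
"""Control experiment: a genuine flow void with attenuation disabled.

With tissue attenuation switched off and a true choriocapillaris flow void
placed under the largest druse, neither device loses OCT signal, so both
should grade the void as *unambiguous* OCTA signal loss (real absence of
flow) and neither should produce a false positive.  This is the logic by
which preserved OCT signal licenses reading dark angiography as pathology.
Writes grades to results/run_void/.
"""

from pathlib import Path

from drusenshadow import classification as cls
from drusenshadow import pipeline
from drusenshadow.cli import format_summary

OUT = Path("results/run_void")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    res = pipeline.run_study(pipeline.scenario_config("true_void"), seed=SEED)
    cls.grades_to_frame(res.grades).to_csv(OUT / "grades.csv", index=False)
    cls.summary_to_frame(res.summary).to_csv(OUT / "summary.csv", index=False)
    print(format_summary(res.summary))
    g = res.grades[-1]  # druse carrying the void
    print()
    print(f"void druse: SD class = {g.sd_class}, SS class = {g.ss_class}")
    if g.sd_class == g.ss_class == "unambiguous":
        print("finding: both devices read the true void as unambiguous loss "
              "(OCT signal preserved), with no false positives.")
    else:
        print("finding: control did NOT behave as expected - inspect slabs.")


if __name__ == "__main__":
    main()
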