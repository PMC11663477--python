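#!/usr/bin/env python
"""Longitudinal change in BrainAGE over partial weight recovery.

Reads the scored cohort from results/ (steps 01-02) and fits, per tissue:
the random-intercept mixed model of the timepoint effect in completers (L1),
its baseline-covariate-adjusted variant (L2) and the change-predictor
regression of dBrainAGE on clinical change (L3). The headline quantities are
the grey-matter normalisation (about -1.7 y over ~3 months) and its coupling
to weight gain (about -0.65 y per BMI-SDS unit).
"""

from pathlib import Path

import pandas as pd

from anbrainage import stats
from anbrainage.cli_io import read_phenotypes
from anbrainage.pipeline import effects_frame

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_phenotypes(OUT / "phenotypes.csv")
    results = pd.read_csv(OUT / "brainage_results.csv")
    effects = []
    for tissue in ("GM", "WM"):
        spec = stats.AnalysisSpec(outcome=f"BrainAGE_{tissue}")
        for tag in ("L1", "L2"):
            effects += stats.longitudinal_model(records, results, spec, model=tag)
        effects += stats.change_predictor_model(records, results, spec)
    frame = effects_frame(effects)
    frame.to_csv(OUT / "longitudinal_effects.csv", index=False)

    for _, row in frame[frame.term.isin(["followup_vs_baseline", "d_bmi_sds"])].iterrows():
        print(f"{row.model_tag} {row.tissue} {row.term:>20}: beta {row.beta:+.3f} "
              f"[{row.ci_low:+.3f}, {row.ci_high:+.3f}], p {row.p_value:.2g}")
    print(f"wrote {len(frame)} effect rows to {OUT / 'longitudinal_effects.csv'}")


if __name__ == "__main__":
    main()
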