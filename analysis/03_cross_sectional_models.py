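#!/usr/bin/env python
"""Cross-sectional group differences and clinical associations in BrainAGE.

Reads the scored cohort from results/ (steps 01-02) and fits, per tissue:
the primary group model (CS1), the age / SSRI / subtype-adjusted variants
(CS2a-c) and the clinical-association model within acute patients (CS3).
Writes the combined effects table and prints the contrasts against controls
at the study's multiplicity threshold 0.05/6 = 0.0083.
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
        for tag in ("CS1", "CS2a", "CS2b", "CS2c"):
            effects += stats.cross_sectional_model(records, results, spec, model=tag)
        effects += stats.clinical_association_model(records, results, spec)
    frame = effects_frame(effects)
    frame.to_csv(OUT / "cross_sectional_effects.csv", index=False)

    alpha = stats.adjust_alpha(2, 3)
    print(f"multiplicity threshold: {stats.format_alpha(alpha)}")
    cs1 = frame[(frame.model_tag == "CS1")]
    for _, row in cs1.iterrows():
        star = "*" if row.p_value < alpha else " "
        print(f"CS1 {row.tissue} {row.term:>12}: beta {row.beta:+.2f} y "
              f"[{row.ci_low:+.2f}, {row.ci_high:+.2f}], p {row.p_value:.2g} {star}")
    print(f"wrote {len(frame)} effect rows to {OUT / 'cross_sectional_effects.csv'}")


if __name__ == "__main__":
    main()
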