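"""Survival stratification by the network signature scores.

Univariate: optimal-cutpoint log-rank per score. Multivariate: Cox
proportional hazards adjusting each score for stromal score, immune score
and tumor purity.
"""

from pathlib import Path

import pandas as pd

from fflscope.config import RunConfig
from fflscope.pipeline import stage_report, stage_survive

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

if __name__ == "__main__":
    config = RunConfig(seed=1)
    stage_survive(config, OUT)
    stage_report(config, OUT)
    rep = pd.read_csv(OUT / "survival_report.tsv", sep="\t")
    print(rep[["variable", "analysis", "hr", "ci_low", "ci_high", "p", "direction"]]
          .to_string(index=False))
    uni = rep[rep["analysis"] == "univariate"].set_index("variable")
    print(f"\nhub score is protective (HR {uni.loc['hub_score', 'hr']:.2f}), "
          f"miRNA score adverse (HR {uni.loc['mirna_score', 'hr']:.2f})")
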