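"""Score the five instruments and estimate prevalences.

PHQ-9A and GAS-7 caseness use the >= 10 cutoff; prevalences come with
Wilson 95% intervals.  Run 02_simulate_survey.py first.
"""

import json
from pathlib import Path

import pandas as pd

from nrsem.scales import prevalence_report, score_dataset

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(OUT / "survey.csv")
    scored = score_dataset(table)
    scored.to_csv(OUT / "survey_scored.csv", index=False)
    rep = prevalence_report(scored)
    (OUT / "prevalence.json").write_text(json.dumps(rep, indent=2))
    for scale, r in rep.items():
        print(f"{scale}: {r['percent']:.2f}% "
              f"(95% CI {r['ci_low_percent']:.1f}, {r['ci_high_percent']:.1f}; "
              f"cutoff >= {r['cutoff']}, n = {r['n']})")


if __name__ == "__main__":
    main()
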