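"""Pre-model screening of the survey data.

Checks, with the conventional thresholds: multivariate normality (Mardia
kurtosis excess > 7 with critical ratio > 5 -> bootstrap CIs instead of
normal-theory ones), multivariate outliers (chi-square p < 0.001),
sampling adequacy (KMO, Bartlett), clustering (ICC < 0.1 permits a
single-level model) and common-method bias (Harman first-factor share).
"""

import json
from pathlib import Path

import pandas as pd

from nrsem import diagnostics as diag
from nrsem.pipeline import CONSTRUCT_ITEMS, composite_scores

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = pd.read_csv(OUT / "survey.csv")
    item_cols = [c for cols in CONSTRUCT_ITEMS.values() for c in cols]
    items = table[item_cols].dropna()

    normality = diag.mardia_kurtosis(items)
    outliers = diag.mahalanobis_outliers(items, alpha=0.001)
    adequacy = diag.adequacy_report(table, CONSTRUCT_ITEMS)
    cmb = diag.harman_single_factor(items)
    icc_rep = diag.clustering_report(composite_scores(table.dropna()),
                                     ["depression", "anxiety", "somatic"],
                                     ["school_private"])

    report = {
        "mardia": vars(normality),
        "outliers": {"n_flagged": outliers.n_outliers, "alpha": 0.001},
        "adequacy": adequacy,
        "harman": vars(cmb),
        "icc": icc_rep.iccs,
    }
    (OUT / "diagnostics.json").write_text(json.dumps(report, indent=2, default=float))
    print(f"Mardia excess {normality.b2p - normality.expected:.1f} "
          f"(CR {normality.critical_ratio:.1f}) -> "
          f"{'non-normal: use bootstrap CIs' if normality.nonnormal else 'acceptable'}")
    print(f"outliers at p<0.001: {outliers.n_outliers}; "
          f"overall KMO {adequacy['overall']['kmo']:.2f}; "
          f"Harman share {100 * cmb.first_factor_share:.1f}%")


if __name__ == "__main__":
    main()
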