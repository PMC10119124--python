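"""Group-wise feature enrichment: a binomial-GLM score (Rao) test of each
feature's occurrence across two genome groups, with Benjamini-Hochberg
q-values and a q < 0.05 enrichment call.

For a binary outcome and a single binary group covariate, the logistic-model
score statistic is algebraically identical to the Pearson chi-square of the
2x2 occurrence-by-group table; the statistic is computed from the score and
expected information of the logistic model and the identity is exercised in
the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OccurrenceTable",
    "rao_score_test",
    "bh_qvalues",
    "enrich",
]


@dataclass
class OccurrenceTable:
    """features x genomes 0/1 occurrence matrix plus a two-level group label
    per genome (canonically "high" / "low" abundance groups)."""

    occurrence: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        vals = self.occurrence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("occurrence entries must be 0/1")
        self.groups = self.groups.reindex(self.occurrence.columns)
        if self.groups.isna().any():
            raise ValueError("every genome needs a group label")
        levels = sorted(self.groups.unique())
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")


def rao_score_test(x, g) -> tuple[float, float]:
    """Score (Rao) test of a group effect on a binary outcome.

    ``x`` are 0/1 outcomes, ``g`` the two-level group labels.  The statistic
    is U^2 / V with U the logistic score for the group coefficient evaluated
    at the intercept-only fit and V its expected information; this equals the
    Pearson chi-square of the 2x2 table.  Degenerate all-0 or all-1 outcomes
    give statistic 0, p = 1.  The p-value is the chi-square (df=1) upper tail.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(g)
    if x.shape != g.shape:
        raise ValueError("outcomes and groups must align")
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {len(levels)}")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("outcomes must be 0/1")
    ind = (g == levels[1]).astype(float)
    n = len(x)
    pbar = x.mean()
    if pbar in (0.0, 1.0):
        return 0.0, 1.0
    u = float(np.sum(ind * (x - pbar)))
    n1 = float(ind.sum())
    v = pbar * (1 - pbar) * n1 * (n - n1) / n
    stat = u * u / v
    return float(stat), float(chi2.sf(stat, df=1))


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(table: OccurrenceTable, q_max: float = 0.05) -> pd.DataFrame:
    """Per-feature enrichment across the two genome groups.

    Returns a frame with group occurrence proportions, the Rao score
    statistic, p, BH q, the ``enriched`` flag (q < q_max) and the associated
    group (the one with the higher occurrence proportion).
    """
    levels = sorted(table.groups.unique())
    g = table.groups.to_numpy()
    rows = []
    for feature, x in table.occurrence.iterrows():
        xv = x.to_numpy(float)
        stat, p = rao_score_test(xv, g)
        props = {lv: xv[g == lv].mean() for lv in levels}
        assoc = max(levels, key=lambda lv: props[lv])
        rows.append(
            {
                "feature": feature,
                **{f"prop_{lv}": props[lv] for lv in levels},
                "statistic": stat,
                "p_value": p,
                "associated_group": assoc,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    out["enriched"] = out["q_value"] < q_max
    return out
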