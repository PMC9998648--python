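"""Post-hoc summaries: RSN-level effect percentages and cohort demographics.

The RSN summary reports, per resting-state network, the percentage of
within-network links whose twin decomposition fell in each scenario
(epistasis, ADE, ACE).  "Within-network" means both link endpoints belong to
the network; boundary-spanning links are excluded.

The demographic statistics are the classic group comparisons computable from
printed summary data alone: a pooled-variance two-sample t test from means,
SDs and counts, and a 2x2 Pearson chi-square (no continuity correction) for
sex-by-zygosity pair counts.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import RSNMap, ValidationError

__all__ = [
    "rsn_effect_percentages",
    "pooled_t_from_summary",
    "chi2_2x2",
]

_SCENARIO_COLUMNS = ("EPISTASIS", "ADE", "ACE", "UNMODELED")


def rsn_effect_percentages(results: pd.DataFrame, rsn_map: RSNMap) -> pd.DataFrame:
    """Percentage of within-RSN links per scenario, one row per RSN.

    Denominator = number of ROI pairs with both endpoints inside the RSN
    (each must appear as a link-scale record in ``results``).  Percentages
    over {EPISTASIS, ADE, ACE, UNMODELED} sum to 100 per RSN.
    """
    links = results[results["scale"] == "link"]
    scenario_by_link = dict(zip(links["feature_id"], links["scenario"]))
    rows = []
    for name, rois in rsn_map.items():
        order = {lab: i for i, lab in enumerate(rsn_map.parcellation.labels)}
        counts = dict.fromkeys(_SCENARIO_COLUMNS, 0)
        n_links = 0
        for a, b in itertools.combinations(sorted(rois, key=order.__getitem__), 2):
            fid = f"link:{a}|{b}"
            if fid not in scenario_by_link:
                raise ValidationError(f"results table has no record for {fid}")
            counts[scenario_by_link[fid]] += 1
            n_links += 1
        rows.append(
            {
                "RSN": name,
                "n_links": n_links,
                **{s: 100.0 * counts[s] / n_links for s in _SCENARIO_COLUMNS},
            }
        )
    return pd.DataFrame(rows)


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int, float]:
    """Two-sample pooled-variance t test from summary statistics.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.  Inputs are the
    group means, standard deviations and counts as printed in a demographic
    table.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValidationError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, int, float]:
    """Pearson chi-square for a 2x2 count table [[a, b], [c, d]].

    No Yates continuity correction.  Returns (chi2, df=1, p).  Both row and
    column margins must be positive.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValidationError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValidationError("chi-square undefined: a table margin is zero")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
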