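"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations, structurally unrelated to the package's
code paths: breadth-first flood fill for connected components, an all-pairs
set-intersection loop for lesion matching, and a regression-based two-way
ANOVA for the ICC mean squares.
"""

from collections import deque

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_components(vox):
    """Partition foreground into 26-connected components by BFS.

    Returns a list of frozensets of voxel index triples, ordered by each
    component's lexicographically smallest voxel.
    """
    remaining = set(map(tuple, np.argwhere(vox)))
    comps = []
    for start in sorted(map(tuple, np.argwhere(vox))):
        if start not in remaining:
            continue
        comp = {start}
        remaining.discard(start)
        queue = deque([start])
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in NEIGHBORS_26:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(frozenset(comp))
    return comps


def brute_force_detected(rs_sets, as_sets, min_rs_fraction, max_as_fraction, interpretation):
    """All-pairs evaluation of the double overlap rule on raw voxel sets.

    ``rs_sets`` / ``as_sets`` map lesion id -> set of voxel triples.
    Returns the set of detected reference lesion ids.
    """
    detected = set()
    for rid, r in rs_sets.items():
        for aid, a in as_sets.items():
            ov = len(r & a)
            if ov == 0 or ov / len(r) < min_rs_fraction:
                continue
            if interpretation == "literal":
                ok = ov / len(a) <= max_as_fraction
            else:
                ok = (len(a) - ov) / len(a) <= max_as_fraction
            if ok:
                detected.add(rid)
                break
    return detected


def icc_2_1_regression_oracle(table):
    """ICC(2,1) with mean squares from a statsmodels OLS two-way ANOVA."""
    import pandas as pd
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    x = np.asarray(table, dtype=float)
    n, k = x.shape
    rows = [
        {"y": x[i, j], "subject": f"s{i}", "rater": f"r{j}"}
        for i in range(n)
        for j in range(k)
    ]
    fit = smf.ols("y ~ C(subject) + C(rater)", pd.DataFrame(rows)).fit()
    tab = anova_lm(fit)
    msr = tab.loc["C(subject)", "sum_sq"] / tab.loc["C(subject)", "df"]
    msc = tab.loc["C(rater)", "sum_sq"] / tab.loc["C(rater)", "df"]
    mse = tab.loc["Residual", "sum_sq"] / tab.loc["Residual", "df"]
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return (msr - mse) / denom
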