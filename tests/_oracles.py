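"""Independent oracles used only by the tests.

These re-derive expected values by brute force (enumeration, per-entry
evaluation, exhaustive scans) without touching the code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def dense_stoichiometry(model, mu: float) -> np.ndarray:
    """Element-wise hand evaluation of S(mu): loop each reaction's entries
    and accumulate a + b*mu into a dense matrix."""
    met_idx = {m: i for i, m in enumerate(model.metabolite_ids)}
    S = np.zeros((len(model.metabolite_ids), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met, a, b in rxn.entries:
            S[met_idx[met], j] += a + b * mu
    return S


def exact_mwu_pvalue(x, y, alternative: str) -> float:
    """Permutation-exact one-tailed MWU p-value by full enumeration.

    Pools the observations, enumerates every C(n1+n2, n1) assignment of the
    pooled values to the first group, and counts assignments whose U statistic
    is at least (alternative='greater') / at most ('less') as extreme as the
    observed one.  Average ranks on ties.
    """
    x = list(x)
    y = list(y)
    pooled = np.array(x + y, dtype=float)
    n1 = len(x)
    ranks = rankdata(pooled)

    def u_of(idx: tuple[int, ...]) -> float:
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    u_obs = u_of(tuple(range(n1)))
    total = 0
    hits = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        u = u_of(idx)
        if alternative == "greater":
            hits += u >= u_obs - 1e-12
        elif alternative == "less":
            hits += u <= u_obs + 1e-12
        else:  # pragma: no cover
            raise ValueError(alternative)
    return hits / total
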