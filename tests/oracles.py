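"""Independent brute-force oracles used to check the implementation.

These deliberately avoid the code paths they verify: the Bayes oracle
enumerates the full joint distribution table; the rank-test oracles
enumerate group labelings / sign patterns directly.
"""

from __future__ import annotations

import itertools
import math

from scipy.stats import rankdata


def enum_posterior(prior_active, gene_params, evidence):
    """Posterior P(active | evidence) by enumerating the full joint over the
    hidden state and every gene's evidence value.

    ``gene_params``: gene -> object with p_high_given_active /
    p_high_given_inactive. ``evidence``: gene -> True (high) / False (low) /
    None (unobserved; marginalised out).
    """
    genes = list(gene_params)
    total = {True: 0.0, False: 0.0}
    for state in (True, False):
        p_state = prior_active if state else 1.0 - prior_active
        for combo in itertools.product((True, False), repeat=len(genes)):
            ok = all(
                evidence.get(g) is None or evidence[g] == e
                for g, e in zip(genes, combo)
            )
            if not ok:
                continue
            p = p_state
            for g, e in zip(genes, combo):
                gp = gene_params[g]
                ph = gp.p_high_given_active if state else gp.p_high_given_inactive
                p *= ph if e else (1.0 - ph)
            total[state] += p
    z = total[True] + total[False]
    return total[True] / z


def _u_statistic(ranks, idx, n1):
    r1 = sum(ranks[i] for i in idx)
    return r1 - n1 * (n1 + 1) / 2.0


def mwu_exact_p(group_a, group_b, alternative):
    """Exact Mann-Whitney p by full enumeration of C(n1+n2, n1) labelings."""
    pooled = list(group_a) + list(group_b)
    n1 = len(group_a)
    ranks = rankdata(pooled)
    obs = _u_statistic(ranks, range(n1), n1)
    us = [
        _u_statistic(ranks, idx, n1)
        for idx in itertools.combinations(range(len(pooled)), n1)
    ]
    n = len(us)
    eps = 1e-9
    p_le = sum(u <= obs + eps for u in us) / n
    p_ge = sum(u >= obs - eps for u in us) / n
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_exact_p(diffs, alternative):
    """Exact signed-rank p by enumerating all 2^n sign patterns.

    ``diffs`` must be nonzero; ties in |diffs| get mid-ranks.
    """
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = rankdata([abs(x) for x in d])
    obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ws = []
    for signs in itertools.product((1, -1), repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s > 0))
    m = len(ws)
    eps = 1e-9
    p_le = sum(w <= obs + eps for w in ws) / m
    p_ge = sum(w >= obs - eps for w in ws) / m
    if alternative == "less":
        return p_le
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_le, p_ge))
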