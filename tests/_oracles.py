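"""Independent brute-force oracles used by the test suite.

These are deliberately naive loop implementations, kept separate from the
package so they can serve as references for the vectorized code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_curve(ordered_scores, hit_flags, weight_exponent):
    """Plain-loop running enrichment sum; returns (curve list, signed extremum)."""
    scores = [float(s) for s in ordered_scores]
    hits = [bool(h) for h in hit_flags]
    n = len(scores)
    m = sum(hits)
    assert 0 < m
    denom = sum(abs(s) ** weight_exponent for s, h in zip(scores, hits) if h)
    running = 0.0
    curve = []
    extremum = 0.0
    for s, h in zip(scores, hits):
        if h:
            if denom > 0:
                running += abs(s) ** weight_exponent / denom
            else:
                running += 1.0 / m
        else:
            running -= 1.0 / (n - m)
        curve.append(running)
        if abs(running) > abs(extremum):
            extremum = running
    return curve, extremum


def brute_force_reversal(ordered_scores, inc_flags, dec_flags, weight_exponent, same_sign_zero):
    """Reversal score from two membership masks, via the loop oracle."""
    _, es_inc = brute_force_curve(ordered_scores, inc_flags, weight_exponent)
    _, es_dec = brute_force_curve(ordered_scores, dec_flags, weight_exponent)
    if same_sign_zero and es_inc * es_dec > 0:
        return 0.0
    return (es_dec - es_inc) / 2.0


def exhaustive_pair_scores(ordered_scores, k_inc, k_dec, weight_exponent, same_sign_zero):
    """Reversal scores of every ordered disjoint (increased, decreased) set pair."""
    n = len(ordered_scores)
    out = []
    for inc in itertools.combinations(range(n), k_inc):
        rest = [i for i in range(n) if i not in inc]
        for dec in itertools.combinations(rest, k_dec):
            inc_flags = [i in inc for i in range(n)]
            dec_flags = [i in dec for i in range(n)]
            out.append(
                brute_force_reversal(
                    ordered_scores, inc_flags, dec_flags, weight_exponent, same_sign_zero
                )
            )
    return np.asarray(out)


def welch_t_scalar(a, b):
    """Textbook Welch statistic and one-sided (a > b) p via the t distribution."""
    from scipy import stats

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, float(stats.t.sf(t, df))
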