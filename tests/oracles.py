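"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately naive (enumeration, explicit loops) and
never calls the code paths it is used to check.
"""

import itertools
import math

import numpy as np


def pairwise_mean(indices, D):
    """Mean distance over unordered slot pairs of a multiset of indices."""
    pairs = list(itertools.combinations(range(len(indices)), 2))
    return sum(D[indices[a], indices[b]] for a, b in pairs) / len(pairs)


def _enumerate_expected(richness, D, variant):
    """Per plot, the list of equally likely null mean pairwise distances.

    ``subset``: the C(K, N) distinct communities; ``multiset``: the K^N
    ordered with-replacement draws (conspecific pairs hit D's zero
    diagonal).
    """
    K = D.shape[0]
    per_plot = []
    for n in richness:
        if variant == "multiset":
            draws = itertools.product(range(K), repeat=n)
        else:
            draws = itertools.combinations(range(K), n)
        per_plot.append([pairwise_mean(draw, D) for draw in draws])
    return per_plot


def exact_zero_threshold_p(observed, richness, D, alternative, variant="subset"):
    """Exact probability that the median of (observed - expected)
    contradicts the alternative (<= 0 for divergence, >= 0 for
    convergence), enumerating every possible null draw."""
    per_plot = _enumerate_expected(richness, D, variant)
    count = 0
    total = 0
    for combo in itertools.product(*per_plot):
        med = float(np.median([o - e for o, e in zip(observed, combo)]))
        if alternative == "divergence":
            count += med <= 0
        else:
            count += med >= 0
        total += 1
    return count / total


def exact_calibrated_p(observed, richness, D, alternative, variant="subset"):
    """Exact randomization p: rank median(observed - E[expected]) within
    the enumerated null medians, centered the same way."""
    per_plot = _enumerate_expected(richness, D, variant)
    ee = [sum(vals) / len(vals) for vals in per_plot]
    t_obs = float(np.median([o - e for o, e in zip(observed, ee)]))
    count = 0
    total = 0
    for combo in itertools.product(*per_plot):
        t = float(np.median([v - e for v, e in zip(combo, ee)]))
        if alternative == "divergence":
            count += t >= t_obs - 1e-9
        else:
            count += t <= t_obs + 1e-9
        total += 1
    return count / total


def tau_pair_oracle(species_i, species_j, get):
    """Brute-force turnover for one plot pair; `get(a, b)` is the distance."""
    within = []
    for group in (species_i, species_j):
        for a, b in itertools.combinations(group, 2):
            within.append(get(a, b))
    among = [get(a, b) for a in species_i for b in species_j if a != b]
    dw = sum(within) / len(within)
    da = sum(among) / len(among)
    return 1 - dw / da, dw, da


def mantel_exact_p(m1, m2):
    """Exact one-tailed Mantel p over all n! label permutations of m2."""
    n = m1.shape[0]
    iu = [(i, j) for i in range(n) for j in range(i + 1, n)]
    x = [m1[i, j] for i, j in iu]

    def corr(perm):
        y = [m2[perm[i], perm[j]] for i, j in iu]
        mx, my = sum(x) / len(x), sum(y) / len(y)
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
        )
        return num / den

    r_obs = corr(tuple(range(n)))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = corr(perm)
        if r_obs >= 0:
            count += r >= r_obs - 1e-12
        else:
            count += r <= r_obs + 1e-12
        total += 1
    return r_obs, count / total
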