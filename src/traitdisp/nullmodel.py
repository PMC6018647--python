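"""Within-plot dispersion test against a random-resampling null.

For each plot the observed mean pairwise trait distance among
co-occurring species is compared to replicate communities built by
redrawing the plot's N species uniformly from the species pool with
trait data (each species equally represented).  Two null variants:

* ``subset`` (default) — each plot receives N *distinct* species;
  species are replaced between plots (the same species may be redrawn
  in many plots).  This null is exactly the neutral assembly process,
  so the test is calibrated: under neutrality the rejection rate equals
  alpha.
* ``multiset`` — the literal within-plot with-replacement draw: a plot
  may receive conspecific duplicates, whose pairs contribute distance
  zero to the expected mean.  This biases expected distances low by a
  factor ~(1 - 1/K) and makes the divergence test anti-conservative;
  it is kept as a labelled sensitivity variant.

The effect size is, per replicate, the median over plots of
(observed - expected) mean distance; its mean +/- SD over replicates is
the reported O-E summary.  Two p-values are computed:

* ``p`` (primary) — an exchangeable randomization p: the observed
  median T_obs = median_p(O_p - Ebar_p) is ranked within the null
  medians T_r = median_p(E_pr - Ebar_p), where Ebar is the mean
  expected distance over all replicates.  Under a neutral community
  the observed communities are one more draw from the null, so this p
  is calibrated (type-I error = alpha).
* ``p_zero_threshold`` — the corrected proportion of replicate medians
  contradicting the stated alternative (<= 0 for divergence, >= 0 for
  convergence).  This matches the source description literally but is
  strongly conservative (its replicate medians are compared to zero
  rather than to each other); it is reported for reference only.

Both use the (count + 1) / (R + 1) correction and are one-tailed:

* ``divergence``  — evidence is large positive medians
* ``convergence`` — evidence is large negative medians
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .dissimilarity import DistanceMatrix, euclidean_distance, filter_shared_columns, jaccard_dissimilarity
from .io_validation import AnalysisBundle, ContinuousTraitMatrix, OccurrenceMatrix, restrict_to_trait_coverage
from .ordination import zscore

__all__ = [
    "NullModelResult",
    "mean_within_plot_distance",
    "null_replicate",
    "median_difference_test",
    "run_all_trait_tests",
]

ALTERNATIVES = ("divergence", "convergence")
NULL_VARIANTS = ("subset", "multiset")


@dataclass
class NullModelResult:
    plot_ids: list[str]
    observed: pd.Series  # per-plot observed mean distance
    replicate_medians: np.ndarray  # length R
    mean: float
    sd: float
    p: float  # calibrated randomization p (see module docstring)
    p_zero_threshold: float  # literal zero-comparison p, conservative
    alternative: str
    seed: int | None
    R: int
    pool: list[str] = field(default_factory=list)
    expected: np.ndarray | None = None  # R x plots, kept on request

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p <= alpha

    def summary(self) -> dict:
        return {
            "O_E_mean": self.mean,
            "O_E_sd": self.sd,
            "p": self.p,
            "p_zero_threshold": self.p_zero_threshold,
            "alternative": self.alternative,
            "R": self.R,
            "seed": self.seed,
            "n_plots": len(self.plot_ids),
            "pool_size": len(self.pool),
        }


def _usable_plot_multisets(
    occurrence: OccurrenceMatrix, covered: set[str]
) -> dict[str, list[str]]:
    """Plot -> co-occurring covered species; plots with <2 are excluded."""
    plots: dict[str, list[str]] = {}
    skipped = []
    for p in occurrence.plot_ids:
        species = [s for s in occurrence.plot_species(p) if s in covered]
        if len(species) >= 2:
            plots[p] = species
        else:
            skipped.append(p)
    if skipped:
        warnings.warn(
            f"excluding plot(s) with fewer than two covered species: {skipped}",
            stacklevel=3,
        )
    return plots


def mean_within_plot_distance(
    occurrence: OccurrenceMatrix, dist: DistanceMatrix
) -> pd.Series:
    """Per-plot mean distance over all unordered pairs of co-occurring species."""
    covered = set(dist.entity_ids)
    plots = _usable_plot_multisets(occurrence, covered)
    if not plots:
        raise ValueError("no plot has two or more species covered by the distance matrix")
    out = {}
    for p, species in plots.items():
        sub = dist.sub(species)
        n = len(species)
        out[p] = float(sub[np.triu_indices(n, k=1)].mean())
    return pd.Series(out, name="observed_mean_distance")


def null_replicate(
    occurrence: OccurrenceMatrix,
    pool: list[str],
    rng: np.random.Generator,
    variant: str = "subset",
) -> dict[str, list[str]]:
    """One randomized community: each plot's N species redrawn from `pool`.

    Draws are uniform over the pool (each species equally represented)
    and independent across plots.  ``subset`` keeps species distinct
    within a plot; ``multiset`` allows conspecific duplicates, whose
    pairs later contribute distance zero.  Returns plot -> species list.
    """
    if variant not in NULL_VARIANTS:
        raise ValueError(f"variant must be one of {NULL_VARIANTS}")
    pool = list(pool)
    out = {}
    for p in occurrence.plot_ids:
        n = int(occurrence.data.loc[p].sum())
        if variant == "multiset":
            idx = rng.integers(0, len(pool), size=n)
        else:
            if n > len(pool):
                raise ValueError(
                    f"plot {p!r} richer than the pool; cannot draw distinct species"
                )
            idx = rng.choice(len(pool), size=n, replace=False)
        out[p] = [pool[i] for i in idx]
    return out


def _expected_means(
    richness: np.ndarray,
    D: np.ndarray,
    n_pool: int,
    R: int,
    rng: np.random.Generator,
    variant: str,
) -> np.ndarray:
    """R x plots matrix of null mean pairwise distances (vectorized draws).

    D has a zero diagonal, so under the multiset variant conspecific
    duplicate pairs automatically contribute zero to the mean.
    """
    n_plots = len(richness)
    exp = np.empty((R, n_plots))
    for j, n in enumerate(richness):
        if variant == "multiset":
            idx = rng.integers(0, n_pool, size=(R, n))
        else:
            if n > n_pool:
                raise ValueError("plot richer than the pool; cannot draw distinct species")
            # distinct draws per replicate: first n slots of a random order
            idx = np.argsort(rng.random((R, n_pool)), axis=1)[:, :n]
        total = np.zeros(R)
        for a in range(n):
            for b in range(a + 1, n):
                total += D[idx[:, a], idx[:, b]]
        exp[:, j] = total / comb(n, 2)
    return exp


def median_difference_test(
    occurrence: OccurrenceMatrix,
    dist: DistanceMatrix,
    pool: list[str],
    R: int = 1000,
    alternative: str = "divergence",
    seed: int | None = None,
    variant: str = "subset",
    outlier_control: bool = False,
    store_expected: bool = False,
) -> NullModelResult:
    """Median-of-differences randomization test over plots.

    ``variant`` selects the null draw (see module docstring);
    ``outlier_control`` is a labelled sensitivity variant: plots whose
    (observed - mean expected) falls beyond 1.5x the interquartile range
    of those differences are excluded before the medians are taken.
    """
    if R < 1:
        raise ValueError("need at least one replicate")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    if variant not in NULL_VARIANTS:
        raise ValueError(f"variant must be one of {NULL_VARIANTS}")
    pool = list(pool)
    missing = sorted(set(pool) - set(dist.entity_ids))
    if missing:
        raise ValueError(f"pool species missing from distance matrix: {missing}")

    observed = mean_within_plot_distance(occurrence, dist)
    plot_ids = list(observed.index)
    # richness counts only species present in the distance matrix
    covered_cols = [s for s in occurrence.species_ids if s in set(dist.entity_ids)]
    richness = occurrence.data.loc[plot_ids, covered_cols].sum(axis=1).to_numpy(dtype=int)

    pool_idx = [dist.entity_ids.index(s) for s in pool]
    D = dist.values[np.ix_(pool_idx, pool_idx)]

    rng = np.random.default_rng(seed)
    expected = _expected_means(richness, D, len(pool), R, rng, variant)

    obs = observed.to_numpy()
    if outlier_control:
        delta = obs - expected.mean(axis=0)
        q1, q3 = np.percentile(delta, [25, 75])
        iqr = q3 - q1
        keep = (delta >= q1 - 1.5 * iqr) & (delta <= q3 + 1.5 * iqr)
        if keep.sum() < 2:
            raise ValueError("outlier control left fewer than two plots")
        obs = obs[keep]
        expected = expected[:, keep]
        plot_ids = [p for p, k in zip(plot_ids, keep) if k]
        observed = observed[keep]

    medians = np.median(obs[None, :] - expected, axis=1)
    if alternative == "divergence":
        contradicting = int((medians <= 0).sum())
    else:
        contradicting = int((medians >= 0).sum())
    p_zero = (contradicting + 1) / (R + 1)

    # calibrated randomization p: rank the observed median among the null
    # medians, both centered on the mean expected distance per plot
    ebar = expected.mean(axis=0)
    t_obs = float(np.median(obs - ebar))
    t_null = np.median(expected - ebar[None, :], axis=1)
    # epsilon keeps exact ties (same draw, different summation order) extreme
    eps = 1e-9 * max(1.0, abs(t_obs))
    if alternative == "divergence":
        extreme = int((t_null >= t_obs - eps).sum())
    else:
        extreme = int((t_null <= t_obs + eps).sum())
    p = (extreme + 1) / (R + 1)

    return NullModelResult(
        plot_ids=plot_ids,
        observed=observed,
        replicate_medians=medians,
        mean=float(medians.mean()),
        sd=float(medians.std(ddof=1)) if R > 1 else 0.0,
        p=float(p),
        p_zero_threshold=float(p_zero),
        alternative=alternative,
        seed=seed,
        R=R,
        pool=pool,
        expected=expected if store_expected else None,
    )


def run_all_trait_tests(
    bundle: AnalysisBundle,
    assemblages: dict[str, list[str]],
    R: int = 1000,
    seed: int | None = None,
    variant: str = "subset",
    outlier_control: bool = False,
) -> dict[str, NullModelResult]:
    """Run the dispersion test for the binary-trait set and each
    continuous-trait assemblage.

    ``assemblages`` maps a label (e.g. ``"rut_axis1"``) to a continuous
    trait subset.  The binary (SM) set is tested for divergence over the
    SM-covered pool; each continuous subset for convergence over the
    RUT-covered pool.  Stage seeds derive deterministically from `seed`.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(1 + len(assemblages))
    results: dict[str, NullModelResult] = {}

    sm_shared = filter_shared_columns(bundle.sm)
    sm_dist = jaccard_dissimilarity(sm_shared)
    occ_sm = restrict_to_trait_coverage(bundle, "SM")
    results["sm"] = median_difference_test(
        occ_sm, sm_dist, pool=sm_shared.species_ids, R=R,
        alternative="divergence",
        seed=int(child_seeds[0].generate_state(1)[0]),
        variant=variant, outlier_control=outlier_control,
    )

    rut_z = ContinuousTraitMatrix(zscore(bundle.rut.data), standardized=True)
    occ_rut = restrict_to_trait_coverage(bundle, "RUT")
    for k, (label, subset) in enumerate(assemblages.items(), start=1):
        d = euclidean_distance(rut_z, subset)
        results[label] = median_difference_test(
            occ_rut, d, pool=rut_z.species_ids, R=R,
            alternative="convergence",
            seed=int(child_seeds[k].generate_state(1)[0]),
            variant=variant, outlier_control=outlier_control,
        )
    return results
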