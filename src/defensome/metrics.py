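"""Defensome abundance/density/prevalence metrics, size correlations,
phylogenetic depth, stepwise regression and habitat comparisons.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import dendropy
import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import DefenseAnnotation, DefenseSystem, GeneStatus, MAGRecord


def density(count: int, size_bp: int) -> float:
    """Per-kb density: count / (size_bp / 1000)."""
    if size_bp <= 0:
        raise ValueError(f"size_bp must be positive, got {size_bp}")
    return count / (size_bp / 1000.0)


@dataclass
class DefensomeProfile:
    """Per-MAG defensome summary."""

    mag_id: str
    habitat: str
    size_bp: int
    n_systems: int                 # complete systems
    n_systems_any: int             # complete + incomplete
    n_defense_genes: int
    families_complete: frozenset   # families with >= 1 complete system
    families_any: frozenset        # families with >= 1 defense gene
    mechanism_counts: Dict[str, int] = field(default_factory=dict)

    @property
    def density_systems_per_kb(self) -> float:
        return density(self.n_systems, self.size_bp)

    @property
    def density_genes_per_kb(self) -> float:
        return density(self.n_defense_genes, self.size_bp)


def build_profile(
    mag: MAGRecord,
    systems: Sequence[DefenseSystem],
    hits: Sequence[DefenseAnnotation],
    mechanism_map: Optional[Mapping[str, str]] = None,
) -> DefensomeProfile:
    """Aggregate one MAG's assembled systems and hits into a profile.

    ``mechanism_map`` maps family -> mechanism class (e.g. RM, Abi, pAbi,
    other); counts are over complete systems and sum to n_systems when
    the map covers every family.
    """
    complete = [s for s in systems if s.complete]
    mech: Dict[str, int] = defaultdict(int)
    if mechanism_map is not None:
        for s in complete:
            mech[mechanism_map.get(s.family, "other")] += 1
    return DefensomeProfile(
        mag_id=mag.mag_id,
        habitat=mag.habitat,
        size_bp=mag.size_bp,
        n_systems=len(complete),
        n_systems_any=len(systems),
        n_defense_genes=len(hits),
        families_complete=frozenset(s.family for s in complete),
        families_any=frozenset(h.family for h in hits),
        mechanism_counts=dict(mech),
    )


def family_prevalence(
    profiles: Sequence[DefensomeProfile], complete_only: bool = True
) -> Dict[str, float]:
    """Percentage of MAGs harboring each family.

    By default a MAG counts when it has >= 1 *complete* system of the
    family; ``complete_only=False`` counts any defense gene instead.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    counts: Dict[str, int] = defaultdict(int)
    for p in profiles:
        fams = p.families_complete if complete_only else p.families_any
        for fam in fams:
            counts[fam] += 1
    n = len(profiles)
    return {fam: 100.0 * c / n for fam, c in sorted(counts.items())}


def size_correlation(
    sizes_bp: Sequence[float], values: Sequence[float]
) -> Tuple[float, float]:
    """Two-sided Spearman rank correlation of a defensome quantity
    against MAG size (average ranks on ties).  Returns (rho, p); a
    constant input leaves rho undefined (NaN) with a warning."""
    x = np.asarray(sizes_bp, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need >= 4 MAGs for a rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# phylogenetic depth
# ---------------------------------------------------------------------------

def phylo_depth(tree: dendropy.Tree, midpoint_root: bool = False) -> float:
    """Mean root-to-tip distance of a rooted tree.

    Equals the diagonal mean of the phylogenetic variance-covariance
    matrix.  A basal polytomy (root with > 2 children) is treated as the
    unrooted convention and rejected unless ``midpoint_root`` is set.
    """
    root = tree.seed_node
    if len(root.child_nodes()) > 2:
        if not midpoint_root:
            raise ValueError(
                "tree appears unrooted (basal polytomy); pass midpoint_root=True"
            )
        tree.reroot_at_midpoint(update_bipartitions=True)
        root = tree.seed_node
    depths = []
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node is not root:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if not depths:
        raise ValueError("tree has no leaves")
    return float(np.mean(depths))


# ---------------------------------------------------------------------------
# stepwise regression
# ---------------------------------------------------------------------------

def stepwise_regression(
    response: Sequence[float],
    predictors: Mapping[str, Sequence[float]],
) -> dict:
    """Bidirectional stepwise OLS by AIC starting from the intercept-only
    model.

    Predictors are standardized (z-score) before selection.  Returns the
    selected terms, their coefficients, partial R-squared, and the final
    model's AIC and R-squared.
    """
    y = np.asarray(response, dtype=float)
    if y.size < 10:
        raise ValueError("need >= 10 observations for stepwise selection")
    X: Dict[str, np.ndarray] = {}
    for name, vals in predictors.items():
        v = np.asarray(vals, dtype=float)
        sd = v.std(ddof=0)
        if sd == 0:
            raise ValueError(f"predictor {name!r} is constant")
        X[name] = (v - v.mean()) / sd

    names = sorted(X)
    for a, b in combinations(names, 2):
        r = np.corrcoef(X[a], X[b])[0, 1]
        if abs(r) > 0.999:
            warnings.warn(f"predictors {a!r} and {b!r} collinear (|r|={abs(r):.4f})", stacklevel=2)

    def fit(selected: Tuple[str, ...]):
        mat = np.column_stack([np.ones_like(y)] + [X[n] for n in selected])
        return sm.OLS(y, mat).fit()

    selected: Tuple[str, ...] = ()
    current = fit(selected)
    improved = True
    while improved:
        improved = False
        candidates: List[Tuple[float, Tuple[str, ...]]] = []
        for name in names:
            if name not in selected:
                candidates.append((fit(selected + (name,)).aic, selected + (name,)))
        for name in selected:
            reduced = tuple(n for n in selected if n != name)
            candidates.append((fit(reduced).aic, reduced))
        if candidates:
            best_aic, best_sel = min(candidates, key=lambda t: t[0])
            if best_aic < current.aic - 1e-9:
                selected = best_sel
                current = fit(selected)
                improved = True

    # partial R^2 of each selected term against the final model
    partial_r2 = {}
    for name in selected:
        reduced = fit(tuple(n for n in selected if n != name))
        rss_red = float(reduced.ssr)
        rss_full = float(current.ssr)
        partial_r2[name] = (rss_red - rss_full) / rss_red if rss_red > 0 else 0.0

    coefs = dict(zip(("intercept",) + selected, map(float, current.params)))
    return {
        "selected": list(selected),
        "coefficients": coefs,
        "partial_r2": partial_r2,
        "aic": float(current.aic),
        "r2": float(current.rsquared),
        "n": int(y.size),
    }


# ---------------------------------------------------------------------------
# habitat comparisons
# ---------------------------------------------------------------------------

def _boxplot_stats(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {
        "n": int(values.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
    }


def habitat_compare(groups: Mapping[str, Sequence[float]], min_n: int = 3) -> dict:
    """Pairwise two-sided Mann-Whitney U tests between habitat groups,
    with per-group boxplot descriptives (median, quartiles, 1.5*IQR
    whiskers).  Groups below ``min_n`` observations are excluded with a
    warning."""
    usable: Dict[str, np.ndarray] = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < min_n:
            warnings.warn(f"group {label!r} excluded (n={arr.size} < {min_n})", stacklevel=2)
            continue
        usable[label] = arr
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with enough observations")

    tests = []
    for a, b in combinations(sorted(usable), 2):
        res = stats.mannwhitneyu(usable[a], usable[b], alternative="two-sided")
        tests.append(
            {
                "group_a": a,
                "group_b": b,
                "U": float(res.statistic),
                "p": float(res.pvalue),
            }
        )
    descriptives = {label: _boxplot_stats(arr) for label, arr in sorted(usable.items())}
    return {"tests": tests, "groups": descriptives}
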