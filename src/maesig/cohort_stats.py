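"""Group-level analyses: mean bias with expression-matched controls,
ChIP-vs-expression allelic association, enrichment, cross-cell-type
similarity, cumulative MAE discovery curves, and bivalent-group overlap."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from maesig.allelic_bias import BiasCall

EXPRESSION_BIN_WIDTH = 0.1  # log10 RPKM units


@dataclass
class GroupBiasSummary:
    """Mean allelic bias for a gene group on the 50-100 scale, where 50 is
    perfect balance and 100 perfectly monoallelic."""

    label: str
    n: int
    mean_bias: float
    sd: float
    permutation_means: list[float] | None = None


def gene_bias_score(n_a: int, n_b: int) -> float:
    """Major-allele percentage: 100 * max(n_a, n_b) / (n_a + n_b)."""
    total = n_a + n_b
    if total == 0:
        raise ValueError("zero total count")
    return 100.0 * max(n_a, n_b) / total


def mean_group_bias(
    calls: Sequence[BiasCall], groups: Mapping[str, str]
) -> dict[str, GroupBiasSummary]:
    """Mean per-gene bias (50-100 scale) per group label; below-threshold
    calls are excluded, empty groups omitted with a warning."""
    by_label: dict[str, list[float]] = {}
    for call in calls:
        label = groups.get(call.unit_id)
        if label is None or call.category == "below_threshold":
            continue
        by_label.setdefault(label, []).append(gene_bias_score(call.n_a, call.n_b))
    for label in set(groups.values()) - set(by_label):
        warnings.warn(f"group {label!r} has no testable calls; omitted")
    return {
        label: GroupBiasSummary(
            label, len(vals), float(np.mean(vals)),
            float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        )
        for label, vals in by_label.items()
    }


def expression_bin(rpkm: float, width: float = EXPRESSION_BIN_WIDTH) -> int:
    """Index of the expression bin (`width` log10-RPKM units)."""
    if rpkm <= 0:
        raise ValueError("RPKM must be positive to bin on a log scale")
    return int(math.floor(math.log10(rpkm) / width))


def expression_matched_controls(
    target_genes: Iterable[str],
    pool: Iterable[str],
    rpkm: Mapping[str, float],
    n_sets: int = 10,
    seed: int = 0,
) -> list[list[str]]:
    """Sample `n_sets` control gene sets matching the targets' expression
    histogram over 0.1-log10-RPKM bins.

    Sampling is without replacement within a set; when a bin holds fewer
    pool genes than targets, the shortfall is borrowed from the nearest
    non-empty bin (a warning notes each borrow).
    """
    targets = list(target_genes)
    pool = list(pool)
    if set(targets) & set(pool):
        raise ValueError("pool must be disjoint from target set")
    if len(pool) < len(targets):
        raise ValueError("pool smaller than target set")
    rng = np.random.default_rng(seed)

    target_hist: dict[int, int] = {}
    for g in targets:
        target_hist[expression_bin(rpkm[g])] = target_hist.get(expression_bin(rpkm[g]), 0) + 1
    pool_bins: dict[int, list[str]] = {}
    for g in pool:
        pool_bins.setdefault(expression_bin(rpkm[g]), []).append(g)
    for genes in pool_bins.values():
        genes.sort()

    sets: list[list[str]] = []
    for _ in range(n_sets):
        available = {b: list(genes) for b, genes in pool_bins.items()}
        chosen: list[str] = []
        for b in sorted(target_hist):
            need = target_hist[b]
            got = available.get(b, [])
            take = min(need, len(got))
            if take:
                picked = rng.choice(len(got), size=take, replace=False)
                for i in sorted(picked, reverse=True):
                    chosen.append(got.pop(i))
            shortfall = need - take
            while shortfall > 0:
                nonempty = [bb for bb, gg in available.items() if gg]
                if not nonempty:
                    raise ValueError("pool exhausted while matching expression bins")
                nearest = min(nonempty, key=lambda bb: (abs(bb - b), bb))
                warnings.warn(
                    f"bin {b} short by {shortfall}; borrowing from bin {nearest}"
                )
                gg = available[nearest]
                take2 = min(shortfall, len(gg))
                picked = rng.choice(len(gg), size=take2, replace=False)
                for i in sorted(picked, reverse=True):
                    chosen.append(gg.pop(i))
                shortfall -= take2
        sets.append(sorted(chosen))
    return sets


def mae_fraction_by_expression_bin(
    calls: Mapping[str, str], rpkm: Mapping[str, float]
) -> dict[int, tuple[int, int, float]]:
    """Per expression bin: (n_mae, n_other, MAE fraction); empty bins omitted."""
    out: dict[int, list[int]] = {}
    for gene, call in calls.items():
        b = expression_bin(rpkm[gene])
        if b not in out:
            out[b] = [0, 0]
        out[b][0 if call == "MAE" else 1] += 1
    return {
        b: (n_mae, n_other, n_mae / (n_mae + n_other))
        for b, (n_mae, n_other) in sorted(out.items())
    }


def chip_bias_association(
    cdna_calls: Sequence[BiasCall],
    chip_counts: Mapping[str, tuple[int, int]],
) -> tuple[dict[str, list[float]], float, float]:
    """Test whether ChIP allelic balance differs across cDNA bias classes.

    SNPs are binned by their cDNA call into {biased_ref, unbiased,
    biased_alt}; the response is the ChIP reference-allele fraction at the
    same SNP.  Returns the per-bin response lists and the Kruskal-Wallis H
    (tie-corrected) with its chi-square p-value.
    """
    bins: dict[str, list[float]] = {"biased_ref": [], "unbiased": [], "biased_alt": []}
    for call in cdna_calls:
        counts = chip_counts.get(call.unit_id)
        if counts is None:
            continue
        na, nb = counts
        if na + nb == 0:
            continue
        frac = na / (na + nb)
        if call.category == "biased":
            bins["biased_ref" if call.direction == "a" else "biased_alt"].append(frac)
        elif call.category == "unbiased":
            bins["unbiased"].append(frac)
    groups = [v for v in bins.values() if v]
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty cDNA bias bins")
    h, p = stats.kruskal(*groups)
    return bins, float(h), float(p)


def enrichment_fisher(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> tuple[float, float]:
    """Two-tailed Fisher's exact test for overlap of two gene sets.

    Returns (odds ratio, p) from the 2x2 table partitioning the universe by
    membership in set_a and set_b; two-tailed p sums the hypergeometric
    probabilities of all tables at most as likely as the observed one.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a, b = set(set_a) & universe, set(set_b) & universe
    if not (a <= universe and b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(universe) - n11 - n12 - n21
    odds, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return float(odds), float(p)


def jaccard_similarity(sets: Mapping[str, Iterable[str]]) -> "np.ndarray":
    """Symmetric Jaccard matrix over cell-type gene sets (|A∩B| / |A∪B|);
    two empty sets get similarity 0 with a warning."""
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    as_sets = {k: set(v) for k, v in sets.items()}
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            union = as_sets[names[i]] | as_sets[names[j]]
            if not union:
                warnings.warn(
                    f"both {names[i]!r} and {names[j]!r} empty; Jaccard set to 0"
                )
                val = 0.0
            else:
                val = len(as_sets[names[i]] & as_sets[names[j]]) / len(union)
            mat[i, j] = mat[j, i] = val
    return mat


def cumulative_mae_curve(
    mae_sets: Mapping[str, Iterable[str]],
    expressed_sets: Mapping[str, Iterable[str]] | None = None,
    universe_mode: str = "common",
    n_perm: int = 1000,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Mean +/- SD of the cumulative MAE union over permuted cell-line order.

    For each k the union of the first k cell lines' MAE sets is counted;
    `universe_mode="common"` restricts to genes expressed in every line,
    `"any_expressed"` to genes expressed in at least one.  All orderings are
    enumerated when there are <= 7 lines, otherwise `n_perm` seeded samples.
    Returns [(mean_k, sd_k)] for k = 1..n_lines.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    names = list(mae_sets)
    sets = {k: set(v) for k, v in mae_sets.items()}
    if expressed_sets is not None:
        expr = {k: set(v) for k, v in expressed_sets.items()}
        if universe_mode == "common":
            universe = set.intersection(*expr.values())
        elif universe_mode == "any_expressed":
            universe = set.union(*expr.values())
        else:
            raise ValueError(f"unknown universe_mode {universe_mode!r}")
        sets = {k: s & universe for k, s in sets.items()}

    if len(names) <= 7:
        orders: list[Sequence[str]] = list(permutations(names))
    else:
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(names)) for _ in range(n_perm)]

    sizes = np.zeros((len(orders), len(names)))
    for i, order in enumerate(orders):
        seen: set[str] = set()
        for k, name in enumerate(order):
            seen |= sets[name]
            sizes[i, k] = len(seen)
    return [
        (float(sizes[:, k].mean()), float(sizes[:, k].std(ddof=0)))
        for k in range(len(names))
    ]


def bivalent_overlap_fractions(
    mae_any: Iterable[str], groups: Mapping[str, str]
) -> dict[str, float]:
    """Per-group fraction of genes carrying the MAE signature in >= 1 cell
    line (and not silent); empty groups report NaN."""
    mae_any = set(mae_any)
    labels = sorted(set(groups.values()))
    out = {}
    for label in labels:
        members = [g for g, lab in groups.items() if lab == label]
        out[label] = (
            sum(g in mae_any for g in members) / len(members) if members else float("nan")
        )
    return out
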