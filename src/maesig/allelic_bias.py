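"""Allele-specific expression statistics: bias and equivalence calling.

Allelic counts at heterozygous SNPs are modeled as Bernoulli draws with
parameter p: 0 is complete bias toward allele b, 0.5 is balance, 1 complete
bias toward allele a.  A unit (gene or SNP) in a sample is called

* **biased** when the FDR-corrected exact binomial test against p = 0.5
  rejects AND the MLE shows at least 2:1 skew (p_hat outside [1/3, 2/3]);
* **unbiased** when a TOST equivalence test with the same 2:1 boundaries
  accepts (both one-sided exact binomial tests reject at alpha);
* **indeterminate** when neither test is conclusive;
* **below_threshold** when coverage is insufficient to test at all.

Clone-level calls aggregate per-clone categories: bias in any clone marks a
gene MAE-consistent, and a direction switch between clones is the hallmark
of clone-specific monoallelic expression (as opposed to imprinting or
cis-regulatory skew, which keep one direction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from maesig.genome_io import AllelicCountRecord

DEFAULT_MIN_COVERAGE_RNASEQ = 10  # gene units from whole-transcriptome RNA-seq
DEFAULT_MIN_COVERAGE_TARGETED = 100  # SNP units from targeted deep sequencing


@dataclass(frozen=True)
class BiasCall:
    """Category and statistics for one unit (gene or SNP) in one sample."""

    unit_id: str
    sample_id: str
    n_a: int
    n_b: int
    p_hat: float
    p_binom: float
    q_binom: float
    p_equiv: float
    category: str  # biased | unbiased | indeterminate | below_threshold
    direction: str  # a | b | none

    @property
    def total(self) -> int:
        return self.n_a + self.n_b


def tally_gene_counts(
    records: Sequence[AllelicCountRecord], phased: bool
) -> list[AllelicCountRecord]:
    """Sum counts over SNPs per (sample, gene, source).

    Cross-SNP summation is only meaningful when the allele assignment is
    consistent across SNPs, i.e. counts are phased (mat/pat).  Unphased
    ref/alt records are returned per SNP, unsummed.
    """
    orientations = {r.orientation for r in records}
    if len(orientations) > 1:
        raise ValueError(f"mixed orientations {sorted(orientations)} cannot be tallied")
    if not records:
        return []
    orientation = records[0].orientation
    if not phased and orientation == "ref_alt":
        return list(records)
    sums: dict[tuple[str, str, str], list[int]] = {}
    for r in records:
        key = (r.sample_id, r.gene_id, r.source)
        if key not in sums:
            sums[key] = [0, 0]
        sums[key][0] += r.count_a
        sums[key][1] += r.count_b
    return [
        AllelicCountRecord(
            sample_id=s, gene_id=g, snp_id="*", count_a=na, count_b=nb,
            orientation=orientation, source=src,
        )
        for (s, g, src), (na, nb) in sorted(sums.items())
    ]


def binomial_bias_test(n_a: int, n_b: int) -> tuple[float, float]:
    """Exact two-sided binomial test of p = 0.5 (doubled smaller tail).

    Returns (p_hat, p_two_sided) with p = min(1, 2 * min(lower tail, upper
    tail)).  The doubled-tail convention is symmetric in (n_a, n_b).
    """
    n = n_a + n_b
    if n < 1:
        raise ValueError("need at least one observed read")
    if n_a < 0 or n_b < 0:
        raise ValueError("counts must be non-negative")
    p_hat = n_a / n
    lower = stats.binom.cdf(n_a, n, 0.5)
    upper = stats.binom.sf(n_a - 1, n, 0.5)
    return p_hat, min(1.0, 2.0 * min(lower, upper))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def equivalence_test(
    n_a: int,
    n_b: int,
    low: float = 1.0 / 3.0,
    high: float = 2.0 / 3.0,
    alpha: float = 0.05,
) -> tuple[float, bool]:
    """TOST for allelic balance with exact one-sided binomial tests.

    Rejecting both H01: p >= high (via P(X <= n_a | n, high)) and
    H02: p <= low (via P(X >= n_a | n, low)) at `alpha` demonstrates the
    Bernoulli parameter lies strictly inside (low, high) — by default the
    2:1 equivalence band (1/3, 2/3).  Returns (max of the two one-sided
    p-values, equivalent?).
    """
    if not (0.0 < low < high < 1.0):
        raise ValueError("require 0 < low < high < 1")
    n = n_a + n_b
    if n < 1:
        raise ValueError("need at least one observed read")
    p_upper = stats.binom.cdf(n_a, n, high)  # small when p_hat well below high
    p_lower = stats.binom.sf(n_a - 1, n, low)  # small when p_hat well above low
    p_equiv = max(float(p_upper), float(p_lower))
    return p_equiv, bool(p_upper < alpha and p_lower < alpha)


def call_bias_category(
    n_a: int,
    n_b: int,
    q_binom: float,
    p_equiv: float,
    min_coverage: int = DEFAULT_MIN_COVERAGE_RNASEQ,
    fold: float = 2.0,
    alpha: float = 0.05,
    unit_id: str = "",
    sample_id: str = "",
) -> BiasCall:
    """Combine the bias and equivalence tests into one category.

    biased:   FDR-adjusted binomial q < alpha AND the MLE shows >= fold:1
              skew (p_hat outside [1/(fold+1), fold/(fold+1)]).
    unbiased: TOST equivalent (p_equiv < alpha on both sides, precomputed).
    The biological fold filter removes statistically significant but weak
    biases at very high coverage.
    """
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    n = n_a + n_b
    hi = fold / (fold + 1.0)
    lo = 1.0 / (fold + 1.0)
    if n < min_coverage:
        category, direction, p_hat, p_binom = "below_threshold", "none", (
            n_a / n if n else float("nan")
        ), float("nan")
        return BiasCall(unit_id, sample_id, n_a, n_b, p_hat, p_binom, q_binom, p_equiv,
                        category, direction)
    p_hat, p_binom = binomial_bias_test(n_a, n_b)
    biased = q_binom < alpha and (p_hat >= hi or p_hat <= lo)
    unbiased = p_equiv < alpha
    # With fold >= 1 and one alpha, a unit cannot satisfy both: bias needs
    # p_hat at or beyond a boundary, equivalence needs both one-sided tests
    # to place p strictly inside the band.
    assert not (biased and unbiased), "mutually exclusive categories violated"
    if biased:
        category = "biased"
        direction = "a" if n_a > n_b else "b"
    elif unbiased:
        category, direction = "unbiased", "none"
    else:
        category, direction = "indeterminate", "none"
    return BiasCall(unit_id, sample_id, n_a, n_b, p_hat, p_binom, q_binom, p_equiv,
                    category, direction)


def call_bias_batch(
    records: Sequence[AllelicCountRecord],
    min_coverage: int = DEFAULT_MIN_COVERAGE_RNASEQ,
    fold: float = 2.0,
    alpha: float = 0.05,
    unit: str = "gene",
) -> list[BiasCall]:
    """Run the full calling pipeline on one batch of count records.

    The BH correction is applied to the binomial p-values of all units in
    the batch that meet the coverage threshold (one experiment = one batch).
    `unit` selects whether the unit_id is the gene or the SNP.
    """
    keyed = [(r.gene_id if unit == "gene" else r.snp_id, r) for r in records]
    testable = [(u, r) for u, r in keyed if r.total >= min_coverage]
    pvals = [binomial_bias_test(r.count_a, r.count_b)[1] for _, r in testable]
    qvals = bh_fdr(pvals) if pvals else np.array([])
    qmap = {id(r): q for (_, r), q in zip(testable, qvals)}
    calls = []
    for u, r in keyed:
        if r.total >= min_coverage:
            p_equiv, _ = equivalence_test(
                r.count_a, r.count_b, 1.0 / (fold + 1.0), fold / (fold + 1.0), alpha
            )
            q = float(qmap[id(r)])
        else:
            p_equiv, q = float("nan"), float("nan")
        calls.append(
            call_bias_category(
                r.count_a, r.count_b, q, p_equiv, min_coverage, fold, alpha,
                unit_id=u, sample_id=r.sample_id,
            )
        )
    return calls


def gdna_filter(assay_calls: Iterable[BiasCall]) -> set[str]:
    """Units whose genomic-DNA control is unbiased wherever testable.

    gDNA should be perfectly balanced; any skew reflects amplification or
    mapping artifacts, so the assay is dropped.  Units that never reach the
    coverage threshold in gDNA are excluded with a warning.
    """
    status: dict[str, bool] = {}
    tested: set[str] = set()
    for call in assay_calls:
        if call.category == "below_threshold":
            status.setdefault(call.unit_id, True)
            continue
        tested.add(call.unit_id)
        ok = call.category == "unbiased"
        status[call.unit_id] = status.get(call.unit_id, True) and ok
    untestable = set(status) - tested
    if untestable:
        warnings.warn(
            f"{len(untestable)} unit(s) below gDNA coverage threshold in all "
            f"samples; excluded: {sorted(untestable)[:5]}..."
        )
    return {u for u in tested if status[u]}


def clone_level_mae_call(
    per_clone_calls: Mapping[str, BiasCall]
) -> tuple[str, bool]:
    """Aggregate per-clone calls for one gene.

    Returns (status, direction_switch):
    MAE-consistent when biased in >= 1 clone; unbiased when unbiased in
    >= 1 clone and biased in none; inconclusive otherwise.  The direction
    switch flag marks opposite bias directions between clones — the pattern
    that distinguishes clone-specific MAE from uniform allelic skew.
    """
    if not per_clone_calls:
        raise ValueError("need at least one clone call")
    cats = [c.category for c in per_clone_calls.values()]
    directions = {
        c.direction for c in per_clone_calls.values() if c.category == "biased"
    }
    switch = directions >= {"a", "b"}
    if "biased" in cats:
        return "MAE-consistent", switch
    if "unbiased" in cats:
        return "unbiased", False
    return "inconclusive", False
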