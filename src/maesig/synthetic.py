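"""Synthetic genomes with the statistical structure the method assumes.

The generator plants a known truth — which genes are monoallelic, which
allele each clone expresses — and emits every input the pipeline consumes:
signal tracks whose gene-body log-ratios form two clusters in the
(H3K36me3, H3K27me3) plane, an RPKM table, and per-clone allelic count
records for cDNA, gDNA and ChIP material.  Key structural features:

* MAE genes are monoallelic in any given clone with a configurable
  probability (default 0.85), the active allele chosen independently per
  (gene, clone) — so some clones of an MAE gene look biallelic;
* X-linked genes share each clone's X-inactivation direction;
* imprinted genes keep one direction across all clones;
* gDNA counts are balanced (Binomial at 0.5) regardless of class;
* H3K36me3 ChIP reads favor the active allele, H3K27me3 the silenced one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from maesig.genome_io import AllelicCountRecord, GeneModel, SignalTrack

GENE_LENGTH = 10_000
GENE_GAP = 5_000

# log2(mark/input) cluster parameters per class: (K36 mean, K27 mean), shared SD
DEFAULT_CLUSTERS: dict[str, tuple[float, float]] = {
    "BAE": (2.5, -1.0),
    "MAE": (2.0, 1.5),
    "silent": (-1.5, -1.0),
    "X-linked": (2.0, 1.5),
    "imprinted": (2.0, 1.5),
}
DEFAULT_CLUSTER_SD = 0.8


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome; `seed` is mandatory."""

    seed: int
    n_genes: int = 10_000
    mae_fraction: float = 0.13  # among expressed autosomal genes
    silent_fraction: float = 0.30
    n_clones: int = 2
    mono_prob: float = 0.85  # chance an MAE gene is monoallelic in a clone
    cdna_bias: float = 0.95  # active-allele fraction in monoallelic states
    coverage_cdna: float = 100.0
    coverage_gdna: float = 500.0
    coverage_chip: float = 100.0
    overdispersion: float = 0.0  # beta-binomial rho; 0 = pure binomial
    n_x_linked: int = 50
    n_imprinted: int = 20
    cluster_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTERS)
    )
    cluster_sd: float = DEFAULT_CLUSTER_SD

    def __post_init__(self) -> None:
        for name, frac in (("mae_fraction", self.mae_fraction),
                           ("silent_fraction", self.silent_fraction),
                           ("mono_prob", self.mono_prob),
                           ("cdna_bias", self.cdna_bias)):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, cov in (("coverage_cdna", self.coverage_cdna),
                          ("coverage_gdna", self.coverage_gdna),
                          ("coverage_chip", self.coverage_chip)):
            if cov <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_clones < 1:
            raise ValueError("need at least one clone")
        if not 0.0 <= self.overdispersion < 1.0:
            raise ValueError("overdispersion must be in [0, 1)")


def _allele_columns(n_clones: int) -> list[str]:
    return [f"clone{i + 1}_allele" for i in range(n_clones)]


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Gene table with class, RPKM, and per-clone active allele.

    Classes: silent / BAE / MAE on the autosome "chrS", plus X-linked genes
    on "chrX" and imprinted genes on the autosome.  Active-allele columns
    hold "a", "b" or "both" per clone.
    """
    rng = np.random.default_rng(config.seed)
    n_auto = config.n_genes - config.n_x_linked
    if n_auto <= config.n_imprinted:
        raise ValueError("n_genes too small for the requested special gene counts")

    classes = np.empty(config.n_genes, dtype=object)
    silent = rng.random(n_auto) < config.silent_fraction
    mae = ~silent & (rng.random(n_auto) < config.mae_fraction)
    classes[:n_auto] = np.where(silent, "silent", np.where(mae, "MAE", "BAE"))
    # imprinted genes replace expressed autosomal genes
    expressed_idx = np.nonzero(~silent)[0]
    imprint_idx = rng.choice(expressed_idx, size=config.n_imprinted, replace=False)
    classes[imprint_idx] = "imprinted"
    classes[n_auto:] = "X-linked"

    rpkm = np.empty(config.n_genes)
    is_silent = classes == "silent"
    rpkm[~is_silent] = 10.0 ** rng.normal(0.8, 0.7, size=int((~is_silent).sum()))
    rpkm[is_silent] = np.minimum(
        10.0 ** rng.normal(-2.0, 0.5, size=int(is_silent.sum())), 0.099
    )

    xci = rng.choice(["a", "b"], size=config.n_clones)  # per-clone XCI direction
    imprint_dir = {
        i: rng.choice(["a", "b"]) for i in range(config.n_genes) if classes[i] == "imprinted"
    }
    alleles = np.full((config.n_genes, config.n_clones), "both", dtype=object)
    for i in range(config.n_genes):
        cls = classes[i]
        if cls == "MAE":
            for c in range(config.n_clones):
                if rng.random() < config.mono_prob:
                    alleles[i, c] = rng.choice(["a", "b"])
        elif cls == "X-linked":
            alleles[i, :] = xci
        elif cls == "imprinted":
            alleles[i, :] = imprint_dir[i]

    chroms = ["chrS"] * n_auto + ["chrX"] * config.n_x_linked
    df = pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(config.n_genes)],
            "chrom": chroms,
            "class": classes,
            "rpkm": rpkm,
        }
    )
    for c, col in enumerate(_allele_columns(config.n_clones)):
        df[col] = alleles[:, c]
    return df.set_index("gene_id")


def simulate_tracks(
    truth: pd.DataFrame, config: SimulationConfig
) -> tuple[dict[str, SignalTrack], SignalTrack, list[GeneModel]]:
    """Constant-step gene-body signal tracks plus matching gene models.

    The input/WCE track is uniform at 1.0, so with 10 kb gene bodies the
    recomputed log2(mark/input) feature of a gene is (up to the pseudocount)
    the Gaussian draw from its class cluster.
    """
    rng = np.random.default_rng(config.seed + 1)
    genes: list[GeneModel] = []
    offsets: dict[str, int] = {}
    for gene_id, row in truth.iterrows():
        pos = offsets.get(row["chrom"], GENE_GAP)
        genes.append(GeneModel(str(gene_id), row["chrom"], "+", pos, pos + GENE_LENGTH))
        offsets[row["chrom"]] = pos + GENE_LENGTH + GENE_GAP

    mark_steps: dict[str, list[tuple[str, int, int, float]]] = {
        "H3K36me3": [],
        "H3K27me3": [],
    }
    for gene, (_, row) in zip(genes, truth.iterrows()):
        mu36, mu27 = config.cluster_means[row["class"]]
        if row["class"] == "silent":  # bimodal K27: poised vs fully inert
            mu27 = 1.0 if rng.random() < 0.5 else -1.0
        z36 = rng.normal(mu36, config.cluster_sd)
        z27 = rng.normal(mu27, config.cluster_sd)
        mark_steps["H3K36me3"].append((gene.chrom, gene.start, gene.end, 2.0 ** z36))
        mark_steps["H3K27me3"].append((gene.chrom, gene.start, gene.end, 2.0 ** z27))

    input_steps = [
        (chrom, 0, end + GENE_GAP, 1.0) for chrom, end in offsets.items()
    ]
    tracks = {mark: SignalTrack(steps) for mark, steps in mark_steps.items()}
    return tracks, SignalTrack(input_steps), genes


def _split_counts(
    rng: np.random.Generator, n: int, p: float, rho: float
) -> tuple[int, int]:
    if n == 0:
        return 0, 0
    if rho > 0:
        conc = (1.0 - rho) / rho
        p = rng.beta(p * conc, (1.0 - p) * conc)
    a = int(rng.binomial(n, p))
    return a, n - a


def simulate_counts(
    truth: pd.DataFrame, config: SimulationConfig
) -> list[AllelicCountRecord]:
    """Allelic count records per clone for cDNA, gDNA and both ChIP marks.

    Coverage is Poisson with mean proportional to RPKM (normalized so that
    the average expressed gene hits the configured mean); gDNA coverage is
    expression-independent.  Allele a is the reference allele; the split is
    Binomial at 0.5 except in monoallelic states, where cDNA and H3K36me3
    favor the active allele at `cdna_bias` and H3K27me3 mirrors it toward
    the silenced allele.
    """
    rng = np.random.default_rng(config.seed + 2)
    allele_cols = _allele_columns(config.n_clones)
    expressed = truth["rpkm"] >= 0.1
    mean_rpkm = float(truth.loc[expressed, "rpkm"].mean()) if expressed.any() else 1.0

    records: list[AllelicCountRecord] = []
    for gene_id, row in truth.iterrows():
        scale = row["rpkm"] / mean_rpkm
        for c, col in enumerate(allele_cols):
            clone = f"clone{c + 1}"
            active = row[col]
            mono = active in ("a", "b")
            p_active = config.cdna_bias if mono else 0.5
            for source, mean_cov, p_ref in (
                ("cDNA", config.coverage_cdna * scale,
                 p_active if active != "b" else 1.0 - p_active),
                ("gDNA", config.coverage_gdna, 0.5),
                ("chip_k36", config.coverage_chip * scale,
                 p_active if active != "b" else 1.0 - p_active),
                ("chip_k27", config.coverage_chip * scale,
                 (1.0 - p_active) if active != "b" else p_active),
            ):
                n = int(rng.poisson(mean_cov))
                if n == 0:
                    continue
                a, b = _split_counts(rng, n, p_ref, config.overdispersion)
                records.append(
                    AllelicCountRecord(
                        sample_id=clone,
                        gene_id=str(gene_id),
                        snp_id=f"{gene_id}_snp1",
                        count_a=a,
                        count_b=b,
                        orientation="ref_alt",
                        source=source,
                    )
                )
    return records
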