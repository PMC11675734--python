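"""Synthetic two-group, multi-breed genotype panels with planted selection.

Allele frequencies follow a hierarchical Balding-Nichols model: an ancestral
frequency p drawn uniformly, a group-level frequency drawn from
Beta(p(1-F_g)/F_g, (1-p)(1-F_g)/F_g) around it, and a breed-level frequency
drawn the same way around the group frequency with drift F_b.  Divergent
selection is planted as localized clusters of SNPs whose two group
frequencies are pushed apart by +/- delta/2 (clipped to [0.01, 0.99])
*before* breed-level drift, so the signal is shared by all breeds of a group
— within-group breed contrasts see only drift at those markers.

Genotypes are Binomial(2, p_breed) per animal and SNP, with uniform random
missingness.  SNPs are evenly spaced along each chromosome.  Everything is
reproducible from the config seed.

Linkage disequilibrium is not simulated: a planted cluster is a run of
independently divergent SNPs standing in for a swept haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeDataset


@dataclass
class SelectedCluster:
    """A localized run of SNPs with divergent group allele frequencies."""

    chromosome: int
    center_snp_index: int  # 0-based index within the chromosome
    width_snps: int
    divergence_delta: float

    def __post_init__(self) -> None:
        if self.width_snps < 1:
            raise ValueError("cluster width must be >= 1")
        if not 0.0 <= self.divergence_delta <= 1.0:
            raise ValueError("divergence_delta must lie in [0, 1]")

    def span(self) -> tuple[int, int]:
        """Half-open (start, stop) SNP-index span within the chromosome."""
        start = self.center_snp_index - self.width_snps // 2
        return start, start + self.width_snps


@dataclass
class SimConfig:
    """Study-shape parameters for the generator.

    Defaults are the desk-scale analogue of a two-group multi-breed SNP-chip
    panel: 2 groups x 3 breeds x 30 animals, 5 chromosomes x 2,000 evenly
    spaced SNPs, mild hierarchical drift (F_group = 0.03, F_breed = 0.02),
    1% missing genotypes and 3 planted clusters of 20 SNPs diverged by
    delta = 0.6 between the groups.
    """

    breeds: list[tuple[str, str, int]] = field(default_factory=lambda: [
        ("BR1", "MEAT", 30), ("BR2", "MEAT", 30), ("BR3", "MEAT", 30),
        ("BR4", "MILK", 30), ("BR5", "MILK", 30), ("BR6", "MILK", 30),
    ])
    n_chromosomes: int = 5
    snps_per_chromosome: int = 2000
    chromosome_length_bp: int = 100_000_000
    ancestral_freq_range: tuple[float, float] = (0.10, 0.90)
    f_group: float = 0.03
    f_breed: float = 0.02
    selected_clusters: list[SelectedCluster] = field(default_factory=list)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_group < 1.0 and 0.0 < self.f_breed < 1.0):
            raise ValueError("drift parameters must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for c in self.selected_clusters:
            if not 1 <= c.chromosome <= self.n_chromosomes:
                raise ValueError(f"cluster chromosome {c.chromosome} out of range")
            lo, hi = c.span()
            if lo < 0 or hi > self.snps_per_chromosome:
                raise ValueError("cluster span exceeds chromosome bounds")
        _selection_mask(self)  # validates that spans are disjoint

    @property
    def group_labels(self) -> list[str]:
        out: list[str] = []
        for _, g, _ in self.breeds:
            if g not in out:
                out.append(g)
        return sorted(out)

    @property
    def n_snps(self) -> int:
        return self.n_chromosomes * self.snps_per_chromosome


def default_clusters(config_like: SimConfig | None = None,
                     delta: float = 0.6, width: int = 20) -> list[SelectedCluster]:
    """Three planted clusters on distinct chromosomes, away from the ends."""
    m = config_like.snps_per_chromosome if config_like else 2000
    return [
        SelectedCluster(1, m // 4, width, delta),
        SelectedCluster(2, m // 2, width, delta),
        SelectedCluster(3, (3 * m) // 4, width, delta),
    ]


@dataclass
class TruthTable:
    """Ground truth for planted selection, for recovery scoring."""

    clusters: pd.DataFrame  # chrom, start_idx, stop_idx (half-open), delta
    selected: np.ndarray    # bool per SNP, aligned to the dataset's map

    def selected_snp_ids(self, snps: pd.DataFrame) -> set[str]:
        return set(snps.loc[self.selected, "snp_id"])

    def write_tsv(self, path) -> None:
        self.clusters.to_csv(path, sep="\t", index=False)


def _beta_drift(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols draw around p with drift coefficient f."""
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-12),
                    np.maximum((1.0 - p) * scale, 1e-12))


def sample_frequencies(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the (ancestral, per-group, per-breed) allele-frequency hierarchy.

    Returns ``(p_anc (m,), p_group (n_groups, m), p_breed (n_breeds, m))``
    with groups ordered by sorted label and breeds in config order.  For
    planted SNPs the first group is shifted up by delta/2 and the second
    down by delta/2 (clipped to [0.01, 0.99]) before breed-level drift.
    """
    m = config.n_snps
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=m)

    groups = config.group_labels
    p_group = np.stack([_beta_drift(p_anc, config.f_group, rng)
                        for _ in groups])

    sel_mask, deltas = _selection_mask(config)
    if sel_mask.any():
        if len(groups) < 2:
            raise ValueError("planted divergence needs at least 2 groups")
        p_group[0, sel_mask] = np.clip(
            p_group[0, sel_mask] + deltas[sel_mask] / 2.0, 0.01, 0.99)
        p_group[1, sel_mask] = np.clip(
            p_group[1, sel_mask] - deltas[sel_mask] / 2.0, 0.01, 0.99)

    gidx = {g: i for i, g in enumerate(groups)}
    p_breed = np.stack([
        _beta_drift(p_group[gidx[g]], config.f_breed, rng)
        for _, g, _ in config.breeds
    ])
    return p_anc, p_group, p_breed


def _selection_mask(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    mask = np.zeros(config.n_snps, dtype=bool)
    deltas = np.zeros(config.n_snps)
    spans: list[tuple[int, int, int]] = []
    for c in config.selected_clusters:
        lo, hi = c.span()
        for pc, plo, phi in spans:
            if pc == c.chromosome and lo < phi and plo < hi:
                raise ValueError("planted cluster spans overlap")
        spans.append((c.chromosome, lo, hi))
        off = (c.chromosome - 1) * config.snps_per_chromosome
        mask[off + lo:off + hi] = True
        deltas[off + lo:off + hi] = c.divergence_delta
    return mask, deltas


def generate(config: SimConfig) -> tuple[GenotypeDataset, TruthTable]:
    """Simulate the genotype panel and its ground-truth table."""
    rng = np.random.default_rng(config.seed)
    _, _, p_breed = sample_frequencies(config, rng)

    m = config.n_snps
    rows_geno = []
    animal_rows = []
    counter = 0
    for b, (breed, group, n_b) in enumerate(config.breeds):
        g = rng.binomial(2, p_breed[b], size=(n_b, m)).astype(np.int8)
        rows_geno.append(g)
        for _ in range(n_b):
            counter += 1
            animal_rows.append((f"{breed}_{counter:04d}", breed, group))
    geno = np.vstack(rows_geno)
    if config.missing_rate > 0:
        miss = rng.random(geno.shape) < config.missing_rate
        geno[miss] = MISSING

    spacing = config.chromosome_length_bp // (config.snps_per_chromosome + 1)
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1),
                       config.snps_per_chromosome)
    pos_in_chr = np.tile(
        (np.arange(config.snps_per_chromosome) + 1) * spacing,
        config.n_chromosomes)
    snps = pd.DataFrame({
        "snp_id": [f"snp_c{c}_{i:05d}"
                   for c, i in zip(chroms, pos_in_chr // spacing)],
        "chrom": chroms.astype(int),
        "pos": pos_in_chr.astype(int),
        "a1": "A",
        "a2": "B",
    })
    animals = pd.DataFrame(animal_rows, columns=["animal_id", "breed", "group"])
    ds = GenotypeDataset(geno, animals, snps)

    sel_mask, _ = _selection_mask(config)
    cl = pd.DataFrame(
        [(c.chromosome, *c.span(), c.divergence_delta)
         for c in config.selected_clusters],
        columns=["chrom", "start_idx", "stop_idx", "delta"],
    )
    return ds, TruthTable(clusters=cl, selected=sel_mask)
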