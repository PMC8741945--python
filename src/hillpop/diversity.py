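"""Individual-level Hill-number SNP diversity and similarity profiles.

An *assemblage* is one individual's (or one pooled population's)
distribution of SNP abundance across the genes of one autosome. Its alpha
diversity profile is the Hill number

    qD = (sum_g p_g^q)^(1/(1-q))          (q != 1)
    1D = exp(-sum_g p_g ln p_g)           (q = 1, the limit)

over the gene relative abundances p_g, evaluated on a grid of diversity
orders q. qD is the effective number of genes: it equals gene richness at
q = 0 and down-weights rare genes increasingly as q grows.

Multiple assemblages decompose multiplicatively, gamma = alpha x beta, with
equal assemblage weights: gamma is the Hill number of the mean relative
abundance vector, alpha the corresponding within-assemblage average, and
beta in [1, N] measures compositional differentiation. Four similarity
transforms map beta to [0, 1]: local overlap (Cq), regional overlap (Uq),
homogeneity (Sq) and turnover complement (Vq); all equal 1 for identical
assemblages and 0 at complete turnover.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import MISSING, GeneIntervals, GenotypeMatrix, PopulationMap

DEFAULT_ALPHA_GRID = (0.0, 1.0, 2.0, 3.0, 4.0)
DEFAULT_BETA_GRID = (1.0, 2.0, 3.0, 4.0)


@dataclass
class AbundanceProfile:
    """Per-gene SNP abundance of one owner on one autosome."""

    owner: str
    autosome: str
    counts: np.ndarray  # non-negative integers aligned to the gene list
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("abundances must be non-negative")
        if len(self.counts) != len(self.gene_ids):
            raise ValueError("counts not aligned to gene list")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def usable(self) -> bool:
        return self.total > 0

    @property
    def relative(self) -> np.ndarray:
        if not self.usable:
            raise ValueError(f"profile for {self.owner!r} has zero total abundance")
        return self.counts / self.counts.sum()


@dataclass
class DiversityProfile:
    owner: str
    autosome: str
    q_grid: np.ndarray
    qD: np.ndarray


@dataclass
class PartitionResult:
    q: float
    n_assemblages: int
    gamma: float
    alpha: float
    beta: float  # gamma / alpha, in [1, N]


@dataclass
class SimilarityIndices:
    Cq: float  # local overlap
    Uq: float  # regional overlap
    Sq: float  # homogeneity
    Vq: float  # turnover complement


def hill_number(p: np.ndarray, q: float) -> float:
    """Hill number of order q for a relative-abundance vector.

    ``p`` must sum to 1 (tolerance 1e-9); zero entries are dropped. The
    q = 1 case uses the exponential-Shannon limit.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"relative abundances sum to {p.sum()}, not 1")
    if q < 0:
        raise ValueError("diversity order q must be >= 0")
    p = p[p > 0]
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def snp_abundance(
    genotypes: GenotypeMatrix,
    gene_intervals: GeneIntervals,
    owner: str | list[str],
    autosome: str,
    counting: str = "allele",
) -> AbundanceProfile:
    """Count SNP abundance per gene for one individual or a pooled set.

    ``counting="allele"`` sums alternate-allele copies (0/1/2 per site);
    ``counting="presence"`` scores each site 1 per individual carrying at
    least one alternate allele. Missing genotypes contribute 0; sites
    outside every gene interval are ignored. Pooled owners sum member
    contributions elementwise.
    """
    if counting not in ("allele", "presence"):
        raise ValueError("counting must be 'allele' or 'presence'")
    members = [owner] if isinstance(owner, str) else list(owner)
    rows = [genotypes.samples.index(m) for m in members]
    genes = gene_intervals.for_chrom(autosome)
    if genes.empty:
        raise ValueError(f"no gene intervals on {autosome}")
    on_chrom = genotypes.sites["chrom"].to_numpy() == autosome
    pos0 = genotypes.sites["pos"].to_numpy()[on_chrom] - 1  # 0-based
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    gene_of_site = np.searchsorted(starts, pos0, side="right") - 1
    inside = (gene_of_site >= 0) & (pos0 < ends[np.clip(gene_of_site, 0, None)])

    d = genotypes.dosages[np.ix_(rows, np.flatnonzero(on_chrom))].astype(np.int64)
    d[d == MISSING] = 0
    if counting == "presence":
        d = (d > 0).astype(np.int64)
    site_totals = d.sum(axis=0)
    counts = np.zeros(len(genes), dtype=np.int64)
    np.add.at(counts, gene_of_site[inside], site_totals[inside])
    name = owner if isinstance(owner, str) else "+".join(members)
    return AbundanceProfile(
        owner=name, autosome=autosome, counts=counts, gene_ids=list(genes["gene_id"])
    )


def alpha_profile(
    profile: AbundanceProfile, q_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
) -> DiversityProfile:
    """Hill-number diversity profile of one assemblage over a q grid."""
    p = profile.relative
    qd = np.array([hill_number(p, q) for q in q_grid])
    return DiversityProfile(
        owner=profile.owner,
        autosome=profile.autosome,
        q_grid=np.asarray(q_grid, dtype=float),
        qD=qd,
    )


def partition(assemblages: list[AbundanceProfile], q: float) -> PartitionResult:
    """Multiplicative gamma/alpha/beta decomposition with equal weights.

    gamma is the Hill number of the pooled (mean relative-abundance)
    assemblage; alpha is the equal-weight within-assemblage component of
    the same order, so that beta = gamma/alpha lies in [1, N].
    """
    n = len(assemblages)
    if n < 2:
        raise ValueError("partition needs at least two assemblages")
    gene_ids = assemblages[0].gene_ids
    autosome = assemblages[0].autosome
    for a in assemblages:
        if a.gene_ids != gene_ids or a.autosome != autosome:
            raise ValueError("assemblages must share one autosome and gene list")
    rel = np.vstack([a.relative for a in assemblages])  # raises if unusable
    gamma = hill_number(rel.mean(axis=0), q)
    z = rel / n  # joint weights p_kg / N
    z = z[z > 0]
    if q == 1.0:
        alpha = float(np.exp(-np.sum(z * np.log(z))) / n)
    else:
        alpha = float(np.sum(z**q) ** (1.0 / (1.0 - q)) / n)
    beta = gamma / alpha
    if not (1.0 - 1e-9 <= beta <= n + 1e-9):
        raise AssertionError(f"beta {beta} outside [1, {n}]")
    beta = float(np.clip(beta, 1.0, n))
    # snap round-off at the boundaries so downstream indices hit 1/0 exactly
    if abs(beta - 1.0) < 1e-12:
        beta = 1.0
    elif abs(beta - n) < 1e-12:
        beta = float(n)
    return PartitionResult(q=q, n_assemblages=n, gamma=gamma, alpha=alpha, beta=beta)


def similarity_indices(beta: float, n: int, q: float) -> SimilarityIndices:
    """The four Hill-number similarity transforms of beta.

    Cq and Uq share the q = 1 limit 1 - ln(beta)/ln(N); Sq and Vq do not
    depend on q. Values are clipped to [0, 1] only against sub-1e-9
    round-off overshoot.
    """
    if n < 2:
        raise ValueError("similarity needs N >= 2 assemblages")
    if not (1.0 - 1e-9 <= beta <= n + 1e-9):
        raise ValueError(f"beta {beta} outside [1, {n}]")
    beta = float(np.clip(beta, 1.0, n))
    if q == 1.0:
        cq = uq = 1.0 - np.log(beta) / np.log(n)
    else:
        cq = ((1.0 / beta) ** (q - 1.0) - (1.0 / n) ** (q - 1.0)) / (
            1.0 - (1.0 / n) ** (q - 1.0)
        )
        uq = ((1.0 / beta) ** (1.0 - q) - (1.0 / n) ** (1.0 - q)) / (
            1.0 - (1.0 / n) ** (1.0 - q)
        )
    sq = (1.0 / beta - 1.0 / n) / (1.0 - 1.0 / n)
    vq = 1.0 - (beta - 1.0) / (n - 1.0)

    def _clip(x: float) -> float:
        if -1e-9 < x < 0.0:
            return 0.0
        if 1.0 < x < 1.0 + 1e-9:
            return 1.0
        return float(x)

    return SimilarityIndices(Cq=_clip(cq), Uq=_clip(uq), Sq=_clip(sq), Vq=_clip(vq))


def _autosomes(genotypes: GenotypeMatrix) -> list[str]:
    return list(dict.fromkeys(genotypes.sites["chrom"]))


def alpha_table(
    genotypes: GenotypeMatrix,
    gene_intervals: GeneIntervals,
    q_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    counting: str = "allele",
) -> pd.DataFrame:
    """Per-individual alpha profiles, one row per (sample, autosome, q).

    Individuals with zero alternate alleles on an autosome are skipped for
    that autosome (unusable assemblage).
    """
    rows = []
    for autosome in _autosomes(genotypes):
        for sample in genotypes.samples:
            prof = snp_abundance(
                genotypes, gene_intervals, sample, autosome, counting
            )
            if not prof.usable:
                continue
            dp = alpha_profile(prof, q_grid)
            for q, qd in zip(dp.q_grid, dp.qD):
                rows.append((sample, autosome, q, qd))
    return pd.DataFrame(rows, columns=["sample", "autosome", "q", "alpha"])


def alpha_mean_table(alpha: pd.DataFrame) -> pd.DataFrame:
    """Autosome-averaged alpha per individual per q."""
    return (
        alpha.groupby(["sample", "q"], as_index=False)["alpha"]
        .mean()
        .rename(columns={"alpha": "alpha_mean"})
    )


def beta_table(
    genotypes: GenotypeMatrix,
    gene_intervals: GeneIntervals,
    pop_map: PopulationMap,
    q_grid: tuple[float, ...] = DEFAULT_BETA_GRID,
    mode: str = "between",
    level: str = "population",
    counting: str = "allele",
    assemblage: str = "pooled",
) -> pd.DataFrame:
    """Beta diversity and similarity indices per group comparison.

    ``mode="between"`` compares every unordered pair of groups: with
    ``assemblage="pooled"`` (the default) each group contributes one pooled
    profile (N = 2); with ``assemblage="individuals"`` every member is its
    own assemblage. ``mode="within"`` uses one group's members as the
    assemblages (N = group size). ``level`` groups samples by "population"
    or "species". One row per (comparison, autosome, q).
    """
    if mode not in ("between", "within"):
        raise ValueError("mode must be 'between' or 'within'")
    if level == "population":
        groups = {g: pop_map.members(g) for g in pop_map.populations}
    elif level == "species":
        groups = {g: pop_map.species_members(g) for g in pop_map.species}
    else:
        raise ValueError("level must be 'population' or 'species'")
    groups = {
        g: [m for m in members if m in genotypes.samples]
        for g, members in groups.items()
    }
    rows = []
    for autosome in _autosomes(genotypes):
        profiles = {
            g: [
                p
                for m in members
                if (
                    p := snp_abundance(
                        genotypes, gene_intervals, m, autosome, counting
                    )
                ).usable
            ]
            for g, members in groups.items()
        }
        pooled = {
            g: snp_abundance(genotypes, gene_intervals, members, autosome, counting)
            for g, members in groups.items()
            if members
        }
        if mode == "within":
            for g, profs in profiles.items():
                if len(profs) < 2:
                    continue
                for q in q_grid:
                    part = partition(profs, q)
                    sim = similarity_indices(part.beta, part.n_assemblages, q)
                    rows.append(
                        (g, autosome, q, part.n_assemblages, part.gamma,
                         part.alpha, part.beta, sim.Cq, sim.Uq, sim.Sq, sim.Vq)
                    )
        else:
            for ga, gb in combinations([g for g in groups if groups[g]], 2):
                if assemblage == "pooled":
                    profs = [pooled[ga], pooled[gb]]
                elif assemblage == "individuals":
                    profs = profiles[ga] + profiles[gb]
                else:
                    raise ValueError("assemblage must be 'pooled' or 'individuals'")
                if len(profs) < 2 or not all(p.usable for p in profs):
                    continue
                for q in q_grid:
                    part = partition(profs, q)
                    sim = similarity_indices(part.beta, part.n_assemblages, q)
                    rows.append(
                        (f"{ga}|{gb}", autosome, q, part.n_assemblages, part.gamma,
                         part.alpha, part.beta, sim.Cq, sim.Uq, sim.Sq, sim.Vq)
                    )
    return pd.DataFrame(
        rows,
        columns=["comparison", "autosome", "q", "N", "gamma", "alpha", "beta",
                 "Cq", "Uq", "Sq", "Vq"],
    )


def beta_mean_table(beta: pd.DataFrame) -> pd.DataFrame:
    """Autosome-averaged beta and similarity indices per comparison per q."""
    return beta.groupby(["comparison", "q"], as_index=False)[
        ["beta", "Cq", "Uq", "Sq", "Vq"]
    ].mean()


def diversity_analysis(
    genotypes: GenotypeMatrix,
    gene_intervals: GeneIntervals,
    pop_map: PopulationMap,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID,
    level: str = "population",
    counting: str = "allele",
) -> dict[str, pd.DataFrame]:
    """The full diversity stage: per-autosome and autosome-averaged alpha,
    within-group and between-group (pooled, N = 2) beta and similarity."""
    alpha = alpha_table(genotypes, gene_intervals, alpha_grid, counting)
    within = beta_table(
        genotypes, gene_intervals, pop_map, beta_grid, "within", level, counting
    )
    between = beta_table(
        genotypes, gene_intervals, pop_map, beta_grid, "between", level, counting
    )
    return {
        "alpha": alpha,
        "alpha_mean": alpha_mean_table(alpha),
        "beta_within": within,
        "beta_within_mean": beta_mean_table(within) if len(within) else within,
        "beta_between": between,
        "beta_between_mean": beta_mean_table(between) if len(between) else between,
    }
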