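"""Synthetic two-species SNP cohort generator.

Emulates the statistical structure the downstream analyses assume: two
strongly diverged species (a one-humped and a two-humped camel analogue),
weakly diverged populations within species, planted duplicate and
parent-offspring sample pairs, missing genotypes, and per-site quality
annotations with a planted failing fraction per annotation.

Allele frequencies follow a hierarchical Balding-Nichols model: an
ancestral frequency ``p`` drawn uniformly from a minor-allele-frequency
window, a species frequency drawn ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with the
species drift coefficient ``F``, and population frequencies drawn the same
way around the species frequency. Genotypes are binomial(2, p_k) within a
population, so Hardy-Weinberg equilibrium holds in expectation.

Every draw is controlled by a single integer seed, and regeneration with
the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GeneIntervals, GenotypeMatrix, PopulationMap

# Distributions used for per-site quality annotations. Passing sites draw
# from distributions comfortably inside the pass region; planted failing
# sites draw beyond the corresponding hard-filter threshold, so filter truth
# is exact by construction. Values are rounded to 4 decimals before use so a
# VCF round-trip is lossless.
ANNOTATION_DISTRIBUTIONS: dict[str, dict] = {
    "QD": {"pass": ("normal", 25.0, 3.0, 10.0, 40.0), "fail": ("uniform", 0.1, 1.9)},
    "MQ": {"pass": ("normal", 55.0, 2.5, 45.0, 65.0), "fail": ("uniform", 20.0, 39.5)},
    "QUAL": {"pass": ("normal", 500.0, 100.0, 40.0, 900.0), "fail": ("uniform", 1.0, 29.5)},
    "FS": {"pass": ("uniform", 0.0, 20.0), "fail": ("uniform", 61.0, 200.0)},
    "MQRankSum": {"pass": ("normal", 0.0, 1.0, -5.0, 5.0), "fail": ("uniform", -20.0, -12.6)},
    "ReadPosRankSum": {"pass": ("normal", 0.0, 1.0, -5.0, 5.0), "fail": ("uniform", -15.0, -8.1)},
    # DP is the per-site mean depth across samples; planted failures are
    # low-coverage sites below the fixed two-read floor, which the
    # data-dependent upper bound can never rescue.
    "DP": {"pass": ("normal", 20.0, 2.5, 10.0, 30.0), "fail": ("uniform", 0.2, 1.5)},
}


@dataclass
class DivergenceModel:
    """Two-level population tree with per-branch drift coefficients.

    ``tree`` groups population names under species names. ``f_species`` and
    ``f_population`` hold the Balding-Nichols drift coefficient for the
    species branch and each population branch; ``F = 0`` means no drift
    (frequencies copied exactly) and ``F = 1`` means instant fixation.
    """

    tree: dict[str, list[str]]
    f_species: dict[str, float]
    f_population: dict[str, float]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        pops = [p for members in self.tree.values() for p in members]
        if len(pops) != len(set(pops)):
            raise ValueError("each population must belong to exactly one species")
        for name, f in {**self.f_species, **self.f_population}.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"drift coefficient for {name!r} outside [0, 1]: {f}")
        for sp in self.tree:
            if sp not in self.f_species:
                raise ValueError(f"missing f_species for {sp!r}")
        for p in pops:
            if p not in self.f_population:
                raise ValueError(f"missing f_population for {p!r}")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")

    @property
    def populations(self) -> list[str]:
        return [p for members in self.tree.values() for p in members]

    def species_of(self, population: str) -> str:
        for sp, members in self.tree.items():
            if population in members:
                return sp
        raise KeyError(population)


@dataclass
class PedigreePlan:
    """Planted relationships: clones and parent-offspring pairs.

    ``duplicates`` lists ``(source, clone)`` sample IDs: the clone is a new
    sample whose genotypes copy the source exactly (before missingness).
    ``parent_offspring`` lists ``(parent, child)``: the child receives one
    allele drawn uniformly from the parent's two and one allele drawn from
    the parent population's frequency. All other samples are unrelated.
    """

    duplicates: list[tuple[str, str]] = field(default_factory=list)
    parent_offspring: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        new = [c for _, c in self.duplicates] + [c for _, c in self.parent_offspring]
        involved = [s for pair in self.duplicates + self.parent_offspring for s in pair]
        if len(set(involved)) != len(involved):
            raise ValueError("a sample may appear in at most one planted relationship")
        self._new_samples = new


@dataclass
class SimulatedCohort:
    """A fully specified synthetic cohort plus its ground truth."""

    genotypes: GenotypeMatrix
    gene_intervals: GeneIntervals
    pop_map: PopulationMap
    truth_frequencies: pd.DataFrame
    truth_relationships: pd.DataFrame  # sample_i, sample_j, relationship
    truth_qc_failures: pd.DataFrame  # site index x annotation booleans
    seed: int


def _beta_drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """One Balding-Nichols drift step: Beta(p(1-F)/F, (1-p)(1-F)/F) per site."""
    if f == 0.0:
        return p.copy()
    if f == 1.0:
        # Beta degenerates to a Bernoulli point mass at 0 or 1.
        return rng.random(p.shape) < p
    scale = (1.0 - f) / f
    out = rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))
    return np.clip(out, 0.0, 1.0)


def simulate_frequencies(
    model: DivergenceModel,
    n_sites: int,
    n_autosomes: int = 1,
    seed: int = 0,
    spacing_bp: int = 1000,
) -> pd.DataFrame:
    """Draw ancestral, species and population allele frequencies.

    Returns a table with one row per site: ``chrom``, ``pos`` (1-based,
    evenly spaced ``spacing_bp`` apart), ``p_ancestral``, one
    ``p_species:<name>`` column per species and one ``p_pop:<name>`` column
    per population. Deterministic given ``seed``.
    """
    if n_sites < 1 or n_autosomes < 1:
        raise ValueError("n_sites and n_autosomes must be >= 1")
    rng = np.random.default_rng(seed)
    total = n_sites * n_autosomes
    lo, hi = model.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=total)
    cols = {
        "chrom": np.repeat([f"chr{i + 1}" for i in range(n_autosomes)], n_sites),
        "pos": np.tile(np.arange(1, n_sites + 1) * spacing_bp, n_autosomes),
        "p_ancestral": p_anc,
    }
    for sp, pops in model.tree.items():
        p_sp = _beta_drift(rng, p_anc, model.f_species[sp]).astype(float)
        cols[f"p_species:{sp}"] = p_sp
        for pop in pops:
            cols[f"p_pop:{pop}"] = _beta_drift(
                rng, p_sp, model.f_population[pop]
            ).astype(float)
    return pd.DataFrame(cols)


def _draw_annotation(
    rng: np.random.Generator, spec: tuple, size: int
) -> np.ndarray:
    kind = spec[0]
    if kind == "normal":
        _, mean, sd, lo, hi = spec
        return np.clip(rng.normal(mean, sd, size), lo, hi)
    _, lo, hi = spec
    return rng.uniform(lo, hi, size)


def simulate_cohort(
    freq_truth: pd.DataFrame,
    pop_sizes: dict[str, int],
    model: DivergenceModel,
    plan: PedigreePlan | None = None,
    missing_rate: float = 0.0,
    qc_failure_spec: dict[str, float] | None = None,
    seed: int = 0,
    gene_length_bp: int = 50_000,
    ld_block_size: int = 1,
    ld_flip_rate: float = 0.05,
) -> SimulatedCohort:
    """Draw genotypes, planted relatives, annotations and truth labels.

    Unrelated samples draw binomial(2, p_k) per site from their population
    frequency, i.e. Hardy-Weinberg proportions within population. When
    ``ld_block_size > 1``, consecutive sites on an autosome form blocks in
    which each sample's genotype copies the block's first site with a small
    per-genotype flip probability -- an artificial linkage-disequilibrium
    structure used to exercise LD pruning.

    ``qc_failure_spec`` maps annotation name -> fraction of sites planted to
    fail the corresponding hard filter; truth labels record every planted
    failure exactly.
    """
    plan = plan or PedigreePlan()
    qc_failure_spec = qc_failure_spec or {}
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    for pop in pop_sizes:
        if pop not in model.populations:
            raise ValueError(f"unknown population {pop!r} in pop_sizes")
        if pop_sizes[pop] < 1:
            raise ValueError("each population needs at least one sample")

    rng = np.random.default_rng(seed)
    n_sites = len(freq_truth)

    # Base (unrelated) samples per population.
    samples: list[str] = []
    rows: list[np.ndarray] = []
    pop_of: dict[str, str] = {}
    for pop, n in pop_sizes.items():
        p_k = freq_truth[f"p_pop:{pop}"].to_numpy()
        for i in range(n):
            name = f"{pop}_{i + 1}"
            samples.append(name)
            pop_of[name] = pop
            rows.append(rng.binomial(2, p_k).astype(np.int8))
    index = {s: i for i, s in enumerate(samples)}

    if ld_block_size > 1:
        geno = np.vstack(rows)
        for _, grp in freq_truth.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            for start in range(0, len(idx), ld_block_size):
                block = idx[start : start + ld_block_size]
                if len(block) < 2:
                    continue
                anchor = geno[:, block[0]]
                for j in block[1:]:
                    copy = anchor.copy()
                    flip = rng.random(copy.shape) < ld_flip_rate
                    copy[flip] = rng.integers(0, 3, size=flip.sum(), dtype=np.int8)
                    geno[:, j] = copy
        rows = [geno[i] for i in range(geno.shape[0])]

    # Planted relatives are appended to their source's population.
    relationships: list[tuple[str, str, str]] = []
    for source, clone in plan.duplicates:
        if source not in index:
            raise ValueError(f"duplicate source {source!r} not a simulated sample")
        samples.append(clone)
        pop_of[clone] = pop_of[source]
        rows.append(rows[index[source]].copy())
        relationships.append((source, clone, "duplicate"))
    for parent, child in plan.parent_offspring:
        if parent not in index:
            raise ValueError(f"parent {parent!r} not a simulated sample")
        pop = pop_of[parent]
        p_k = freq_truth[f"p_pop:{pop}"].to_numpy()
        parent_geno = rows[index[parent]]
        from_parent = rng.random(n_sites) < parent_geno / 2.0
        from_pop = rng.binomial(1, p_k)
        samples.append(child)
        pop_of[child] = pop
        rows.append((from_parent + from_pop).astype(np.int8))
        relationships.append((parent, child, "parent_offspring"))

    dosages = np.vstack(rows)
    if missing_rate > 0.0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages = dosages.copy()
        dosages[mask] = MISSING

    # Per-site quality annotations with planted failing fractions.
    sites = freq_truth[["chrom", "pos"]].copy()
    ref_alt = rng.integers(0, 4, size=(n_sites, 2))
    bases = np.array(list("ACGT"))
    sites["ref"] = bases[ref_alt[:, 0]]
    sites["alt"] = bases[(ref_alt[:, 0] + 1 + ref_alt[:, 1] % 3) % 4]
    fail_truth = {}
    for name, dist in ANNOTATION_DISTRIBUTIONS.items():
        values = _draw_annotation(rng, dist["pass"], n_sites)
        frac = qc_failure_spec.get(name, 0.0)
        fail = np.zeros(n_sites, dtype=bool)
        if frac > 0.0:
            n_fail = int(round(frac * n_sites))
            chosen = rng.choice(n_sites, size=n_fail, replace=False)
            fail[chosen] = True
            values[chosen] = _draw_annotation(rng, dist["fail"], n_fail)
        # DP is reserved as an integer field in VCF; other annotations keep
        # 4 decimals so a VCF round-trip is lossless.
        sites[name] = np.round(values, 0 if name == "DP" else 4)
        fail_truth[name] = fail

    genotypes = GenotypeMatrix(dosages=dosages, samples=samples, sites=sites)

    # Gene intervals tile each autosome with fixed-length genes.
    gene_rows = []
    for chrom, grp in freq_truth.groupby("chrom", sort=False):
        span = int(grp["pos"].max())
        n_genes = int(np.ceil(span / gene_length_bp))
        for g in range(n_genes):
            gene_rows.append(
                (chrom, g * gene_length_bp, (g + 1) * gene_length_bp,
                 f"{chrom}_g{g + 1:03d}")
            )
    gene_intervals = GeneIntervals(
        pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"])
    )

    pop_map = PopulationMap(
        pd.DataFrame(
            {
                "sample_id": samples,
                "population": [pop_of[s] for s in samples],
                "species": [model.species_of(pop_of[s]) for s in samples],
            }
        )
    )
    return SimulatedCohort(
        genotypes=genotypes,
        gene_intervals=gene_intervals,
        pop_map=pop_map,
        truth_frequencies=freq_truth,
        truth_relationships=pd.DataFrame(
            relationships, columns=["sample_i", "sample_j", "relationship"]
        ),
        truth_qc_failures=pd.DataFrame(fail_truth),
        seed=seed,
    )


def default_divergence_model(
    f_species: float = 0.3, f_population: float = 0.02
) -> DivergenceModel:
    """Two species: ten weakly diverged populations plus two reference
    populations of a strongly diverged sister species."""
    dromedary_pops = [f"pop{i + 1:02d}" for i in range(10)]
    bactrian_pops = ["refA", "refB"]
    return DivergenceModel(
        tree={"dromedary": dromedary_pops, "bactrian": bactrian_pops},
        f_species={"dromedary": f_species, "bactrian": f_species},
        f_population={p: f_population for p in dromedary_pops + bactrian_pops},
    )


def default_cohort(
    seed: int = 0,
    n_autosomes: int = 10,
    sites_per_autosome: int = 2000,
    samples_per_population: int = 3,
    missing_rate: float = 0.02,
    f_species: float = 0.3,
    f_population: float = 0.02,
    qc_failure_spec: dict[str, float] | None = None,
    plan: PedigreePlan | None = None,
) -> SimulatedCohort:
    """The default study-scale cohort: 10 autosomes x 2000 sites, twelve
    populations of three samples, one planted duplicate and one planted
    parent-offspring pair."""
    model = default_divergence_model(f_species, f_population)
    freqs = simulate_frequencies(
        model, sites_per_autosome, n_autosomes, seed=seed
    )
    if plan is None:
        plan = PedigreePlan(
            duplicates=[("pop01_1", "pop01_dup")],
            parent_offspring=[("pop02_1", "pop02_child")],
        )
    if qc_failure_spec is None:
        qc_failure_spec = {
            "QD": 0.02, "MQ": 0.02, "QUAL": 0.01, "FS": 0.01,
            "MQRankSum": 0.01, "ReadPosRankSum": 0.01, "DP": 0.02,
        }
    return simulate_cohort(
        freqs,
        pop_sizes={p: samples_per_population for p in model.populations},
        model=model,
        plan=plan,
        missing_rate=missing_rate,
        qc_failure_spec=qc_failure_spec,
        seed=seed + 1,
    )


def emit_cohort(cohort: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as VCF + BED + population-map TSV + truth TSVs."""
    from . import io as hio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "bed": out / "genes.bed",
        "pop_map": out / "popmap.tsv",
        "truth_frequencies": out / "truth_frequencies.tsv",
        "truth_relationships": out / "truth_relationships.tsv",
        "truth_qc_failures": out / "truth_qc_failures.tsv",
    }
    hio.write_vcf(cohort.genotypes, paths["vcf"])
    hio.write_bed(cohort.gene_intervals, paths["bed"])
    hio.write_pop_map(cohort.pop_map, paths["pop_map"])
    cohort.truth_frequencies.to_csv(paths["truth_frequencies"], sep="\t", index=False)
    cohort.truth_relationships.to_csv(
        paths["truth_relationships"], sep="\t", index=False
    )
    cohort.truth_qc_failures.to_csv(paths["truth_qc_failures"], sep="\t", index=False)
    return paths
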