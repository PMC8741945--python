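"""Variant and sample quality control.

Two filtering stages, mirroring common WGS practice: per-site hard filters
on caller annotations (quality-by-depth, mapping quality, base quality,
strand bias, rank-sum statistics, depth of coverage), followed by
population-genetic filters (minor allele frequency, call rate,
Hardy-Weinberg exact test, linkage-disequilibrium pruning). Sample-level QC
removes low-call-rate samples and the worse member of near-duplicate pairs
detected by identity-by-state.

The cascade is sequential and order-dependent; the report records the order
used and, for each stage, the sites excluded and remaining.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import MISSING, GenotypeMatrix

HARD_FILTER_CRITERIA = ("QD", "MQ", "QUAL", "FS", "MQRankSum", "ReadPosRankSum")


@dataclass
class FilterConfig:
    """Thresholds for the full cascade. Inequalities are strict exactly as
    stated: e.g. a site with QD equal to ``qd_min`` is retained, a site with
    MAF equal to ``maf_min`` is excluded."""

    qd_min: float = 2.0  # exclude QD < 2
    mq_min: float = 40.0  # exclude MQ < 40
    qual_min: float = 30.0  # exclude QUAL < 30
    fs_max: float = 60.0  # exclude FS > 60
    mqranksum_min: float = -12.5  # exclude MQRankSum < -12.5
    readposranksum_min: float = -8.0  # exclude ReadPosRankSum < -8
    depth_min: float = 2.0  # retain mean depth >= 2 reads
    depth_sd_factor: float = 3.0  # ... and <= grand mean + 3 SD
    maf_min: float = 0.05  # exclude MAF <= 5%
    site_call_rate_min: float = 0.95  # exclude call rate <= 95%
    hwe_p_min: float = 1e-6  # exclude HWE exact p < 1e-6
    ld_window_bp: int = 50_000
    ld_step_bp: int = 10_000
    ld_r2_max: float = 0.1  # exclude one of each pair with r^2 > 0.1
    sample_call_rate_min: float = 0.95
    ibs_max: float = 0.95  # pairs with IBS >= 0.95 lose their worse member

    def __post_init__(self) -> None:
        if not self.ld_window_bp >= self.ld_step_bp > 0:
            raise ValueError("require ld_window_bp >= ld_step_bp > 0")


@dataclass
class FilterReport:
    """Ordered per-stage exclusion counts plus the surviving indices."""

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    retained_sites: np.ndarray | None = None
    retained_samples: np.ndarray | None = None
    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    #: Site indices surviving the quality stages only (hard filters + depth),
    #: before the population filters. Diversity profiling uses this set; the
    #: population filters serve PCA and kinship.
    quality_retained_sites: np.ndarray | None = None

    def add(self, name: str, excluded: int, remaining: int) -> None:
        self.stages.append((name, excluded, remaining))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["filter", "sites_excluded", "sites_remaining"]
        )


def apply_hard_filters(
    annotations: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[np.ndarray, list[tuple[str, np.ndarray]]]:
    """Per-criterion hard-filter masks on caller annotations.

    Returns the overall retained mask plus, per criterion, the mask of
    sites failing that criterion. A missing (NaN) annotation never triggers
    exclusion, following the variant-caller convention that absent
    annotations are not filtered on.
    """
    config = config or FilterConfig()
    n = len(annotations)
    checks = {
        "QD": lambda a: a < config.qd_min,
        "MQ": lambda a: a < config.mq_min,
        "QUAL": lambda a: a < config.qual_min,
        "FS": lambda a: a > config.fs_max,
        "MQRankSum": lambda a: a < config.mqranksum_min,
        "ReadPosRankSum": lambda a: a < config.readposranksum_min,
    }
    retained = np.ones(n, dtype=bool)
    per_criterion: list[tuple[str, np.ndarray]] = []
    for name in HARD_FILTER_CRITERIA:
        if name not in annotations.columns:
            per_criterion.append((name, np.zeros(n, dtype=bool)))
            continue
        values = annotations[name].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            fails = checks[name](values)
        fails &= ~np.isnan(values)
        per_criterion.append((name, fails))
        retained &= ~fails
    return retained, per_criterion


def depth_range_filter(
    depths: np.ndarray, config: FilterConfig | None = None
) -> np.ndarray:
    """Retain sites whose mean depth lies between the read floor and
    (grand mean + 3 SD), both bounds inclusive. The SD is computed over the
    per-site mean depths."""
    config = config or FilterConfig()
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty site set")
    if (depths[~np.isnan(depths)] < 0).any():
        raise ValueError("depths must be non-negative")
    upper = np.nanmean(depths) + config.depth_sd_factor * np.nanstd(depths)
    with np.errstate(invalid="ignore"):
        keep = (depths >= config.depth_min) & (depths <= upper)
    keep |= np.isnan(depths)  # absent depth annotation: not filtered on
    return keep


def hwe_exact_pvalue(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed configuration (the standard two-sided exact HWE
    test). Monomorphic sites return 1.0.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_bb_hom + n_het
    if n == 0 or n_a == 0 or n_b == 0:
        return 1.0
    n_minor = min(n_a, n_b)
    # Heterozygote counts share the parity of the minor allele count.
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    aa = (min(n_a, n_b) - hets) // 2
    bb = (max(n_a, n_b) - hets) // 2
    valid = (aa >= 0) & (bb >= 0)
    hets, aa, bb = hets[valid], aa[valid], bb[valid]
    logp = (
        gammaln(n + 1)
        - gammaln(aa + 1)
        - gammaln(hets + 1)
        - gammaln(bb + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def site_statistics(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Per-site minor allele frequency, call rate and genotype counts.

    MAF is computed over called genotypes only and lies in [0, 0.5]; a site
    with no called genotypes has call rate 0 and MAF NaN.
    """
    d = genotypes.dosages
    called = d != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_freq = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    return pd.DataFrame(
        {
            "maf": maf,
            "call_rate": n_called / genotypes.n_samples,
            "n_called": n_called,
            "n_hom_ref": ((d == 0) & called).sum(axis=0),
            "n_het": (d == 1).sum(axis=0),
            "n_hom_alt": (d == 2).sum(axis=0),
        }
    )


def hwe_pvalues(genotypes: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per site (1.0 where untestable)."""
    stats = site_statistics(genotypes)
    return np.array(
        [
            hwe_exact_pvalue(int(r.n_hom_ref), int(r.n_het), int(r.n_hom_alt))
            for r in stats.itertuples()
        ]
    )


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete samples. Zero variance (or fewer than two complete
    observations) makes r^2 undefined; 0.0 is returned with a warning."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if len(a) < 2 or a.var() == 0.0 or b.var() == 0.0:
        warnings.warn("r^2 undefined (insufficient data or zero variance); using 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _r2_matrix(dosages: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 among columns of a samples x sites block."""
    called = (dosages != MISSING).astype(float)
    x = np.where(dosages == MISSING, 0.0, dosages).astype(float)
    n = called.T @ called
    sa = x.T @ called  # sum of a over sites where both called
    sab = x.T @ x
    saa = (x * x).T @ called
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_a = sa / n
        cov = sab / n - mean_a * mean_a.T
        var_a = saa / n - mean_a**2
        r2 = cov**2 / (var_a * var_a.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    genotypes: GenotypeMatrix, config: FilterConfig | None = None
) -> np.ndarray:
    """Greedy sliding-window LD pruning (indep-pairwise style).

    Windows of ``ld_window_bp`` advance by ``ld_step_bp`` within each
    chromosome. While any retained pair in the window has r^2 above the
    threshold, the worst pair's lower-MAF member is removed (ties broken by
    removing the later position). Returns retained site indices; afterwards
    no two retained sites within one window length of each other exceed the
    threshold.
    """
    config = config or FilterConfig()
    sites = genotypes.sites
    maf = site_statistics(genotypes)["maf"].to_numpy()
    keep = np.ones(genotypes.n_sites, dtype=bool)
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        if (np.diff(pos) < 0).any():
            raise ValueError(f"positions not sorted on {chrom}")
        start = int(pos.min())
        stop = int(pos.max())
        w = start
        while w <= stop:
            in_win = idx[(pos >= w) & (pos < w + config.ld_window_bp)]
            in_win = in_win[keep[in_win]]
            if len(in_win) > 1:
                r2 = _r2_matrix(genotypes.dosages[:, in_win])
                np.fill_diagonal(r2, 0.0)
                local = np.ones(len(in_win), dtype=bool)
                while True:
                    sub = np.where(local)[0]
                    if len(sub) < 2:
                        break
                    block = r2[np.ix_(sub, sub)]
                    worst = np.unravel_index(np.argmax(block), block.shape)
                    if block[worst] <= config.ld_r2_max:
                        break
                    i, j = in_win[sub[worst[0]]], in_win[sub[worst[1]]]
                    if maf[i] < maf[j]:
                        victim = i
                    elif maf[j] < maf[i]:
                        victim = j
                    else:  # tie: remove the later position
                        victim = max(i, j)
                    keep[victim] = False
                    local[np.where(in_win == victim)[0][0]] = False
            w += config.ld_step_bp
    return np.flatnonzero(keep)


def ibs_matrix(genotypes: GenotypeMatrix) -> np.ndarray:
    """Mean identity-by-state per sample pair: (2 - |g_i - g_j|)/2 averaged
    over pairwise-complete sites (NaN when no complete sites)."""
    d = genotypes.dosages
    n = genotypes.n_samples
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (d[i] != MISSING) & (d[j] != MISSING)
            if not ok.any():
                out[i, j] = out[j, i] = np.nan
                continue
            ibs = (2.0 - np.abs(d[i, ok].astype(float) - d[j, ok])) / 2.0
            out[i, j] = out[j, i] = ibs.mean()
    return out


def sample_qc(
    genotypes: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Sample-level exclusions: low call rate, then near-duplicate pairs.

    A sample is excluded if its genotyping call rate is at or below the
    threshold; for each pair with IBS at or above the duplicate threshold,
    the member with the lower call rate is excluded (tie: later sample
    order). Returns retained sample indices and (sample, reason) pairs.
    """
    config = config or FilterConfig()
    if genotypes.n_samples < 2:
        raise ValueError("sample QC needs at least two samples")
    call_rate = genotypes.called.mean(axis=1)
    excluded: dict[int, str] = {}
    for i, cr in enumerate(call_rate):
        if cr <= config.sample_call_rate_min:
            excluded[i] = f"call_rate<={config.sample_call_rate_min}"
    ibs = ibs_matrix(genotypes)
    for i in range(genotypes.n_samples):
        for j in range(i + 1, genotypes.n_samples):
            if i in excluded or j in excluded:
                continue
            if np.isnan(ibs[i, j]) or ibs[i, j] < config.ibs_max:
                continue
            if call_rate[i] < call_rate[j]:
                victim = i
            elif call_rate[j] < call_rate[i]:
                victim = j
            else:
                victim = j  # tie: later sample order
            excluded[victim] = (
                f"IBS>={config.ibs_max} with "
                f"{genotypes.samples[i if victim == j else j]}"
            )
    retained = np.array(
        [i for i in range(genotypes.n_samples) if i not in excluded], dtype=int
    )
    reasons = [(genotypes.samples[i], r) for i, r in sorted(excluded.items())]
    return retained, reasons


def run_variant_qc(
    genotypes: GenotypeMatrix, config: FilterConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """The full sequential cascade.

    Order: the six annotation hard filters, the depth-range filter, sample
    QC (call rate, then IBS near-duplicates), then the population filters
    on the surviving samples: MAF, site call rate, HWE exact test, LD
    pruning. Each stage consumes the previous stage's survivors.
    """
    config = config or FilterConfig()
    report = FilterReport()
    current = genotypes
    original_index = np.arange(genotypes.n_sites)

    def drop_sites(keep_mask: np.ndarray, name: str) -> None:
        nonlocal current, original_index
        excluded = int((~keep_mask).sum())
        current = current.take_sites(keep_mask)
        original_index = original_index[keep_mask]
        report.add(name, excluded, current.n_sites)

    _, per_criterion = apply_hard_filters(current.annotations(), config)
    mask_sofar = np.ones(current.n_sites, dtype=bool)
    for name, fails in per_criterion:
        report.add(f"hard:{name}", int((fails & mask_sofar).sum()), 0)
        mask_sofar &= ~fails
    current = current.take_sites(mask_sofar)
    original_index = original_index[mask_sofar]
    # Fill in remaining counts for the sequential hard-filter rows.
    remaining = genotypes.n_sites
    fixed = []
    for name, excluded, _ in report.stages:
        remaining -= excluded
        fixed.append((name, excluded, remaining))
    report.stages = fixed

    if "DP" in current.sites.columns:
        keep = depth_range_filter(current.sites["DP"].to_numpy(), config)
        drop_sites(keep, "depth_range")

    report.quality_retained_sites = original_index.copy()

    retained_samples, reasons = sample_qc(current, config)
    report.excluded_samples = reasons
    report.retained_samples = retained_samples
    current = current.take_samples(retained_samples)
    report.add("sample_qc", 0, current.n_sites)

    stats = site_statistics(current)
    maf = stats["maf"].to_numpy()
    keep = ~(np.isnan(maf) | (maf <= config.maf_min))
    drop_sites(keep, "maf")

    stats = site_statistics(current)
    drop_sites(stats["call_rate"].to_numpy() > config.site_call_rate_min, "call_rate")

    keep = hwe_pvalues(current) >= config.hwe_p_min
    drop_sites(keep, "hwe")

    retained = ld_prune(current, config)
    keep = np.zeros(current.n_sites, dtype=bool)
    keep[retained] = True
    drop_sites(keep, "ld_prune")

    report.retained_sites = original_index
    return current, report
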