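"""KING-robust pairwise kinship and relationship-degree classification.

The within-pair estimator uses only heterozygosity and opposite-homozygote
counts, so it needs no allele-frequency estimates and is robust to
population structure:

    phi = (N_AaAa - 2 * N_AAaa) / (N_Aa(i) + N_Aa(j))

where N_AaAa counts sites at which both samples are heterozygous, N_AAaa
counts opposite homozygotes, and N_Aa(.) counts heterozygous sites per
sample — all over pairwise-complete sites. phi is 0.5 for duplicates,
about 0.25 for first-degree relatives and about 0 for unrelated pairs;
negative values occur for diverged pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, PopulationMap

#: Degree bands on phi (upper bound inclusive), from closest to unrelated.
DEGREE_BANDS = (
    (0.354, "duplicate/MZ"),  # phi > 0.354
    (0.177, "first"),  # 0.177 < phi <= 0.354
    (0.0884, "second"),
    (0.0442, "third"),
)
UNRELATED = "unrelated"  # phi <= 0.0442


@dataclass
class KinshipRecord:
    sample_i: str
    sample_j: str
    phi: float  # NaN when undefined (no heterozygous sites)
    n_sites_used: int
    degree: str


def king_kinship(dosage_i: np.ndarray, dosage_j: np.ndarray) -> tuple[float, int]:
    """KING-robust phi for one sample pair.

    Returns ``(phi, n_sites_used)`` computed over pairwise-complete sites;
    phi is NaN (undefined) if neither sample has a heterozygous call there.
    """
    a = np.asarray(dosage_i)
    b = np.asarray(dosage_j)
    if a.shape != b.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    het_i = int((a == 1).sum())
    het_j = int((b == 1).sum())
    if het_i + het_j == 0:
        return float("nan"), int(ok.sum())
    both_het = int(((a == 1) & (b == 1)).sum())
    opp_hom = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    phi = (both_het - 2.0 * opp_hom) / (het_i + het_j)
    return float(phi), int(ok.sum())


def classify_degree(phi: float) -> str:
    """Map phi to a relationship degree. Band boundaries are assigned to
    the more distant degree (upper-inclusive bands)."""
    if np.isnan(phi):
        return "undefined"
    for lower, label in DEGREE_BANDS:
        if phi > lower:
            return label
    return UNRELATED


def kinship_matrix(
    genotypes: GenotypeMatrix, pop_map: PopulationMap | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs kinship records plus per-group summaries.

    Returns ``(pairs, summary)``: one row per unordered sample pair with
    phi, sites used and degree; and mean +/- SD of phi over within-group
    pairs for each population and species in ``pop_map`` (empty when no map
    is given). Pairs with undefined phi propagate as NaN and are dropped
    from summaries.
    """
    if genotypes.n_samples < 2:
        raise ValueError("kinship needs at least two samples")
    records = []
    for i, j in combinations(range(genotypes.n_samples), 2):
        phi, n_used = king_kinship(genotypes.dosages[i], genotypes.dosages[j])
        records.append(
            KinshipRecord(
                genotypes.samples[i],
                genotypes.samples[j],
                phi,
                n_used,
                classify_degree(phi),
            )
        )
    pairs = pd.DataFrame(
        [(r.sample_i, r.sample_j, r.n_sites_used, r.phi, r.degree) for r in records],
        columns=["sample_i", "sample_j", "n_sites", "phi", "degree"],
    )
    summaries = []
    if pop_map is not None:
        groups = [("population", p, set(pop_map.members(p))) for p in pop_map.populations]
        groups += [("species", s, set(pop_map.species_members(s))) for s in pop_map.species]
        for level, name, members in groups:
            sub = pairs[
                pairs["sample_i"].isin(members) & pairs["sample_j"].isin(members)
            ]["phi"].dropna()
            if len(sub) == 0:
                continue
            summaries.append(
                (level, name, len(sub), sub.mean(), sub.std(ddof=1) if len(sub) > 1 else 0.0)
            )
    summary = pd.DataFrame(
        summaries, columns=["level", "group", "n_pairs", "phi_mean", "phi_sd"]
    )
    return pairs, summary
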