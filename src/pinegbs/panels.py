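"""Pedigree-panel SNP selection and random sub-panel generation.

Candidate SNPs for parentage and clone work must be common (MAF between
0.35 and 0.5 in the putatively unrelated cohort), well called (call rate
above 0.75), consistent with Hardy-Weinberg proportions (chi-square
goodness-of-fit p above 0.10) and mutually unlinked (squared genotypic
correlation below 0.02).  From the passing pool, seeded random panels of a
fixed size are drawn, and panels can be truncated to nested prefixes for
panel-size experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import GenotypeMatrix, Panel


@dataclass
class SelectionCriteria:
    call_rate_min: float = 0.75
    maf_range: tuple[float, float] = (0.35, 0.5)
    hwe_p_min: float = 0.10
    ld_r2_max: float = 0.02
    reference_cohort: list[str] = field(default_factory=list)
    #: cohort for the LD r^2 computation; ``None`` = every diploid sample in
    #: the matrix.  Sampling noise of r^2 is ~1/n, so a tight r^2 ceiling
    #: only admits a large mutually-unlinked pool when measured on a cohort
    #: substantially larger than the 135-tree frequency cohort.
    ld_cohort: list[str] | None = None

    def __post_init__(self):
        if not 0 < self.call_rate_min <= 1:
            raise ValueError("call_rate_min must be in (0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


def hwe_chisq(genotype_counts: tuple[int, int, int]) -> tuple[float, float]:
    """Chi-square goodness-of-fit test for Hardy-Weinberg proportions.

    ``genotype_counts`` are (n_AA, n_Aa, n_aa).  Expected counts come from
    the estimated allele frequency; the statistic has 1 degree of freedom
    (no continuity correction).  Monomorphic counts admit no test and
    return ``(0.0, 1.0)``.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(((observed - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def genotypic_r2(snp_a: np.ndarray, snp_b: np.ndarray) -> float:
    """Squared Pearson correlation of allele-dosage vectors (composite LD).

    Uses pairwise-complete individuals (NaN = missing).  A zero-variance
    vector makes the correlation undefined; such pairs are treated as
    unlinked and return 0.0.
    """
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete individuals")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def select_pedigree_snps(
    matrix: GenotypeMatrix,
    criteria: SelectionCriteria,
    return_diagnostics: bool = False,
):
    """Select the pedigree-reconstruction candidate pool.

    Criteria are applied in order: call rate (strictly above the floor),
    MAF in the closed range, HWE p strictly above the floor, then greedy LD
    pruning (SNPs visited in descending call rate, a SNP is kept only if
    its r^2 against every already-kept SNP is below the ceiling).  All
    statistics are computed over the criteria's diploid reference cohort.

    With ``return_diagnostics=True`` also returns a per-SNP frame of the
    computed criteria and the reason each SNP was excluded (or "retained").
    """
    if not criteria.reference_cohort:
        raise ValueError("criteria.reference_cohort must be provided")
    cohort = [s for s in criteria.reference_cohort if s in matrix.samples]
    sub = matrix.subset(sample_ids=cohort)
    dos = sub.dosage()  # (n_cohort, n_sites), NaN = missing

    n = dos.shape[0]
    n_called = (~np.isnan(dos)).sum(axis=0)
    call_rate = n_called / n
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.nansum(dos, axis=0) / (2 * np.maximum(n_called, 1))
    maf = np.minimum(q, 1 - q)

    lo, hi = criteria.maf_range
    keep = (call_rate > criteria.call_rate_min) & (maf >= lo) & (maf <= hi) & (n_called > 0)

    hwe_p = np.full(matrix.n_sites, np.nan)  # NaN = not evaluated (failed earlier)
    for j in np.flatnonzero(keep):
        col = dos[:, j]
        col = col[~np.isnan(col)]
        counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
        hwe_p[j] = hwe_chisq(counts)[1]
    keep &= hwe_p > criteria.hwe_p_min

    # greedy LD pruning, deterministic: descending call rate, ties by site order
    if criteria.ld_cohort is None:
        ld_samples = [s for s, p in zip(matrix.samples, matrix.ploidy) if p == 2]
    else:
        ld_samples = [s for s in criteria.ld_cohort if s in matrix.samples]
    ld_dos = matrix.subset(sample_ids=ld_samples).dosage()
    candidates = sorted(np.flatnonzero(keep), key=lambda j: (-call_rate[j], j))
    kept: list[int] = []
    for j in candidates:
        linked = False
        for k in kept:
            try:
                if genotypic_r2(ld_dos[:, j], ld_dos[:, k]) >= criteria.ld_r2_max:
                    linked = True
                    break
            except ValueError:
                continue  # too few complete pairs: treated as unlinked
        if not linked:
            kept.append(j)
    kept.sort()
    if not kept:
        import warnings

        warnings.warn("no SNPs satisfy the pedigree-panel selection criteria", stacklevel=2)
    panel = Panel(snp_ids=[matrix.site_ids[j] for j in kept], label="pedigree_pool")
    if not return_diagnostics:
        return panel
    import pandas as pd

    lo, hi = criteria.maf_range
    reason = np.where(
        ~(call_rate > criteria.call_rate_min), "call_rate",
        np.where(
            ~((maf >= lo) & (maf <= hi) & (n_called > 0)), "maf",
            np.where(~(hwe_p > criteria.hwe_p_min), "hwe", "ld_pruned"),
        ),
    ).astype(object)
    reason[np.asarray(kept, dtype=int)] = "retained"
    diagnostics = pd.DataFrame(
        {
            "site_id": matrix.site_ids,
            "call_rate": call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "status": reason,
        }
    )
    return panel, diagnostics


def random_panels(pool: Panel, n_panels: int, panel_size: int, seed: int) -> list[Panel]:
    """Draw ``n_panels`` independent uniform without-replacement panels of
    ``panel_size`` SNPs from *pool* (overlap across panels allowed)."""
    if panel_size > len(pool):
        raise ValueError(f"panel_size {panel_size} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(pool.snp_ids, dtype=object)
    return [
        Panel(
            snp_ids=list(rng.choice(ids, size=panel_size, replace=False)),
            label=f"panel_{i + 1:02d}",
        )
        for i in range(n_panels)
    ]


def truncate_panel(panel: Panel, sizes: list[int]) -> list[Panel]:
    """Nested prefix truncations (the first *k* SNPs) of *panel*."""
    for k in sizes:
        if k > len(panel):
            raise ValueError(f"truncation size {k} exceeds panel size {len(panel)}")
    return [
        Panel(snp_ids=panel.snp_ids[:k], label=f"{panel.label}_first{k}") for k in sizes
    ]
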