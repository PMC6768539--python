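"""The two published SNP filtering pipelines and the associated QC metrics.

The pilot pipeline (80K probe panel) removes whole probes and SNPs in five
ordered stages: paralogous probes (heterozygous megagametophytes), low site
quality, low mean depth, more than two alleles, and extreme population-level
allele-depth ratio.

The revised pipeline (49K probe panel) establishes data quality first and
prefers blanking individual data points over removing sites: mean depth per
SNP, depth-based triallelic resolution (weakly supported extra alleles are
dropped and the SNP reclassified biallelic; well-supported ones are routed
to a separate true-triallelic table), per-individual depth and allele-ratio
masking, paralogous-probe removal, monomorphic removal, and a MAF floor over
the putatively unrelated cohort.

Per-individual stages mask data points (forced missing) instead of zeroing
their depths, so depth statistics are computed on raw depths and re-running
a pipeline on its own output is a no-op for the site-level stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import call_genotypes
from .model import FilterReport, GenotypeMatrix, SampleSheet, VariantTable

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the two pipelines (defaults as published)."""

    pipeline: str = "final49K"  # or "pilot80K"
    haploid_het_fraction: float = 0.05
    site_quality_min: float = 10.0
    mean_depth_min_80K: float = 5.0
    mean_depth_min_49K: float = 10.0
    indiv_depth_min: int = 10
    pop_allele_ratio_bounds: tuple[float, float] = (0.1, 0.9)
    indiv_allele_ratio_min: float = 0.1
    alt_allele_true_depth: int = 10
    maf_min: float = 0.03
    maf_reference_samples: list[str] | None = None  # default: unrelated cohort

    def __post_init__(self):
        if not 0 < self.maf_min < 0.5:
            raise ValueError("maf_min must be in (0, 0.5)")
        lo, hi = self.pop_allele_ratio_bounds
        if not lo < hi:
            raise ValueError("pop_allele_ratio_bounds must be ordered")


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def haploid_het_site_fraction(table: VariantTable, sheet: SampleSheet) -> np.ndarray:
    """Per-site fraction of megagametophytes that look heterozygous.

    A haploid is heterozygous at a site when its depth vector supports two
    or more alleles with at least 2 reads each (single-read alternative
    observations are ignored — they are overwhelmingly sequencing error).
    The denominator is the number of megagametophytes with any unmasked
    reads at the site; sites unseen in every haploid get fraction 0.
    """
    megas = sheet.megagametophyte_ids
    megas = [m for m in megas if m in table.samples]
    if not megas:
        return np.zeros(table.n_sites)
    idx = table.sample_index(megas)
    depths = np.where(table.allele_mask()[None, :, :], table.depths[idx], 0)
    unmasked = ~table.masked[idx]
    covered = (depths.sum(axis=2) >= 1) & unmasked
    het = ((depths >= 2).sum(axis=2) >= 2) & covered
    denom = covered.sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(denom > 0, het.sum(axis=0) / np.maximum(denom, 1), 0.0)
    return frac


def _paralogous_probes(table: VariantTable, sheet: SampleSheet, threshold: float) -> set[str]:
    frac = haploid_het_site_fraction(table, sheet)
    probes = table.sites["probe_id"].to_numpy()
    return set(probes[frac > threshold])  # strictly "more than"


def population_alt_ratio(table: VariantTable, sheet: SampleSheet | None = None) -> np.ndarray:
    """Mean over informative diploid individuals of alt/(ref+alt) depth.

    Haploids are excluded — a megagametophyte legitimately sits at ratio 0
    or 1 and would bias the population average.  Individuals with zero
    ref+alt depth (or masked) at a site are excluded from the mean; sites
    with no informative individual get NaN.
    """
    ref = table.depths[:, :, 0].astype(float)
    alt = table.depths[:, :, 1].astype(float)
    tot = ref + alt
    informative = (tot > 0) & ~table.masked
    if sheet is not None:
        informative &= (sheet.ploidy_for(table.samples) == 2)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(informative, alt / np.where(tot > 0, tot, 1), np.nan)
    n = informative.sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, np.nansum(ratio, axis=0) / np.maximum(n, 1), np.nan)


# ---------------------------------------------------------------------------
# pilot 80K pipeline
# ---------------------------------------------------------------------------

def filter_pilot80K(
    table: VariantTable, sheet: SampleSheet, cfg: FilterConfig | None = None
) -> tuple[VariantTable, FilterReport]:
    """Apply the pilot pipeline's five stages in their published order."""
    cfg = cfg or FilterConfig(pipeline="pilot80K")
    report = FilterReport()
    t = table.copy()
    report.add_stage("None", t)

    # (1) whole probes heterozygous in > threshold of megagametophytes
    if sheet.megagametophyte_ids:
        bad = _paralogous_probes(t, sheet, cfg.haploid_het_fraction)
        t = t.subset_sites(~t.sites["probe_id"].isin(bad).to_numpy())
    else:
        log.warning("no megagametophytes in sheet; polymorphic-haploid stage skipped")
    report.add_stage("Polymorphic haploids", t)

    # (2) site quality
    t = t.subset_sites(t.sites["qual"].to_numpy() >= cfg.site_quality_min)
    report.add_stage("Quality", t)

    # (3) mean read depth per SNP
    t = t.subset_sites(t.mean_site_depth() >= cfg.mean_depth_min_80K)
    report.add_stage("Read depth per SNP", t)

    # (4) more than two alleles present
    t = t.subset_sites(t.sites["n_alleles"].to_numpy() <= 2)
    report.add_stage("Biallelic", t)

    # (5) population-average alt/(ref+alt) ratio
    lo, hi = cfg.pop_allele_ratio_bounds
    ratio = population_alt_ratio(t, sheet)
    keep = ~np.isnan(ratio) & (ratio >= lo) & (ratio <= hi)
    t = t.subset_sites(keep)
    report.add_stage("Allele ratio", t)

    return t, report


# ---------------------------------------------------------------------------
# revised 49K pipeline
# ---------------------------------------------------------------------------

def _resolve_extra_alleles(
    t: VariantTable, true_depth: int
) -> tuple[VariantTable, VariantTable | None]:
    """Stage (2) of the 49K pipeline.

    At sites listing >2 alleles, the alternate kept is the one with the
    highest total depth; every other listed alternate is an "extra" allele.
    If any individual supports an extra allele at depth > ``true_depth`` the
    site is a true triallelic and moves to the separate table; otherwise
    (max individual depth <= ``true_depth``, the boundary treated as weak)
    the extra alleles are dropped and the site reclassified biallelic.
    """
    n_alleles = t.sites["n_alleles"].to_numpy()
    multi = np.flatnonzero(n_alleles > 2)
    if multi.size == 0:
        return t, None

    tri_sites = []
    depths = t.depths
    new_sites = t.sites.copy()
    new_depths = depths.copy()
    amask = t.allele_mask()
    for j in multi:
        d = np.where(amask[j][None, :], depths[:, j, :], 0)
        alt_tot = d[:, 1:].sum(axis=0)
        keep_alt = 1 + int(np.argmax(alt_tot))  # deepest alternate, ties -> lower index
        extras = [k for k in range(1, int(n_alleles[j])) if k != keep_alt]
        if max(int(d[:, k].max()) for k in extras) > true_depth:
            tri_sites.append(j)
            continue
        alleles = list(t.sites.iloc[j]["alleles"])
        new_sites.at[new_sites.index[j], "alleles"] = (alleles[0], alleles[keep_alt])
        new_sites.at[new_sites.index[j], "n_alleles"] = 2
        nd = np.zeros_like(new_depths[:, j, :])
        nd[:, 0] = d[:, 0]
        nd[:, 1] = d[:, keep_alt]
        new_depths[:, j, :] = nd

    resolved = VariantTable(
        samples=list(t.samples), sites=new_sites, depths=new_depths, masked=t.masked.copy()
    )
    tri = resolved.subset_sites(np.asarray(tri_sites, dtype=int)) if tri_sites else None
    keep = np.ones(t.n_sites, dtype=bool)
    keep[tri_sites] = False
    return resolved.subset_sites(keep), tri


def filter_final49K(
    table: VariantTable, sheet: SampleSheet, cfg: FilterConfig | None = None
) -> tuple[VariantTable, VariantTable | None, FilterReport]:
    """Apply the revised pipeline's seven stages in their published order.

    Returns ``(filtered, true_triallelic, report)``; the second element is
    ``None`` when no site was routed to the true-triallelic table.
    """
    cfg = cfg or FilterConfig(pipeline="final49K")
    report = FilterReport()
    t = table.copy()
    report.add_stage("None", t)

    # (1) mean read depth per SNP across all individuals
    t = t.subset_sites(t.mean_site_depth() >= cfg.mean_depth_min_49K)
    report.add_stage("Read depth per SNP", t)

    # (2) resolve extra alleles / split off true triallelics
    t, tri = _resolve_extra_alleles(t, cfg.alt_allele_true_depth)
    report.add_stage("Biallelic", t)

    # (3) individual data points with depth < threshold -> missing
    total = np.where(t.allele_mask()[None, :, :], t.depths, 0).sum(axis=2)
    new_mask = (total < cfg.indiv_depth_min) & ~t.masked
    t.masked |= new_mask
    report.add_stage("Read depth per individual", t, n_masked=int(new_mask.sum()))

    # (4) individual data points with minor-allele read ratio < threshold
    d = np.where(t.allele_mask()[None, :, :], t.depths, 0)
    part = -np.sort(-d, axis=2)
    d1, d2 = part[:, :, 0].astype(float), part[:, :, 1].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(d1 + d2 > 0, d2 / (d1 + d2), 0.0)
    new_mask = (d2 >= 1) & (ratio < cfg.indiv_allele_ratio_min) & ~t.masked
    t.masked |= new_mask
    report.add_stage("Allele ratio", t, n_masked=int(new_mask.sum()))

    # (5) paralogous probes via heterozygous megagametophytes
    if sheet.megagametophyte_ids:
        bad = _paralogous_probes(t, sheet, cfg.haploid_het_fraction)
        t = t.subset_sites(~t.sites["probe_id"].isin(bad).to_numpy())
    else:
        log.warning("no megagametophytes in sheet; polymorphic-haploid stage skipped")
    report.add_stage("Polymorphic haploids", t)

    # calls for the genotype-level stages (6) and (7)
    matrix = call_genotypes(
        t, sheet,
        min_depth=cfg.indiv_depth_min,
        min_allele_ratio=cfg.indiv_allele_ratio_min,
        low_ratio_action="missing",
    )

    # (6) monomorphic across every sample (haploids included)
    observed = np.where(matrix.calls >= 0, matrix.calls, np.int8(-1))
    n_distinct = np.zeros(t.n_sites, dtype=int)
    for a in range(3):
        n_distinct += (observed == a).any(axis=(0, 2)).astype(int)
    t = t.subset_sites(n_distinct >= 2)
    matrix = matrix.subset(site_ids=t.site_ids)
    report.add_stage("Monomorphic markers", t)

    # (7) MAF floor over the putatively unrelated cohort
    cohort = cfg.maf_reference_samples or sheet.unrelated_cohort
    cohort = [c for c in cohort if c in matrix.samples]
    if not cohort:
        raise ValueError("MAF reference cohort is empty")
    maf = cohort_maf(matrix, cohort)
    t = t.subset_sites(~np.isnan(maf) & (maf >= cfg.maf_min))
    report.add_stage(f"MAF >= {cfg.maf_min}", t)

    return t, tri, report


def cohort_maf(matrix: GenotypeMatrix, cohort: list[str]) -> np.ndarray:
    """Minor-allele frequency per site from called genotypes of *cohort*.

    Counts alleles over non-missing calls (each diploid call contributes two
    alleles); sites with no calls in the cohort get NaN.
    """
    idx = matrix.sample_index(cohort)
    calls = matrix.calls[np.atleast_1d(idx)]
    valid = calls[:, :, 0] >= 0
    n_alleles = 2 * valid.sum(axis=0).astype(float)
    alt = ((calls == 1) & valid[:, :, None]).sum(axis=(0, 2)).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return np.minimum(q, 1.0 - q)


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """The quality metrics reported for both panel evaluations."""

    call_rate_per_sample: pd.Series
    call_rate_per_site: pd.Series
    mean_depth_per_site: pd.Series
    snps_per_probe: pd.Series  # index: SNPs-per-probe count; values: probe count
    maf_spectrum: pd.Series  # per-site MAF over the unrelated cohort
    haploid_het_per_probe: pd.Series
    replicate_concordance: pd.DataFrame  # sample_a, sample_b, n_shared, concordance
    missingness_vs_depth: pd.DataFrame  # depth_bin_low, depth_bin_high, n_samples, mean_missing

    def write(self, prefix) -> None:
        self.call_rate_per_sample.rename("call_rate").to_csv(f"{prefix}.sample_callrate.tsv", sep="\t")
        self.call_rate_per_site.rename("call_rate").to_frame().assign(
            mean_depth=self.mean_depth_per_site
        ).to_csv(f"{prefix}.site_metrics.tsv", sep="\t")
        self.snps_per_probe.rename("n_probes").to_csv(f"{prefix}.snps_per_probe.tsv", sep="\t")
        self.maf_spectrum.rename("maf").to_csv(f"{prefix}.maf.tsv", sep="\t")
        self.haploid_het_per_probe.rename("het_fraction").to_csv(f"{prefix}.haploid_het.tsv", sep="\t")
        self.replicate_concordance.to_csv(f"{prefix}.replicates.tsv", sep="\t", index=False)
        self.missingness_vs_depth.to_csv(f"{prefix}.missing_vs_depth.tsv", sep="\t", index=False)


_DEPTH_BINS = [0, 5, 10, 15, 20, 30, 40, 60, 80, np.inf]


def qc_report(matrix: GenotypeMatrix, table: VariantTable, sheet: SampleSheet) -> QCReport:
    """Compute the full QC metric set for a (matrix, table) pair describing
    the same sites."""
    if matrix.site_ids != table.site_ids:
        raise ValueError("matrix and table describe different sites")

    miss = matrix.missing_mask()
    crs = pd.Series(1.0 - miss.mean(axis=1), index=matrix.samples)
    crt = pd.Series(1.0 - miss.mean(axis=0), index=matrix.site_ids)
    mdepth = pd.Series(table.mean_site_depth(), index=table.site_ids)

    per_probe = table.sites.groupby("probe_id").size()
    snps_per_probe = per_probe.value_counts().sort_index()

    cohort = [c for c in sheet.unrelated_cohort if c in matrix.samples]
    maf = pd.Series(
        cohort_maf(matrix, cohort) if cohort else np.full(table.n_sites, np.nan),
        index=table.site_ids,
    )

    frac = haploid_het_site_fraction(table, sheet)
    het_probe = pd.Series(frac, index=table.sites["probe_id"].to_numpy()).groupby(level=0).max()

    codes = matrix.genotype_codes()
    rows = []
    for group, members in sheet.replicate_groups().items():
        members = [m for m in members if m in matrix.samples]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = matrix.sample_index(members[i]), matrix.sample_index(members[j])
                shared = (codes[a] >= 0) & (codes[b] >= 0)
                n = int(shared.sum())
                conc = float((codes[a][shared] == codes[b][shared]).mean()) if n else np.nan
                rows.append(
                    {"group": group, "sample_a": members[i], "sample_b": members[j],
                     "n_shared": n, "concordance": conc}
                )
    replicate_concordance = pd.DataFrame(
        rows, columns=["group", "sample_a", "sample_b", "n_shared", "concordance"]
    )

    sample_depth = table.total_depth().mean(axis=1)
    sample_missing = miss.mean(axis=1)
    bins = pd.cut(sample_depth, _DEPTH_BINS, right=False)
    mvd = (
        pd.DataFrame({"bin": bins, "missing": sample_missing})
        .groupby("bin", observed=True)["missing"]
        .agg(["size", "mean"])
        .reset_index()
    )
    mvd["depth_bin_low"] = [iv.left for iv in mvd["bin"]]
    mvd["depth_bin_high"] = [iv.right for iv in mvd["bin"]]
    mvd = mvd.rename(columns={"size": "n_samples", "mean": "mean_missing"})[
        ["depth_bin_low", "depth_bin_high", "n_samples", "mean_missing"]
    ]

    return QCReport(
        call_rate_per_sample=crs,
        call_rate_per_site=crt,
        mean_depth_per_site=mdepth,
        snps_per_probe=snps_per_probe,
        maf_spectrum=maf,
        haploid_het_per_probe=het_probe,
        replicate_concordance=replicate_concordance,
        missingness_vs_depth=mvd,
    )


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def mendelian_check(matrix: GenotypeMatrix, sheet: SampleSheet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trio and per-duo Mendelian inconsistency counts.

    A trio inconsistency is an offspring genotype not producible from one
    gamete of each parent; a duo inconsistency is a megagametophyte allele
    absent from its mother's genotype.  Sites with any missing genotype in
    the relationship are skipped.
    """
    from .parentage import _pair_compatible  # local import to avoid a cycle

    trios = sheet.trios()
    duos = sheet.duos()
    if not trios and not duos:
        raise ValueError("sheet declares no trios or duos")

    trio_rows = []
    for off, mother, father in trios:
        o = matrix.calls[matrix.sample_index(off)]
        m = matrix.calls[matrix.sample_index(mother)]
        f = matrix.calls[matrix.sample_index(father)]
        valid = (o[:, 0] >= 0) & (m[:, 0] >= 0) & (f[:, 0] >= 0)
        ok = _pair_compatible(m, f, o)
        trio_rows.append(
            {"offspring": off, "mother": mother, "father": father,
             "n_checked": int(valid.sum()), "n_inconsistent": int((valid & ~ok).sum())}
        )

    duo_rows = []
    for mega, mother in duos:
        g = matrix.calls[matrix.sample_index(mega)]
        m = matrix.calls[matrix.sample_index(mother)]
        valid = (g[:, 0] >= 0) & (m[:, 0] >= 0)
        ok = (g[:, 0] == m[:, 0]) | (g[:, 0] == m[:, 1])
        duo_rows.append(
            {"megagametophyte": mega, "mother": mother,
             "n_checked": int(valid.sum()), "n_inconsistent": int((valid & ~ok).sum())}
        )

    return (
        pd.DataFrame(trio_rows, columns=["offspring", "mother", "father", "n_checked", "n_inconsistent"]),
        pd.DataFrame(duo_rows, columns=["megagametophyte", "mother", "n_checked", "n_inconsistent"]),
    )
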