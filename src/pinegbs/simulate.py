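"""Synthetic exome-capture GBS data with the study's structure.

The generator emulates a conifer breeding-population genotyping experiment:
a cohort of putatively unrelated founder trees, full-sib families from pairs
of those founders, haploid megagametophytes (maternal seed tissue carrying a
single maternal gamete), technical replicates (ramets), negative-binomial
read depth, a small substitution-error rate, and a fraction of capture
probes that co-capture a paralogous locus and therefore make haploids look
heterozygous.

Sites are unlinked.  Missingness arises solely through the depth threshold
at calling time — low mean depth produces more sub-threshold data points.

Every function takes or threads a :class:`numpy.random.Generator`; a fixed
seed yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import SampleSheet, VariantTable

#: Fixed per-site allele universe: ref, alt, and a slot sequencing error or
#: a triallelic artifact can populate.
N_ALLELE_SLOTS = 3

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults follow the genotyping experiment the package models: 135
    putatively unrelated founders, two full-sib mapping families of 90
    offspring, one megagametophyte from each of 104 founders, technical
    replicates of the four family parents, ~60X mean depth with strong
    overdispersion, 0.2% substitution error and 5% paralogous probes.
    """

    n_unrelated: int = 135
    families: list[tuple[str, str, int]] = field(
        default_factory=lambda: [("P0001", "P0002", 90), ("P0003", "P0004", 90)]
    )
    n_mega_mothers: int = 104
    n_megagametophytes_per_mother: int = 1
    n_replicate_copies: dict[str, int] = field(
        default_factory=lambda: {"P0001": 2, "P0002": 2, "P0003": 2, "P0004": 2}
    )
    n_sites: int = 2000
    maf_distribution: tuple = ("beta", 0.25, 5.0)  # or ("uniform", lo, hi)
    mean_depth: float = 60.0
    depth_dispersion: float = 6.0  # NB size parameter; smaller = more overdispersed
    substitution_error: float = 0.002
    paralog_probe_fraction: float = 0.05
    triallelic_artifact_rate: float = 0.01
    snps_per_probe_distribution: tuple = ("geometric", 0.77)  # mean ~1.3 SNPs/probe
    probes_per_gene_p: float = 0.65  # geometric; mean ~1.5 probes/gene
    seed: int = 0

    def __post_init__(self):
        if self.n_unrelated < 2:
            raise ValueError("need at least 2 unrelated founders")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for name in ("substitution_error", "paralog_probe_fraction", "triallelic_artifact_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.substitution_error > 0.01:
            raise ValueError("substitution_error above 1% is outside the modelled regime")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("mean_depth and depth_dispersion must be positive")
        if any(n < 0 for _, _, n in self.families):
            raise ValueError("n_offspring must be >= 0")


@dataclass
class TruthSet:
    """Ground truth behind a rendered dataset.

    ``genotypes[i, j]`` holds sample *i*'s true allele-index pair at site
    *j* (haploids duplicate their single maternal allele; ploidy
    disambiguates).  ``freqs[j]`` are the true allele probabilities over the
    3-slot allele universe.
    """

    site_meta: pd.DataFrame  # site_id, probe_id, gene_id, chrom, pos, alleles
    freqs: np.ndarray  # (n_sites, 3)
    samples: list[str]
    ploidy: np.ndarray  # (n_samples,)
    genotypes: np.ndarray  # (n_samples, n_sites, 2) int8
    meta: pd.DataFrame  # sample_id, ploidy, role, family_id, mother_id, father_id, replicate_group
    paralog_probes: set[str] = field(default_factory=set)
    paralog_allele: np.ndarray | None = None  # (n_sites,) int8

    @property
    def n_sites(self) -> int:
        return len(self.site_meta)

    def sample_loc(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def to_matrix(self) -> "GenotypeMatrix":
        """The true genotypes as an error-free, complete genotype matrix."""
        from .model import GenotypeMatrix

        return GenotypeMatrix(
            samples=list(self.samples),
            site_ids=list(self.site_meta["site_id"]),
            calls=self.genotypes.copy(),
            ploidy=self.ploidy.copy(),
        )

    def true_maf(self) -> np.ndarray:
        """Minor-allele frequency per site (alt1 frequency folded at 0.5)."""
        q = self.freqs[:, 1]
        return np.minimum(q, 1.0 - q)

    def _append(self, sample_id: str, ploidy: int, genotype: np.ndarray, **meta) -> None:
        if sample_id in self.samples:
            raise ValueError(f"duplicate sample {sample_id!r}")
        self.samples.append(sample_id)
        self.ploidy = np.append(self.ploidy, np.int8(ploidy))
        self.genotypes = np.concatenate([self.genotypes, genotype[None, :, :]], axis=0)
        row = {
            "sample_id": sample_id,
            "ploidy": ploidy,
            "role": meta.get("role"),
            "family_id": meta.get("family_id"),
            "mother_id": meta.get("mother_id"),
            "father_id": meta.get("father_id"),
            "replicate_group": meta.get("replicate_group"),
        }
        self.meta = pd.concat([self.meta, pd.DataFrame([row])], ignore_index=True)

    def write(self, prefix) -> None:
        """Dump truth as tab-separated text (test/debug oracle)."""
        self.site_meta.assign(
            freq_ref=self.freqs[:, 0], freq_alt=self.freqs[:, 1], freq_extra=self.freqs[:, 2],
            paralog=self.site_meta["probe_id"].isin(self.paralog_probes),
        ).to_csv(f"{prefix}.sites.tsv", sep="\t", index=False)
        g = pd.DataFrame(
            {
                s: ["|".join(map(str, self.genotypes[i, j])) for j in range(self.n_sites)]
                for i, s in enumerate(self.samples)
            },
            index=self.site_meta["site_id"],
        )
        g.to_csv(f"{prefix}.genotypes.tsv", sep="\t")
        self.meta.to_csv(f"{prefix}.samples.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def _draw_maf(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    kind, *params = cfg.maf_distribution
    if kind == "uniform":
        lo, hi = params
        if not (0 <= lo <= hi <= 0.5):
            raise ValueError("uniform MAF bounds must satisfy 0 <= lo <= hi <= 0.5")
        return rng.uniform(lo, hi, size=cfg.n_sites) if lo < hi else np.full(cfg.n_sites, lo)
    if kind == "beta":
        a, b = params
        if a <= 0 or b <= 0:
            raise ValueError("beta MAF shape parameters must be positive")
        x = rng.beta(a, b, size=cfg.n_sites)
        return np.where(x > 0.5, 1.0 - x, x)  # fold onto (0, 0.5]
    raise ValueError(f"unknown maf_distribution kind {kind!r}")


def _make_site_meta(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign sites to probes and probes to genes, with positions on 12
    chromosomes (the species' haploid number)."""
    kind, p = cfg.snps_per_probe_distribution
    if kind != "geometric":
        raise ValueError(f"unknown snps_per_probe_distribution kind {kind!r}")
    probe_sizes = []
    total = 0
    while total < cfg.n_sites:
        k = int(rng.geometric(p))
        probe_sizes.append(k)
        total += k
    probe_sizes[-1] -= total - cfg.n_sites

    probe_of_site = np.repeat(np.arange(len(probe_sizes)), probe_sizes)
    gene_sizes = []
    total = 0
    while total < len(probe_sizes):
        k = int(rng.geometric(cfg.probes_per_gene_p))
        gene_sizes.append(k)
        total += k
    gene_sizes[-1] -= total - len(probe_sizes)
    gene_of_probe = np.repeat(np.arange(len(gene_sizes)), gene_sizes)

    chrom_of_probe = np.arange(len(probe_sizes)) % 12 + 1
    # probes laid out every 10 kb along their chromosome; SNPs inside a
    # 120 bp window
    probe_rank = np.zeros(len(probe_sizes), dtype=int)
    seen: dict[int, int] = {}
    for i, c in enumerate(chrom_of_probe):
        probe_rank[i] = seen.get(c, 0)
        seen[c] = probe_rank[i] + 1
    offsets = np.concatenate([np.sort(rng.choice(120, size=n, replace=False)) for n in probe_sizes])
    pos = probe_rank[probe_of_site] * 10_000 + 1 + offsets

    ref = _BASES[rng.integers(0, 4, size=cfg.n_sites)]
    alt1 = _BASES[(np.searchsorted(_BASES, ref) + rng.integers(1, 4, size=cfg.n_sites)) % 4]
    alt2 = _BASES[(np.searchsorted(_BASES, ref) + rng.integers(1, 4, size=cfg.n_sites)) % 4]
    alt2 = np.where(alt2 == alt1, _BASES[(np.searchsorted(_BASES, alt1) + 1) % 4], alt2)
    alt2 = np.where(alt2 == ref, _BASES[(np.searchsorted(_BASES, alt1) + 2) % 4], alt2)
    # final guard: force the three alleles distinct
    for j in np.flatnonzero((alt2 == ref) | (alt2 == alt1)):
        alt2[j] = next(b for b in _BASES if b not in (ref[j], alt1[j]))

    return pd.DataFrame(
        {
            "site_id": [f"SNP{j:06d}" for j in range(cfg.n_sites)],
            "probe_id": [f"probe{p:05d}" for p in probe_of_site],
            "gene_id": [f"gene{g:05d}" for g in gene_of_probe[probe_of_site]],
            "chrom": [f"chr{c}" for c in chrom_of_probe[probe_of_site]],
            "pos": pos,
            "alleles": [(r, a1, a2) for r, a1, a2 in zip(ref, alt1, alt2)],
        }
    )


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Draw unrelated diploid founders under Hardy-Weinberg proportions.

    Site frequencies come from ``cfg.maf_distribution`` (the alt allele is
    the minor one); a ``triallelic_artifact_rate`` fraction of sites
    segregates a rare third allele.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    site_meta = _make_site_meta(cfg, rng)
    maf = _draw_maf(cfg, rng)
    extra = np.zeros(cfg.n_sites)
    tri = rng.random(cfg.n_sites) < cfg.triallelic_artifact_rate
    extra[tri] = rng.uniform(0.01, 0.05, size=tri.sum())
    freqs = np.stack([1.0 - maf - extra, maf, extra], axis=1)
    if (freqs < -1e-12).any():
        raise ValueError("allele frequencies out of range; check maf_distribution")
    freqs = np.clip(freqs, 0.0, 1.0)
    freqs /= freqs.sum(axis=1, keepdims=True)

    names = [f"P{i + 1:04d}" for i in range(cfg.n_unrelated)]
    # two gametes per founder, iid from the site frequency vector
    cum = freqs.cumsum(axis=1)
    u = rng.random((cfg.n_unrelated, cfg.n_sites, 2))
    geno = (u[:, :, :, None] > cum[None, :, None, :]).sum(axis=3).astype(np.int8)
    geno.sort(axis=2)

    meta = pd.DataFrame(
        {
            "sample_id": names,
            "ploidy": 2,
            "role": "unrelated",
            "family_id": None,
            "mother_id": None,
            "father_id": None,
            "replicate_group": None,
        }
    )
    return TruthSet(
        site_meta=site_meta,
        freqs=freqs,
        samples=list(names),
        ploidy=np.full(cfg.n_unrelated, 2, dtype=np.int8),
        genotypes=geno,
        meta=meta,
    )


def simulate_family(
    truth: TruthSet,
    mother: str,
    father: str,
    n_offspring: int,
    rng: np.random.Generator,
) -> TruthSet:
    """Extend *truth* with a full-sib family: each offspring receives one
    uniformly chosen allele from each parent, independently per site."""
    mi, fi = truth.sample_loc(mother), truth.sample_loc(father)
    fam = f"{mother}x{father}"
    gm, gf = truth.genotypes[mi], truth.genotypes[fi]
    for parent in (mi, fi):
        truth.meta.loc[truth.meta.index[parent], "role"] = "parent"
    for k in range(n_offspring):
        pick_m = rng.integers(0, 2, size=truth.n_sites)
        pick_f = rng.integers(0, 2, size=truth.n_sites)
        g = np.stack(
            [gm[np.arange(truth.n_sites), pick_m], gf[np.arange(truth.n_sites), pick_f]],
            axis=1,
        ).astype(np.int8)
        g.sort(axis=1)
        truth._append(
            f"{fam}_o{k + 1:03d}", 2, g,
            role="offspring", family_id=fam, mother_id=mother, father_id=father,
        )
    return truth


def simulate_megagametophyte(truth: TruthSet, mother: str, rng: np.random.Generator, tag: int = 1) -> TruthSet:
    """Extend *truth* with one haploid megagametophyte: a single uniformly
    chosen maternal allele per site."""
    mi = truth.sample_loc(mother)
    gm = truth.genotypes[mi]
    pick = rng.integers(0, 2, size=truth.n_sites)
    allele = gm[np.arange(truth.n_sites), pick].astype(np.int8)
    g = np.stack([allele, allele], axis=1)
    truth._append(f"{mother}_mega{tag}", 1, g, role="megagametophyte", mother_id=mother)
    return truth


def add_replicates(truth: TruthSet, sample: str, n_copies: int) -> TruthSet:
    """Register *n_copies* additional ramets of *sample* (same true
    genotype; depth and error re-rendered independently)."""
    si = truth.sample_loc(sample)
    truth.meta.loc[truth.meta.index[si], "replicate_group"] = sample
    for k in range(n_copies):
        truth._append(
            f"{sample}_rep{k + 1}",
            int(truth.ploidy[si]),
            truth.genotypes[si].copy(),
            role="replicate",
            replicate_group=sample,
        )
    return truth


# ---------------------------------------------------------------------------
# read rendering
# ---------------------------------------------------------------------------

def render_reads(
    truth: TruthSet, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[VariantTable, SampleSheet]:
    """Render per-allele read depths from true genotypes.

    Total depth per data point is negative binomial (mean ``mean_depth``,
    size ``depth_dispersion``); reads are drawn from the true alleles
    (uniformly for heterozygotes) and each read is substituted to one of the
    other two alleles in the site's universe with probability
    ``substitution_error``.  Probes flagged paralogous receive an extra,
    independently-deep read stream from a latent duplicated locus fixed for
    one allele — the source of pseudo-heterozygous haploids.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n, S = len(truth.samples), truth.n_sites
    if n == 0 or S == 0:
        raise ValueError("truth set is empty")

    probes = truth.site_meta["probe_id"].to_numpy()
    uniq = pd.unique(probes)
    flags = rng.random(len(uniq)) < cfg.paralog_probe_fraction
    truth.paralog_probes = set(uniq[flags])
    paralog_site = np.isin(probes, list(truth.paralog_probes))
    truth.paralog_allele = np.where(
        paralog_site, rng.integers(0, 2, size=S), -1
    ).astype(np.int8)

    p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.mean_depth)
    depth = rng.negative_binomial(cfg.depth_dispersion, p_nb, size=(n, S))

    g1 = truth.genotypes[:, :, 0].astype(np.intp)
    g2 = truth.genotypes[:, :, 1].astype(np.intp)
    het = g1 != g2
    n1 = np.where(het, rng.binomial(depth, 0.5), depth)
    n2 = depth - n1
    slots = np.arange(N_ALLELE_SLOTS)
    counts = (
        n1[:, :, None] * (g1[:, :, None] == slots)
        + n2[:, :, None] * (g2[:, :, None] == slots)
    ).astype(np.int64)

    if paralog_site.any():
        extra = rng.negative_binomial(cfg.depth_dispersion, p_nb, size=(n, S))
        extra = np.where(paralog_site[None, :], extra, 0)
        counts += extra[:, :, None] * (truth.paralog_allele[None, :, None] == slots)

    e = cfg.substitution_error
    if e > 0:
        for k in range(N_ALLELE_SLOTS):
            errs = rng.binomial(counts[:, :, k], e)
            counts[:, :, k] -= errs
            others = [j for j in range(N_ALLELE_SLOTS) if j != k]
            to_first = rng.binomial(errs, 0.5)
            counts[:, :, others[0]] += to_first
            counts[:, :, others[1]] += errs - to_first

    # an allele slot is listed (the caller reports it) if the site truly
    # segregates it or any read supports it — single-read alternative
    # observations are emitted too, exactly the artifact the filtering
    # pipelines must handle.  Ref and alt1 are always listed.
    supported = (counts > 0).any(axis=0) | (truth.freqs > 0)
    supported[:, :2] = True
    n_alleles = np.where(supported[:, 2], 3, 2).astype(np.int64)

    # site-quality stand-in; 2 decimals so VCF text round-trips exactly
    qual = np.round(rng.gamma(shape=2.0, scale=30.0, size=S), 2)

    sites = truth.site_meta.copy()
    sites["qual"] = qual
    sites["n_alleles"] = n_alleles
    sites["alleles"] = [
        tuple(a[:na]) for a, na in zip(sites["alleles"], n_alleles)
    ]
    sites = sites[VariantTable.SITE_COLUMNS]

    table = VariantTable(
        samples=list(truth.samples),
        sites=sites.reset_index(drop=True),
        depths=counts.astype(np.int32),
    )
    sheet = SampleSheet(truth.meta)
    return table, sheet


def perturb_genotypes(
    matrix, error_rate: float, missing_rate: float, rng: np.random.Generator
):
    """Inject post-call genotype noise for robustness experiments.

    Each non-missing call independently becomes missing with
    ``missing_rate`` or is replaced (with ``error_rate``) by a uniformly
    chosen *different* biallelic genotype.  Returns a new matrix.
    """
    from .model import MISSING, GenotypeMatrix

    calls = matrix.calls.copy()
    valid = calls[:, :, 0] >= 0
    u = rng.random(valid.shape)
    drop = valid & (u < missing_rate)
    err = valid & ~drop & (u < missing_rate + error_rate)
    calls[drop] = MISSING
    if err.any():
        genos = np.array([[0, 0], [0, 1], [1, 1]], dtype=np.int8)
        cur = (calls[:, :, 0] == 1).astype(int) + (calls[:, :, 1] == 1)
        # uniformly one of the two other biallelic genotypes
        shift = rng.integers(1, 3, size=valid.shape)
        new = (cur + shift) % 3
        haploid = (matrix.ploidy == 1)[:, None]
        new = np.where(err & haploid, 2 - cur, new)  # haploids flip to the other homozygote
        idx = np.where(err)
        calls[idx[0], idx[1], :] = genos[new[idx]]
    return GenotypeMatrix(
        samples=list(matrix.samples),
        site_ids=list(matrix.site_ids),
        calls=calls,
        ploidy=matrix.ploidy.copy(),
    )


def simulate_dataset(cfg: SimConfig) -> tuple[VariantTable, SampleSheet, TruthSet]:
    """Full study-shaped dataset: founders, families, megagametophytes,
    replicates, rendered reads.  Deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_founders(cfg, rng)
    for mother, father, n_off in cfg.families:
        truth = simulate_family(truth, mother, father, n_off, rng)
    mothers = truth.meta.loc[truth.meta["ploidy"] == 2, "sample_id"].iloc[: cfg.n_mega_mothers]
    for mother in mothers:
        for t in range(cfg.n_megagametophytes_per_mother):
            truth = simulate_megagametophyte(truth, mother, rng, tag=t + 1)
    for sample, k in cfg.n_replicate_copies.items():
        if sample in truth.samples:
            truth = add_replicates(truth, sample, k)
    table, sheet = render_reads(truth, cfg, rng)
    return table, sheet, truth
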