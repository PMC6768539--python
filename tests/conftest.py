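"""Shared fixtures: tiny constructed datasets and small simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pinegbs.model import GenotypeMatrix, SampleSheet, VariantTable
from pinegbs.simulate import SimConfig, simulate_dataset


def make_sheet(rows: list[dict]) -> SampleSheet:
    """Build a SampleSheet from partial row dicts (defaults: diploid unrelated)."""
    full = []
    for r in rows:
        full.append(
            {
                "sample_id": r["sample_id"],
                "ploidy": r.get("ploidy", 2),
                "role": r.get("role", "unrelated"),
                "family_id": r.get("family_id"),
                "mother_id": r.get("mother_id"),
                "father_id": r.get("father_id"),
                "replicate_group": r.get("replicate_group"),
            }
        )
    return SampleSheet(pd.DataFrame(full))


def make_table(
    samples: list[str],
    site_specs: list[dict],
) -> VariantTable:
    """Build a VariantTable from site spec dicts.

    Each spec: ``{"depths": {sample: [ref, alt, ...]}, "qual": 50,
    "probe": "p1", "gene": "g1", "alleles": ("A","C")}`` — unlisted samples
    get zero depth.
    """
    max_a = max(len(s.get("alleles", ("A", "C"))) for s in site_specs)
    rows = []
    depths = np.zeros((len(samples), len(site_specs), max_a), dtype=np.int32)
    for j, s in enumerate(site_specs):
        alleles = tuple(s.get("alleles", ("A", "C")))
        rows.append(
            {
                "site_id": s.get("site_id", f"S{j}"),
                "probe_id": s.get("probe", f"p{j}"),
                "gene_id": s.get("gene", f"g{j}"),
                "chrom": s.get("chrom", "chr1"),
                "pos": s.get("pos", j + 1),
                "qual": float(s.get("qual", 50.0)),
                "alleles": alleles,
                "n_alleles": len(alleles),
            }
        )
        for sample, ad in s.get("depths", {}).items():
            depths[samples.index(sample), j, : len(ad)] = ad
    sites = pd.DataFrame(rows, columns=VariantTable.SITE_COLUMNS)
    return VariantTable(samples=list(samples), sites=sites, depths=depths)


def make_matrix(samples: list[str], genotypes: dict[str, list], ploidy=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-sample genotype lists.

    Genotypes are pairs like ``(0, 1)``, single ints for haploids, or
    ``None`` for missing.
    """
    n_sites = len(next(iter(genotypes.values())))
    calls = np.full((len(samples), n_sites, 2), -1, dtype=np.int8)
    for i, s in enumerate(samples):
        for j, g in enumerate(genotypes[s]):
            if g is None:
                continue
            if isinstance(g, int):
                calls[i, j] = (g, g)
            else:
                calls[i, j] = tuple(sorted(g))
    if ploidy is None:
        ploidy = np.full(len(samples), 2, dtype=np.int8)
    return GenotypeMatrix(
        samples=list(samples),
        site_ids=[f"S{j}" for j in range(n_sites)],
        calls=calls,
        ploidy=np.asarray(ploidy, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A realistic small dataset: error, paralogs, megagametophytes,
    replicates, two families."""
    cfg = SimConfig(
        n_sites=400,
        n_unrelated=60,
        families=[("P0001", "P0002", 25), ("P0003", "P0004", 25)],
        n_mega_mothers=30,
        seed=101,
    )
    table, sheet, truth = simulate_dataset(cfg)
    return cfg, table, sheet, truth


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free, paralog-free simulation with common alleles (the regime
    of the pedigree/clone analyses)."""
    cfg = SimConfig(
        n_sites=300,
        n_unrelated=50,
        families=[("P0001", "P0002", 20), ("P0003", "P0004", 20)],
        n_mega_mothers=20,
        maf_distribution=("uniform", 0.35, 0.5),
        substitution_error=0.0,
        paralog_probe_fraction=0.0,
        triallelic_artifact_rate=0.0,
        seed=202,
    )
    table, sheet, truth = simulate_dataset(cfg)
    return cfg, table, sheet, truth
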