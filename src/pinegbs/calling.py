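"""Genotype calling from per-allele read depths.

A data point becomes a call only when its total depth reaches ``min_depth``;
haploids get their single deepest allele, diploids the top two alleles when
the minor-read ratio supports heterozygosity.  A putative heterozygote whose
minor allele is seen but under-supported (minor ratio below
``min_allele_ratio``) is either demoted to the homozygous major call
(``low_ratio_action="demote"``, the default used during plain calling) or
set missing (``"missing"``, the behaviour of the published per-individual
allele-ratio filter stage).  A clean homozygote (zero minor reads) is never
touched by the ratio rule.
"""

from __future__ import annotations

import numpy as np

from .model import MISSING, GenotypeMatrix, SampleSheet, VariantTable


def call_genotypes(
    table: VariantTable,
    sheet: SampleSheet,
    min_depth: int = 10,
    min_allele_ratio: float = 0.1,
    low_ratio_action: str = "demote",
) -> GenotypeMatrix:
    """Call genotypes for every sample/site in *table*.

    Parameters
    ----------
    min_depth
        Total-depth floor; a data point with depth strictly below it is
        missing (depth exactly equal survives).
    min_allele_ratio
        Minor-read-ratio floor for accepting a heterozygous diploid call,
        in [0, 0.5).
    low_ratio_action
        ``"demote"`` or ``"missing"`` — fate of an observed-but-weak minor
        allele (see module docstring).
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    if not (0 <= min_allele_ratio < 0.5):
        raise ValueError("min_allele_ratio must be in [0, 0.5)")
    if low_ratio_action not in ("demote", "missing"):
        raise ValueError(f"unknown low_ratio_action {low_ratio_action!r}")

    ploidy = sheet.ploidy_for(table.samples)
    depths = np.where(table.allele_mask()[None, :, :], table.depths, 0)
    total = depths.sum(axis=2)

    # rank alleles by depth, descending; stable sort breaks depth ties in
    # favour of the lower allele index
    order = np.argsort(-depths, axis=2, kind="stable")
    top1 = order[:, :, 0]
    top2 = order[:, :, 1]
    d1 = np.take_along_axis(depths, top1[:, :, None], axis=2)[:, :, 0]
    d2 = np.take_along_axis(depths, top2[:, :, None], axis=2)[:, :, 0]

    with np.errstate(invalid="ignore", divide="ignore"):
        minor_ratio = np.where(d1 + d2 > 0, d2 / (d1 + d2), 0.0)

    callable_ = (total >= min_depth) & ~table.masked
    diploid = (ploidy == 2)[:, None]
    het = callable_ & diploid & (d2 >= 1) & (minor_ratio >= min_allele_ratio)
    weak_minor = callable_ & diploid & (d2 >= 1) & (minor_ratio < min_allele_ratio)

    calls = np.full((table.n_samples, table.n_sites, 2), MISSING, dtype=np.int8)
    # homozygous / haploid default: deepest allele in both slots
    hom = callable_.copy()
    if low_ratio_action == "missing":
        hom &= ~weak_minor
    calls[:, :, 0] = np.where(hom, top1, MISSING)
    calls[:, :, 1] = np.where(hom, top1, MISSING)
    # heterozygous diploids: sorted top-two pair
    lo = np.minimum(top1, top2)
    hi = np.maximum(top1, top2)
    calls[:, :, 0] = np.where(het, lo, calls[:, :, 0])
    calls[:, :, 1] = np.where(het, hi, calls[:, :, 1])

    return GenotypeMatrix(
        samples=list(table.samples),
        site_ids=table.site_ids,
        calls=calls,
        ploidy=ploidy,
    )
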