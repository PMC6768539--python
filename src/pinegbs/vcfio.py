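"""VCF reading and writing for pre-call variant tables.

The variant caller's output is carried as VCF 4.2 with per-sample ``AD``
(per-allele read depth) and ``DP`` (total depth) fields.  Probe and gene
identifiers ride along as ``PROBE`` / ``GENE`` INFO fields, and the VCF QUAL
column stands in for the genotyping provider's proprietary site quality
score.  Genotype calls are *not* serialised — calling from depths is a
downstream, threshold-dependent step.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .model import SampleSheet, VariantTable


def read_vcf(path, sheet: SampleSheet) -> VariantTable:
    """Read a VCF with AD/DP per-sample fields into a :class:`VariantTable`.

    Every sample column must be declared in *sheet*.  Records missing AD
    fields get zero-depth entries (the calls there will be missing at any
    depth threshold).  Allele order and 1-based positions are preserved.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    known = set(sheet.sample_ids)
    for s in samples:
        if s not in known:
            raise ValueError(f"VCF sample {s!r} is not in the sample sheet")

    rows = []
    depth_rows = []
    max_alleles = 2
    for lineno, rec in enumerate(vf.fetch() if vf.index else vf, start=1):
        try:
            alleles = tuple(rec.alleles)
            if len(alleles) < 2:
                raise ValueError("fewer than 2 alleles listed")
            max_alleles = max(max_alleles, len(alleles))
            rows.append(
                {
                    "site_id": rec.id or f"{rec.chrom}:{rec.pos}",
                    "probe_id": rec.info.get("PROBE", "."),
                    "gene_id": rec.info.get("GENE", "."),
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    # pysam exposes QUAL as float32; recover the shortest
                    # decimal so text quals round-trip exactly
                    "qual": float(np.format_float_positional(np.float32(rec.qual), unique=True, trim="-"))
                    if rec.qual is not None
                    else 0.0,
                    "alleles": alleles,
                    "n_alleles": len(alleles),
                }
            )
            per_sample = []
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or all(v is None for v in np.atleast_1d(ad)):
                    per_sample.append([0] * len(alleles))
                else:
                    per_sample.append([int(v) if v is not None else 0 for v in ad])
            depth_rows.append(per_sample)
        except Exception as exc:  # noqa: BLE001 - rewrap with line context
            raise ValueError(f"malformed VCF record at data line {lineno}: {exc}") from exc
    vf.close()
    if not rows:
        raise ValueError(f"no variant records in {path}")

    sites = pd.DataFrame(rows, columns=VariantTable.SITE_COLUMNS)
    depths = np.zeros((len(samples), len(sites), max_alleles), dtype=np.int32)
    for j, per_sample in enumerate(depth_rows):
        for i, ad in enumerate(per_sample):
            depths[i, j, : len(ad)] = ad
    return VariantTable(samples=samples, sites=sites, depths=depths)


def write_vcf(table: VariantTable, path) -> None:
    """Write a :class:`VariantTable` as an uncompressed VCF, sites sorted by
    (chrom, pos)."""
    if table.n_sites == 0:
        raise ValueError("refusing to write an empty variant table")
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=PROBE,Number=1,Type=String,Description="Capture probe id">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene model id">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Per-allele read depth">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    for chrom in pd.unique(table.sites["chrom"]):
        header.contigs.add(str(chrom))
    for s in table.samples:
        header.add_sample(s)

    order = table.sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in order:
            row = table.sites.iloc[j]
            na = int(row["n_alleles"])
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                alleles=tuple(row["alleles"])[:na],
                id=str(row["site_id"]),
                qual=float(row["qual"]),
            )
            rec.info["PROBE"] = str(row["probe_id"])
            rec.info["GENE"] = str(row["gene_id"])
            for i, s in enumerate(table.samples):
                ad = table.depths[i, j, :na]
                rec.samples[s]["AD"] = tuple(int(v) for v in ad)
                rec.samples[s]["DP"] = int(ad.sum())
            out.write(rec)
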