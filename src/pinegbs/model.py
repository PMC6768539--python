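"""Core domain types shared by every analysis stage.

The package works on three substrates:

* :class:`VariantTable` — pre-call per-SNP records carrying per-sample
  per-allele read depths and a site quality value (the raw material of the
  filtering pipelines);
* :class:`GenotypeMatrix` — called genotypes (unordered allele multisets,
  haploid or diploid, with a missing sentinel) for the downstream pedigree
  and clone analyses;
* :class:`SampleSheet` — per-sample ploidy, role, family and replicate-group
  annotations.

Genotypes are stored as sorted allele-index pairs in an ``int8`` array;
``(-1, -1)`` is the missing sentinel.  A haploid call duplicates its single
allele, and the sample's ploidy (from the sheet) disambiguates.  Phase is
never represented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Missing-genotype sentinel used throughout the calls array.
MISSING = -1

ROLES = frozenset({"parent", "offspring", "unrelated", "megagametophyte", "replicate"})

#: Roles that make up the "putatively unrelated" cohort used for MAF
#: estimation and the unrelated relationship class (the study's unrelated
#: cohort includes the mapping-population parents).
UNRELATED_ROLES = frozenset({"unrelated", "parent"})


class SampleSheet:
    """Per-sample metadata: ploidy, role, pedigree links, replicate group.

    Parameters
    ----------
    frame
        DataFrame with columns ``sample_id, ploidy, role, family_id,
        mother_id, father_id, replicate_group``.  Nullable columns use
        ``None``/NaN.
    """

    COLUMNS = [
        "sample_id",
        "ploidy",
        "role",
        "family_id",
        "mother_id",
        "father_id",
        "replicate_group",
    ]

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.COLUMNS:
            if col not in frame.columns:
                frame[col] = None
        frame = frame[self.COLUMNS]
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["ploidy"] = frame["ploidy"].astype(int)
        if frame["sample_id"].duplicated().any():
            dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id in sheet: {dup!r}")
        bad_role = ~frame["role"].isin(ROLES)
        if bad_role.any():
            raise ValueError(f"unknown role(s): {sorted(frame.loc[bad_role, 'role'].unique())}")
        bad_ploidy = ~frame["ploidy"].isin((1, 2))
        if bad_ploidy.any():
            raise ValueError("ploidy must be 1 or 2")
        mega = frame["role"] == "megagametophyte"
        if (frame.loc[mega, "ploidy"] != 1).any():
            raise ValueError("megagametophytes must have ploidy 1")
        if frame.loc[mega, "mother_id"].isna().any():
            raise ValueError("megagametophytes must have a mother_id")
        fam = frame["family_id"].notna() & (frame["role"] == "offspring")
        if frame.loc[fam, ["mother_id", "father_id"]].isna().any(axis=None):
            raise ValueError("offspring with a family_id need both parent ids")
        self.frame = frame.reset_index(drop=True)
        self._index = pd.Index(frame["sample_id"])

    # -- basic access -----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in set(self._index)

    def __len__(self) -> int:
        return len(self.frame)

    def row(self, sample_id: str) -> pd.Series:
        loc = self._index.get_loc(sample_id)
        return self.frame.iloc[loc]

    def ploidy_of(self, sample_id: str) -> int:
        return int(self.row(sample_id)["ploidy"])

    def ploidy_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        sub = self.frame.set_index("sample_id").loc[list(sample_ids), "ploidy"]
        return sub.to_numpy(dtype=np.int8)

    def ids_with_role(self, *roles: str) -> list[str]:
        return list(self.frame.loc[self.frame["role"].isin(roles), "sample_id"])

    @property
    def megagametophyte_ids(self) -> list[str]:
        return self.ids_with_role("megagametophyte")

    @property
    def unrelated_cohort(self) -> list[str]:
        """Diploid members of the putatively unrelated cohort."""
        sel = self.frame["role"].isin(UNRELATED_ROLES) & (self.frame["ploidy"] == 2)
        return list(self.frame.loc[sel, "sample_id"])

    def trios(self) -> list[tuple[str, str, str]]:
        """(offspring, mother, father) triples where all three are in the sheet."""
        ids = set(self.sample_ids)
        out = []
        off = self.frame[(self.frame["role"] == "offspring")]
        for _, r in off.iterrows():
            if r["mother_id"] in ids and r["father_id"] in ids:
                out.append((r["sample_id"], str(r["mother_id"]), str(r["father_id"])))
        return out

    def duos(self) -> list[tuple[str, str]]:
        """(megagametophyte, mother) pairs where the mother is present."""
        ids = set(self.sample_ids)
        out = []
        for _, r in self.frame[self.frame["role"] == "megagametophyte"].iterrows():
            if r["mother_id"] in ids:
                out.append((r["sample_id"], str(r["mother_id"])))
        return out

    def replicate_groups(self) -> dict[str, list[str]]:
        grp = self.frame.dropna(subset=["replicate_group"])
        return {k: list(v) for k, v in grp.groupby("replicate_group")["sample_id"]}

    # -- text round trip ---------------------------------------------------
    @classmethod
    def read(cls, path) -> "SampleSheet":
        frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=[""])
        return cls(frame)

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="")

    def __eq__(self, other) -> bool:
        if not isinstance(other, SampleSheet):
            return NotImplemented
        a = self.frame.fillna("")
        b = other.frame.fillna("")
        return a.equals(b)


@dataclass
class VariantTable:
    """Pre-call variant records: site metadata plus a depth tensor.

    ``depths[i, j, k]`` is the read depth for sample ``i`` at site ``j`` of
    allele ``k`` (allele 0 = reference).  Sites may list different numbers of
    alleles; ``n_alleles`` gives each site's count and trailing positions are
    zero-padded.  ``masked`` flags data points forced missing by the 49K
    per-individual stages — their depths are retained so that depth
    statistics stay reproducible, but genotype calling treats them as
    missing.
    """

    samples: list[str]
    sites: pd.DataFrame  # site_id, probe_id, gene_id, chrom, pos, qual, alleles, n_alleles
    depths: np.ndarray  # (n_samples, n_sites, max_alleles) int32
    masked: np.ndarray | None = None  # (n_samples, n_sites) bool

    SITE_COLUMNS = ["site_id", "probe_id", "gene_id", "chrom", "pos", "qual", "alleles", "n_alleles"]

    def __post_init__(self):
        if self.masked is None:
            self.masked = np.zeros(self.depths.shape[:2], dtype=bool)
        if self.depths.shape[0] != len(self.samples):
            raise ValueError("depth tensor does not match sample list")
        if self.depths.shape[1] != len(self.sites):
            raise ValueError("depth tensor does not match site table")
        if (self.sites["pos"] < 1).any():
            raise ValueError("positions are 1-based; pos >= 1 required")
        if (self.sites["n_alleles"] < 2).any():
            raise ValueError("every site must list at least 2 alleles")

    # -- shapes ------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])

    # -- derived quantities ------------------------------------------------
    def total_depth(self) -> np.ndarray:
        """Per sample/site total read depth, (n_samples, n_sites)."""
        return self.depths.sum(axis=2)

    def mean_site_depth(self) -> np.ndarray:
        """Mean total depth per site across all samples (raw, mask ignored)."""
        return self.total_depth().mean(axis=0)

    def allele_mask(self) -> np.ndarray:
        """(n_sites, max_alleles) bool — which allele slots are listed."""
        arange = np.arange(self.depths.shape[2])
        return arange[None, :] < self.sites["n_alleles"].to_numpy()[:, None]

    # -- manipulation ------------------------------------------------------
    def subset_sites(self, keep: np.ndarray | Sequence[int]) -> "VariantTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return VariantTable(
            samples=list(self.samples),
            sites=self.sites.iloc[keep].reset_index(drop=True),
            depths=self.depths[:, keep, :],
            masked=self.masked[:, keep],
        )

    def sample_index(self, sample_ids: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.samples)
        locs = idx.get_indexer(list(sample_ids))
        if (locs < 0).any():
            missing = [s for s, l in zip(sample_ids, locs) if l < 0]
            raise KeyError(f"samples not in table: {missing}")
        return locs

    def copy(self) -> "VariantTable":
        return VariantTable(
            samples=list(self.samples),
            sites=self.sites.copy(),
            depths=self.depths.copy(),
            masked=self.masked.copy(),
        )

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.samples == other.samples
            and self.sites.reset_index(drop=True).equals(other.sites.reset_index(drop=True))
            and np.array_equal(self.depths, other.depths)
            and np.array_equal(self.masked, other.masked)
        )


@dataclass
class GenotypeMatrix:
    """Called genotypes: samples x sites grid of unordered allele pairs.

    ``calls[i, j]`` is a sorted pair of allele indices; ``(-1, -1)`` is
    missing.  Haploid samples duplicate their single allele; ``ploidy``
    (one entry per sample) records which samples those are.
    """

    samples: list[str]
    site_ids: list[str]
    calls: np.ndarray  # (n_samples, n_sites, 2) int8
    ploidy: np.ndarray  # (n_samples,) int8

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.site_ids), 2):
            raise ValueError("calls shape does not match sample/site lists")
        if len(self.ploidy) != len(self.samples):
            raise ValueError("ploidy vector does not match sample list")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def sample_index(self, sample_ids: Sequence[str] | str) -> np.ndarray | int:
        idx = pd.Index(self.samples)
        if isinstance(sample_ids, str):
            return int(idx.get_loc(sample_ids))
        locs = idx.get_indexer(list(sample_ids))
        if (locs < 0).any():
            missing = [s for s, l in zip(sample_ids, locs) if l < 0]
            raise KeyError(f"samples not in matrix: {missing}")
        return locs

    def site_index(self, site_ids: Sequence[str]) -> np.ndarray:
        idx = pd.Index(self.site_ids)
        locs = idx.get_indexer(list(site_ids))
        if (locs < 0).any():
            missing = [s for s, l in zip(site_ids, locs) if l < 0]
            raise KeyError(f"sites not in matrix: {missing}")
        return locs

    def missing_mask(self) -> np.ndarray:
        """(n_samples, n_sites) bool — True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage (count of allele 1) as float, NaN where missing
        or where a call carries an allele outside {0, 1}."""
        d = (self.calls == 1).sum(axis=2).astype(float)
        bad = (self.calls > 1).any(axis=2) | self.missing_mask()
        d[bad] = np.nan
        return d

    def call_rate_per_sample(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def call_rate_per_site(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def genotype_codes(self) -> np.ndarray:
        """Integer code per call usable for equality tests; -1 = missing."""
        code = self.calls[:, :, 0].astype(np.int16) * 8 + self.calls[:, :, 1]
        code[self.missing_mask()] = -1
        return code

    def subset(self, sample_ids: Sequence[str] | None = None, site_ids: Sequence[str] | None = None) -> "GenotypeMatrix":
        si = self.sample_index(sample_ids) if sample_ids is not None else np.arange(self.n_samples)
        ti = self.site_index(site_ids) if site_ids is not None else np.arange(self.n_sites)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in np.atleast_1d(si)],
            site_ids=[self.site_ids[j] for j in np.atleast_1d(ti)],
            calls=self.calls[np.ix_(np.atleast_1d(si), np.atleast_1d(ti))],
            ploidy=self.ploidy[np.atleast_1d(si)],
        )


@dataclass
class Panel:
    """An ordered SNP-id list used for parentage / clone analyses."""

    snp_ids: list[str]
    label: str = "panel"

    def __post_init__(self):
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"panel {self.label!r} contains duplicate SNP ids")

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __iter__(self):
        return iter(self.snp_ids)

    @classmethod
    def read(cls, path, label: str | None = None) -> "Panel":
        with open(path) as fh:
            ids = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
        return cls(snp_ids=ids, label=label or str(path))

    def write(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            for sid in self.snp_ids:
                fh.write(sid + "\n")


@dataclass
class FilterReport:
    """Per-stage survival counts in the genes / probes / SNPs shape.

    ``n_datapoints_masked`` tracks the per-individual stages that blank data
    points without removing sites (those rows keep their site counts
    unchanged, so site counts alone would hide their effect).
    """

    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, table: VariantTable, n_masked: int = 0) -> None:
        row = {
            "stage": name,
            "n_genes": int(table.sites["gene_id"].nunique()),
            "n_probes": int(table.sites["probe_id"].nunique()),
            "n_snps": int(table.n_sites),
            "n_datapoints_masked": int(n_masked),
        }
        if self.stages:
            prev = self.stages[-1]
            removed = prev["n_snps"] - row["n_snps"]
            if removed or n_masked:
                logging.getLogger("pinegbs.filtering").info(
                    "stage %r: removed %d SNPs (%d probes, %d genes), masked %d data points",
                    name, removed, prev["n_probes"] - row["n_probes"],
                    prev["n_genes"] - row["n_genes"], n_masked,
                )
        self.stages.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_genes", "n_probes", "n_snps", "n_datapoints_masked"])

    def is_monotone(self) -> bool:
        f = self.to_frame()
        return bool(
            all(f[c].is_monotonic_decreasing for c in ("n_genes", "n_probes", "n_snps"))
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "FilterReport":
        f = pd.read_csv(path, sep="\t")
        rep = cls()
        rep.stages = f.to_dict("records")
        return rep


def sorted_pair(a: int, b: int) -> tuple[int, int]:
    """Canonical (unordered) representation of a diploid genotype."""
    return (a, b) if a <= b else (b, a)
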