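"""Clone identification by pairwise genotype mismatch.

Two samples are compared SNP-by-SNP over a panel: a SNP is comparable when
both genotypes are non-missing, and a mismatch when the unordered allele
multisets differ (a heterozygote versus either homozygote is one mismatch —
no allele-sharing partial credit).  Pairs with too few comparable SNPs are
flagged excluded.  Mismatch percentages are profiled per declared
relationship class (ramet, full-sib, parent-offspring, unrelated), and
panels are ranked by the *gap statistic*: the class separation

    gap = (minimum full-sib mismatch %) - (maximum ramet mismatch %),

which measures how safely a panel distinguishes true clones from their
closest relatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenotypeMatrix, Panel, SampleSheet, UNRELATED_ROLES

RELATIONSHIPS = ("ramet", "full-sib", "parent-offspring", "unrelated")


@dataclass
class PairMismatch:
    sample_a: str
    sample_b: str
    relationship: str
    n_comparable: int
    n_mismatch: int
    included: bool

    @property
    def pct_mismatch(self) -> float:
        if self.n_comparable == 0:
            return float("nan")
        return 100.0 * self.n_mismatch / self.n_comparable


def default_min_comparable(panel_size: int) -> int:
    """The published comparability floor (80 of 110), scaled proportionally
    to other panel sizes."""
    return int(np.ceil(panel_size * 80 / 110))


def relationship_of(a: str, b: str, sheet: SampleSheet) -> str:
    """Declared relationship class of a sample pair.

    Precedence: ramet (shared replicate group) > full-sib (offspring of the
    same family) > parent-offspring (one is the other's declared parent) >
    unrelated (both in the putatively unrelated cohort); anything else is
    ``"other"`` and excluded from the printed classes.
    """
    ra, rb = sheet.row(a), sheet.row(b)
    ga, gb = ra["replicate_group"], rb["replicate_group"]
    if pd.notna(ga) and pd.notna(gb) and ga == gb:
        return "ramet"
    fa, fb = ra["family_id"], rb["family_id"]
    if (
        pd.notna(fa) and pd.notna(fb) and fa == fb
        and ra["role"] == "offspring" and rb["role"] == "offspring"
    ):
        return "full-sib"
    if a in (rb["mother_id"], rb["father_id"]) or b in (ra["mother_id"], ra["father_id"]):
        return "parent-offspring"
    if ra["role"] in UNRELATED_ROLES and rb["role"] in UNRELATED_ROLES:
        return "unrelated"
    return "other"


def pairwise_mismatch(
    a: str,
    b: str,
    panel: Panel,
    matrix: GenotypeMatrix,
    min_comparable: int | None = None,
    sheet: SampleSheet | None = None,
) -> PairMismatch:
    """Mismatch count and percentage for one sample pair over *panel*."""
    if min_comparable is None:
        min_comparable = default_min_comparable(len(panel))
    sidx = matrix.site_index(panel.snp_ids)
    codes = matrix.genotype_codes()
    ca = codes[matrix.sample_index(a)][sidx]
    cb = codes[matrix.sample_index(b)][sidx]
    comparable = (ca >= 0) & (cb >= 0)
    mism = comparable & (ca != cb)
    rel = relationship_of(a, b, sheet) if sheet is not None else "other"
    n_comp = int(comparable.sum())
    return PairMismatch(
        sample_a=a,
        sample_b=b,
        relationship=rel,
        n_comparable=n_comp,
        n_mismatch=int(mism.sum()),
        included=n_comp >= min_comparable,
    )


def _class_pairs(sheet: SampleSheet, matrix: GenotypeMatrix) -> list[tuple[str, str, str]]:
    """All diploid within-class pairs: (sample_a, sample_b, relationship)."""
    present = set(matrix.samples)
    diploid = {
        s for s, p in zip(matrix.samples, matrix.ploidy) if p == 2
    }

    pairs: list[tuple[str, str, str]] = []

    for members in sheet.replicate_groups().values():
        members = [m for m in members if m in present and m in diploid]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j], "ramet"))

    fam = sheet.frame[(sheet.frame["role"] == "offspring") & sheet.frame["family_id"].notna()]
    for _, group in fam.groupby("family_id"):
        members = [m for m in group["sample_id"] if m in present and m in diploid]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j], "full-sib"))

    for _, r in sheet.frame.iterrows():
        child = r["sample_id"]
        if child not in present or child not in diploid:
            continue
        for parent in (r["mother_id"], r["father_id"]):
            if pd.notna(parent) and parent in present and parent in diploid:
                pairs.append((parent, child, "parent-offspring"))

    cohort = [s for s in sheet.unrelated_cohort if s in present]
    for i in range(len(cohort)):
        for j in range(i + 1, len(cohort)):
            pairs.append((cohort[i], cohort[j], "unrelated"))

    return pairs


class _PairMismatchEngine:
    """Pooled mismatch matrices over a union SNP list: panel profiles are
    column sums, so ranking 60 panels reuses one pass over the data."""

    def __init__(self, matrix: GenotypeMatrix, sheet: SampleSheet, snp_ids: list[str]):
        self.pairs = _class_pairs(sheet, matrix)
        self.snp_ids = list(snp_ids)
        self._col = {s: j for j, s in enumerate(self.snp_ids)}
        codes = matrix.genotype_codes()[:, matrix.site_index(self.snp_ids)]
        ia = matrix.sample_index([p[0] for p in self.pairs])
        ib = matrix.sample_index([p[1] for p in self.pairs])
        ca, cb = codes[np.atleast_1d(ia)], codes[np.atleast_1d(ib)]
        self.comparable = (ca >= 0) & (cb >= 0)  # (n_pairs, U)
        self.mismatch = self.comparable & (ca != cb)

    def profile(self, panel: Panel, min_comparable: int | None) -> pd.DataFrame:
        if min_comparable is None:
            min_comparable = default_min_comparable(len(panel))
        cols = np.asarray([self._col[s] for s in panel.snp_ids], dtype=int)
        comp = self.comparable[:, cols].sum(axis=1)
        mism = self.mismatch[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(comp > 0, 100.0 * mism / np.maximum(comp, 1), np.nan)
        return pd.DataFrame(
            {
                "sample_a": [p[0] for p in self.pairs],
                "sample_b": [p[1] for p in self.pairs],
                "relationship": [p[2] for p in self.pairs],
                "n_comparable": comp,
                "n_mismatch": mism,
                "pct_mismatch": pct,
                "included": comp >= min_comparable,
            }
        )


def pair_table(
    panel: Panel,
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    min_comparable: int | None = None,
) -> pd.DataFrame:
    """Long-format mismatch table for every within-class pair over *panel*."""
    return _PairMismatchEngine(matrix, sheet, panel.snp_ids).profile(panel, min_comparable)


def class_profiles(
    panel: Panel,
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    min_comparable: int | None = None,
) -> pd.DataFrame:
    """Per-class min/mean/max mismatch percentage over included pairs.

    Classes with no included pairs are reported with NaN statistics and a
    zero count rather than failing.
    """
    t = pair_table(panel, matrix, sheet, min_comparable)
    inc = t[t["included"]]
    rows = []
    for rel in RELATIONSHIPS:
        sub = inc[inc["relationship"] == rel]["pct_mismatch"]
        rows.append(
            {
                "relationship": rel,
                "n_pairs": len(sub),
                "min_pct": sub.min() if len(sub) else np.nan,
                "mean_pct": sub.mean() if len(sub) else np.nan,
                "max_pct": sub.max() if len(sub) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def rank_panels_by_gap(
    panels: list[Panel],
    matrix: GenotypeMatrix,
    sheet: SampleSheet,
    min_comparable: int | None = None,
) -> pd.DataFrame:
    """Rank panels by the ramet/full-sib gap (descending; ties by label).

    Also reports the analogous gaps against the parent-offspring and
    unrelated classes.  A negative gap means the ramet and relative
    mismatch profiles overlap for that panel.
    """
    if not panels:
        raise ValueError("need at least one panel")
    union: list[str] = []
    seen = set()
    for p in panels:
        for s in p.snp_ids:
            if s not in seen:
                seen.add(s)
                union.append(s)
    engine = _PairMismatchEngine(matrix, sheet, union)
    rows = []
    for p in panels:
        prof = engine.profile(p, min_comparable).query("included")
        by = {rel: prof[prof["relationship"] == rel]["pct_mismatch"] for rel in RELATIONSHIPS}
        ramet_max = by["ramet"].max() if len(by["ramet"]) else np.nan
        row = {"panel": p.label, "ramet_max_pct": ramet_max}
        for rel, col in (
            ("full-sib", "gap_fullsib"),
            ("parent-offspring", "gap_parent_offspring"),
            ("unrelated", "gap_unrelated"),
        ):
            rel_min = by[rel].min() if len(by[rel]) else np.nan
            row[f"{rel}_min_pct".replace("-", "_")] = rel_min
            row[col] = rel_min - ramet_max
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["gap_fullsib", "panel"], ascending=[False, True], kind="stable"
    )
    return out.reset_index(drop=True)
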