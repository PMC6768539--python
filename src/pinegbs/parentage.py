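"""Exclusion-analysis parentage assignment.

A trio (offspring + two candidate parents) is scored by counting
*exclusions*: panel SNPs at which the offspring's genotype cannot be formed
by one gamete from each candidate parent.  SNPs with any missing genotype
among the three are skipped and do not count as comparable.  Over all
candidate parent pairs, the pair with the fewest exclusions is the assigned
parentage; ties are reported as ambiguous, never silently broken.

The panel-size reduction experiment re-scores every offspring against every
pair for each random panel and each nested prefix truncation, tabulating
true-trio / false-trio / ambiguous / dropped counts against the declared
pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenotypeMatrix, Panel, SampleSheet, sorted_pair


@dataclass
class TrioResult:
    offspring_id: str
    parent_pair: tuple[str, str]  # unordered; stored sorted
    n_exclusions: int
    n_comparable_snps: int
    is_minimal: bool = False
    margin: int | None = None  # runner-up exclusions minus this pair's

    def __post_init__(self):
        if self.n_exclusions > self.n_comparable_snps:
            raise ValueError("exclusions cannot exceed comparable SNPs")


def compatible_offspring_genotypes(
    p1: tuple[int, int] | None, p2: tuple[int, int] | None
) -> set[tuple[int, int]]:
    """Unordered offspring genotypes formable from one gamete of each parent.

    Missing parents (``None`` or containing the missing sentinel) yield the
    empty set — the locus is non-informative.  Het x het realises the
    maximum of 4 ordered gamete combinations (3 distinct unordered
    genotypes).
    """
    if p1 is None or p2 is None:
        return set()
    if MISSING in p1 or MISSING in p2:
        return set()
    return {sorted_pair(a, b) for a in p1 for b in p2}


def _pair_compatible(m: np.ndarray, f: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Vectorised Mendelian compatibility.

    ``m``, ``f``, ``o`` are (..., 2) sorted allele-pair arrays (broadcastable);
    returns a boolean array: the offspring pair equals one of the four
    (sorted) gamete combinations.  Missing entries yield False — callers
    must combine with their own validity mask.
    """
    ok = np.zeros(np.broadcast_shapes(m.shape[:-1], f.shape[:-1], o.shape[:-1]), dtype=bool)
    for a in (0, 1):
        for b in (0, 1):
            ga, gb = m[..., a], f[..., b]
            lo, hi = np.minimum(ga, gb), np.maximum(ga, gb)
            ok |= (lo == o[..., 0]) & (hi == o[..., 1])
    return ok


def trio_exclusions(
    offspring: str,
    p1: str,
    p2: str,
    panel: Panel,
    matrix: GenotypeMatrix,
) -> TrioResult:
    """Count exclusions for one candidate trio over *panel*."""
    sidx = matrix.site_index(panel.snp_ids)
    o = matrix.calls[matrix.sample_index(offspring)][sidx]
    a = matrix.calls[matrix.sample_index(p1)][sidx]
    b = matrix.calls[matrix.sample_index(p2)][sidx]
    valid = (o[:, 0] >= 0) & (a[:, 0] >= 0) & (b[:, 0] >= 0)
    ok = _pair_compatible(a, b, o)
    return TrioResult(
        offspring_id=offspring,
        parent_pair=tuple(sorted((p1, p2))),
        n_exclusions=int((valid & ~ok).sum()),
        n_comparable_snps=int(valid.sum()),
    )


class ExclusionEngine:
    """Precomputed pairwise exclusion machinery for one offspring cohort.

    For an offspring, builds the (candidate-pair x SNP) exclusion and
    comparability matrices over a pooled SNP list once; panel scores and
    nested truncations are then cheap column sums.  This is what makes the
    60-panel experiments tractable at the study's candidate count.
    """

    def __init__(
        self,
        matrix: GenotypeMatrix,
        candidates: list[str],
        snp_ids: list[str],
        allow_self: bool = False,
    ):
        self.matrix = matrix
        self.candidates = list(candidates)
        self.snp_ids = list(snp_ids)
        self.allow_self = allow_self
        cidx = matrix.sample_index(self.candidates)
        sidx = matrix.site_index(self.snp_ids)
        self._cand_calls = matrix.calls[np.ix_(np.atleast_1d(cidx), sidx)]  # (C, U, 2)
        self._cand_valid = self._cand_calls[:, :, 0] >= 0
        k = 0 if allow_self else 1
        self._iu, self._ju = np.triu_indices(len(self.candidates), k=k)
        self._col = {s: j for j, s in enumerate(self.snp_ids)}
        self._p1 = self._cand_calls[self._iu]  # (P, U, 2)
        self._p2 = self._cand_calls[self._ju]
        self._pair_valid = self._cand_valid[self._iu] & self._cand_valid[self._ju]

    @property
    def pair_index(self) -> list[tuple[str, str]]:
        return [
            (self.candidates[i], self.candidates[j]) for i, j in zip(self._iu, self._ju)
        ]

    def offspring_matrices(self, offspring: str) -> tuple[np.ndarray, np.ndarray]:
        """(exclusion, comparable) boolean matrices, shape (n_pairs, n_snps)."""
        o = self.matrix.calls[self.matrix.sample_index(offspring)][
            self.matrix.site_index(self.snp_ids)
        ]
        comparable = self._pair_valid & (o[None, :, 0] >= 0)
        ok = _pair_compatible(self._p1, self._p2, o[None, :, :])
        return comparable & ~ok, comparable

    def columns(self, snp_ids: list[str]) -> np.ndarray:
        return np.asarray([self._col[s] for s in snp_ids], dtype=int)


def assign_parents(
    offspring: str,
    candidates: list[str],
    panel: Panel,
    matrix: GenotypeMatrix,
    allow_self: bool = False,
    rank_by: str = "count",
) -> list[TrioResult]:
    """Score every unordered candidate pair for *offspring* over *panel*.

    Returns results sorted by exclusion count (ties by pair name); all
    minimal pairs carry ``is_minimal=True`` and the margin to the runner-up
    exclusion count (0 under a tie).  More than one minimal pair means the
    assignment is ambiguous.

    ``rank_by="count"`` ranks by raw exclusion counts (the published
    ranking); ``"rate"`` ranks by exclusions per comparable SNP, which can
    matter when missing parent genotypes make comparable counts differ
    between candidate pairs.
    """
    if len(candidates) < (1 if allow_self else 2):
        raise ValueError("need at least two candidates (or one with allow_self)")
    if rank_by not in ("count", "rate"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    engine = ExclusionEngine(matrix, candidates, panel.snp_ids, allow_self=allow_self)
    excl, comp = engine.offspring_matrices(offspring)
    e = excl.sum(axis=1)
    c = comp.sum(axis=1)
    if rank_by == "rate":
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.where(c > 0, e / np.maximum(c, 1), np.inf)
    else:
        score = e
    order = np.lexsort((engine._ju, engine._iu, score))
    smin = score.min() if len(score) else 0
    s_sorted = np.sort(score)
    emin = int(e[order[0]]) if len(order) else 0
    # runner-up counts multiplicity: a tie at the minimum gives margin 0
    runner_e = int(e[order[1]]) if len(order) > 1 else None
    results = []
    for idx in order:
        pair = tuple(sorted((engine.candidates[engine._iu[idx]], engine.candidates[engine._ju[idx]])))
        minimal = score[idx] == smin
        results.append(
            TrioResult(
                offspring_id=offspring,
                parent_pair=pair,
                n_exclusions=int(e[idx]),
                n_comparable_snps=int(c[idx]),
                is_minimal=minimal,
                margin=(runner_e - emin) if (minimal and runner_e is not None) else None,
            )
        )
    return results


def _classify(
    e: np.ndarray,
    pairs: list[tuple[str, str]],
    declared: tuple[str, str],
) -> str:
    emin = e.min()
    winners = np.flatnonzero(e == emin)
    if len(winners) > 1:
        return "ambiguous"
    best = tuple(sorted(pairs[winners[0]]))
    return "true-trio" if best == tuple(sorted(declared)) else "false-trio"


def reduction_experiment(
    trios: list[tuple[str, str, str]],
    candidates: list[str],
    panels: list[Panel],
    sizes: list[int],
    matrix: GenotypeMatrix,
    comparable_floor_frac: float = 0.5,
    allow_self: bool = False,
) -> pd.DataFrame:
    """Panel-size reduction experiment.

    For every panel and nested prefix size, assigns each offspring in
    *trios* (``(offspring, mother, father)``) against all candidate pairs
    and tabulates the outcome versus the declared parents.  An offspring is
    dropped for a given (panel, size) when its own non-missing call count
    within the truncated panel falls below ``comparable_floor_frac x size``
    (the published behaviour for low-call-rate individuals).

    Returns a long-format frame: panel, size, n_offspring, n_true, n_false,
    n_ambiguous, n_dropped.
    """
    union: list[str] = []
    seen = set()
    for p in panels:
        for s in p.snp_ids:
            if s not in seen:
                seen.add(s)
                union.append(s)
    engine = ExclusionEngine(matrix, candidates, union, allow_self=allow_self)
    pairs = engine.pair_index

    counts = {
        (p.label, k): {"true-trio": 0, "false-trio": 0, "ambiguous": 0, "dropped": 0}
        for p in panels
        for k in sizes
    }
    ks = sorted(set(sizes))
    kmax = ks[-1]
    starts = np.asarray([0] + ks[:-1], dtype=int)  # prefix-segment boundaries
    miss = matrix.missing_mask()
    for off, mother, father in trios:
        excl, _comp = engine.offspring_matrices(off)
        orow = ~miss[matrix.sample_index(off)]
        for p in panels:
            cols = engine.columns(p.snp_ids)
            x = excl[:, cols[:kmax]].astype(np.uint8)
            # nested-prefix sums in one pass: segment sums then cumsum
            e_at = np.add.reduceat(x, starts, axis=1).astype(np.int32).cumsum(axis=1)
            o_called = orow[matrix.site_index(p.snp_ids)][:kmax]
            o_at = np.add.reduceat(o_called.astype(np.uint8), starts).astype(int).cumsum()
            for ki, k in enumerate(ks):
                if int(o_at[ki]) < comparable_floor_frac * k:
                    counts[(p.label, k)]["dropped"] += 1
                    continue
                counts[(p.label, k)][_classify(e_at[:, ki], pairs, (mother, father))] += 1

    rows = [
        {
            "panel": label,
            "size": k,
            "n_offspring": len(trios),
            "n_true": v["true-trio"],
            "n_false": v["false-trio"],
            "n_ambiguous": v["ambiguous"],
            "n_dropped": v["dropped"],
        }
        for (label, k), v in counts.items()
    ]
    return pd.DataFrame(rows).sort_values(["panel", "size"], ascending=[True, False]).reset_index(drop=True)
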