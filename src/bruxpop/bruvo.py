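"""Bruvo's stepwise-mutation-aware genotype distance for mixed ploidy.

Alleles are repeat counts; the distance between two alleles is
``1 - 2**(-|x - y|)``, so a single mutation step costs 0.5 and distant
alleles saturate towards 1.  Genotype (allele-set) distances minimise the
mean allele distance over a perfect matching of the two sets.  Sets of
unequal size are reconciled by the genome *addition* model (the smaller set
is padded with copies of its own alleles, averaging over all distinct
paddings), the genome *loss* model (padded with alleles from the larger
set), or an *infinity* fallback (phantom alleles at distance 1); enabled
models are averaged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotype_io import MISSING, MicrosatDataset

__all__ = [
    "BruvoModel",
    "DistanceMatrix",
    "allele_distance",
    "locus_distance",
    "distance_matrix",
    "impute_nearest",
]

MAX_SET = 5


@dataclass(frozen=True)
class BruvoModel:
    """Treatment of unequal allele counts: genome addition and/or loss,
    or the infinity fallback (pad with distance-1 phantom alleles)."""

    addition: bool = True
    loss: bool = True
    infinity: bool = False

    def __post_init__(self) -> None:
        if not (self.addition or self.loss or self.infinity):
            raise ValueError("at least one unequal-ploidy model must be enabled")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix keyed by isolate ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.d, checks=False)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids=list(ids), d=self.d[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ids=[str(i) for i in df.index], d=df.to_numpy(dtype=float))

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for name, row in zip(self.ids, self.d):
                fh.write(name[:10].ljust(12))
                fh.write(" ".join(f"{v:.6f}" for v in row))
                fh.write("\n")


def allele_distance(x: int, y: int) -> float:
    """Distance between two alleles under the stepwise mutation model."""
    if x != int(x) or y != int(y):
        raise ValueError("repeat counts must be integers")
    if x < 0 or y < 0:
        raise ValueError("repeat counts must be non-negative")
    return 1.0 - 2.0 ** (-abs(int(x) - int(y)))


def _matched_mean(a: tuple, b: tuple) -> float:
    """Minimum mean allele distance over perfect matchings of equal-size tuples."""
    k = len(a)
    cost = np.empty((k, k))
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            cost[i, j] = 1.0 - 2.0 ** (-abs(x - y))
    ri, ci = linear_sum_assignment(cost)
    return float(cost[ri, ci].sum()) / k


@lru_cache(maxsize=1_000_000)
def _locus_distance_cached(a: tuple, b: tuple, model: BruvoModel) -> float:
    ka, kb = len(a), len(b)
    if ka == kb:
        return _matched_mean(a, b)
    small, large = (a, b) if ka < kb else (b, a)
    pad = len(large) - len(small)
    branches = []
    if model.addition:
        vals = [
            _matched_mean(small + extra, large)
            for extra in itertools.combinations_with_replacement(small, pad)
        ]
        branches.append(float(np.mean(vals)))
    if model.loss:
        vals = [
            _matched_mean(small + extra, large)
            for extra in itertools.combinations_with_replacement(large, pad)
        ]
        branches.append(float(np.mean(vals)))
    if model.infinity:
        branches.append(_infinity_distance(small, large))
    return float(np.mean(branches))


def _infinity_distance(small: tuple, large: tuple) -> float:
    """Pad the smaller set with phantom alleles at distance 1."""
    k = len(large)
    cost = np.ones((k, k))
    for i, x in enumerate(small):
        for j, y in enumerate(large):
            cost[i, j] = 1.0 - 2.0 ** (-abs(x - y))
    ri, ci = linear_sum_assignment(cost)
    return float(cost[ri, ci].sum()) / k


def locus_distance(A: frozenset, B: frozenset, model: Optional[BruvoModel] = None) -> float:
    """Bruvo distance between two allele sets at one locus (both called)."""
    if A is MISSING or B is MISSING:
        raise ValueError("locus_distance requires called allele sets")
    if len(A) > MAX_SET or len(B) > MAX_SET:
        raise ValueError(f"allele sets larger than {MAX_SET} are not supported")
    if model is None:
        model = BruvoModel()
    a = tuple(sorted(int(x) for x in A))
    b = tuple(sorted(int(x) for x in B))
    if any(x < 0 for x in a + b):
        raise ValueError("repeat counts must be non-negative")
    if a > b:  # canonical order for the cache; the distance is symmetric
        a, b = b, a
    return _locus_distance_cached(a, b, model)


def distance_matrix(ds: MicrosatDataset, model: Optional[BruvoModel] = None) -> DistanceMatrix:
    """Pairwise Bruvo distances: mean locus distance over mutually called loci."""
    if model is None:
        model = BruvoModel()
    n = ds.n_isolates
    d = np.zeros((n, n))
    calls = ds.calls
    nl = ds.n_loci
    for i in range(n):
        ci = calls[i]
        for j in range(i + 1, n):
            cj = calls[j]
            tot = 0.0
            m = 0
            for l in range(nl):
                a, b = ci[l], cj[l]
                if a is MISSING or b is MISSING:
                    continue
                tot += locus_distance(a, b, model)
                m += 1
            if m == 0:
                raise ValueError(
                    f"isolates {ds.isolate_ids[i]} and {ds.isolate_ids[j]} share "
                    f"no called locus; impute first"
                )
            d[i, j] = d[j, i] = tot / m
    return DistanceMatrix(ids=ds.isolate_ids, d=d)


def impute_nearest(ds: MicrosatDataset, model: Optional[BruvoModel] = None) -> MicrosatDataset:
    """Fill MISSING loci from each isolate's nearest neighbour.

    The neighbour is the closest isolate by Bruvo distance over mutually
    called loci that is itself called at the missing locus; ties break by
    dataset order.  The input dataset is left unmodified.
    """
    if model is None:
        model = BruvoModel()
    out = ds.copy()
    calls = ds.calls
    n, nl = ds.n_isolates, ds.n_loci
    for l in range(nl):
        if all(row[l] is MISSING for row in calls):
            raise ValueError(f"locus {ds.locus_names[l]} is MISSING in every isolate")
    for i in range(n):
        missing_loci = [l for l in range(nl) if calls[i][l] is MISSING]
        if not missing_loci:
            continue
        # distances from isolate i to all others over shared called loci
        dist = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            tot, m = 0.0, 0
            for l in range(nl):
                a, b = calls[i][l], calls[j][l]
                if a is MISSING or b is MISSING:
                    continue
                tot += locus_distance(a, b, model)
                m += 1
            if m:
                dist[j] = tot / m
        order = np.argsort(dist, kind="stable")
        for l in missing_loci:
            for j in order:
                if np.isinf(dist[j]):
                    break
                if calls[j][l] is not MISSING:
                    out.calls[i][l] = calls[j][l]
                    break
            else:
                raise ValueError(
                    f"no neighbour callable at locus {ds.locus_names[l]} for "
                    f"isolate {ds.isolate_ids[i]}"
                )
            if out.calls[i][l] is MISSING:
                raise ValueError(
                    f"no neighbour callable at locus {ds.locus_names[l]} for "
                    f"isolate {ds.isolate_ids[i]}"
                )
    return out
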