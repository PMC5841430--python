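"""Distance-based AMOVA, Mantel test, geographic distances and pairwise FST.

AMOVA partitions the total squared genetic distance into among-group and
within-group variance components (single factor, permutation p-value).
The Mantel test correlates two distance matrices over their upper triangles
with simultaneous row/column permutations of the second.  Pairwise FST uses
the Weir & Cockerham (1984) theta estimator on diploid core genotypes,
summing the variance components over alleles and loci (ratio of averages).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .bruvo import DistanceMatrix
from .genotype_io import MISSING, IsolateMeta, MicrosatDataset

__all__ = [
    "AmovaResult",
    "MantelResult",
    "amova",
    "mantel",
    "haversine_matrix",
    "pairwise_fst",
    "COUNTRY_CENTROIDS",
]

EARTH_RADIUS_KM = 6371.0

#: Rough country centroids (decimal degrees) for the fermentation-niche
#: collection; editable/overridable via per-isolate lat/lon metadata.
COUNTRY_CENTROIDS: dict[str, tuple[float, float]] = {
    "France": (46.2, 2.2),
    "Italy": (42.8, 12.8),
    "Spain": (40.2, -3.6),
    "Portugal": (39.6, -8.0),
    "Germany": (51.1, 10.4),
    "Belgium": (50.6, 4.7),
    "Netherlands": (52.2, 5.3),
    "UK": (54.0, -2.5),
    "Denmark": (56.0, 9.9),
    "Greece": (39.0, 22.0),
    "Hungary": (47.2, 19.4),
    "Russia": (61.5, 105.0),
    "South Africa": (-29.0, 25.1),
    "Australia": (-25.3, 133.8),
    "New Zealand": (-41.8, 172.8),
    "USA": (39.8, -98.6),
    "Canada": (56.1, -106.3),
    "Argentina": (-34.0, -64.0),
    "Chile": (-35.7, -71.5),
    "Brazil": (-10.8, -52.9),
    "Uruguay": (-32.6, -55.8),
    "Mexico": (23.6, -102.5),
    "Thailand": (15.9, 101.0),
    "Japan": (36.2, 138.3),
    "Tunisia": (34.0, 9.6),
}


@dataclass
class AmovaResult:
    factor: str
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    pct_variance: float
    p: float
    nperm: int
    dropped: list[str] = field(default_factory=list)


@dataclass
class MantelResult:
    r: float
    p: float
    nperm: int


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ssw = 0.0
    for g in groups:
        rows = np.flatnonzero(labels == g)
        ssw += d2[np.ix_(rows, rows)].sum() / (2.0 * len(rows))
    return ssw


def amova(
    D: DistanceMatrix,
    labels: dict[str, str],
    nperm: int = 9999,
    seed: int | None = None,
    factor: str = "group",
) -> AmovaResult:
    """Single-factor distance-based AMOVA with a permutation p-value.

    SS_total = (1/N) sum_{i<j} d^2; SS_within sums (1/n_g) sum_{i<j in g} d^2
    per group; sigma2 components follow the standard one-level AMOVA
    moments with n0 = (N - sum n_g^2 / N)/(G-1).  Groups of size 1 are
    dropped with a warning.  p = (1 + #{permuted sigma2_among >= observed})
    / (1 + nperm) under random label permutation.
    """
    lab = np.array([labels[i] for i in D.ids], dtype=object)
    uniq, counts = np.unique(lab, return_counts=True)
    dropped = [str(g) for g, c in zip(uniq, counts) if c < 2]
    if dropped:
        warnings.warn(f"AMOVA: dropping singleton groups {dropped}")
    keep = np.array([l not in dropped for l in lab])
    if keep.sum() < 4:
        raise ValueError("fewer than 4 isolates usable after dropping singletons")
    lab = lab[keep]
    ids_keep = [i for i, k in zip(D.ids, keep) if k]
    d2 = D.submatrix(ids_keep).d ** 2
    uniq, counts = np.unique(lab, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("AMOVA needs >= 2 groups with >= 2 members")

    n = len(lab)
    g = len(uniq)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, lab, uniq)
    ss_among = ss_total - ss_within
    df_among, df_within = g - 1, n - g
    sigma2_w = ss_within / df_within
    n0 = (n - (counts ** 2).sum() / n) / df_among
    sigma2_a = (ss_among / df_among - sigma2_w) / n0

    def stat(perm_lab: np.ndarray) -> float:
        ssw = _ss_within(d2, perm_lab, uniq)
        return ((ss_total - ssw) / df_among - ssw / df_within) / n0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(nperm):
        if stat(rng.permutation(lab)) >= sigma2_a:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + nperm)

    sa = max(sigma2_a, 0.0)
    pct = 100.0 * sa / (sa + sigma2_w) if (sa + sigma2_w) > 0 else 0.0
    return AmovaResult(
        factor=factor,
        ss_among=ss_among,
        ss_within=ss_within,
        df_among=df_among,
        df_within=df_within,
        sigma2_among=sigma2_a,
        sigma2_within=sigma2_w,
        pct_variance=pct,
        p=p,
        nperm=nperm,
        dropped=dropped,
    )


def mantel(
    D1: DistanceMatrix,
    D2: DistanceMatrix,
    nperm: int = 9999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) Mantel correlation between two distance matrices."""
    if D1.ids != D2.ids:
        raise ValueError("matrices must share ids in the same order")
    iu = np.triu_indices(D1.n, k=1)
    x = D1.d[iu]
    y = D2.d[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance distance triangle; r undefined")
    r = float(pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(nperm):
        perm = rng.permutation(D2.n)
        yp = D2.d[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, yp)[0, 1] >= r:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + nperm)
    return MantelResult(r=r, p=p, nperm=nperm)


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371 km."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def haversine_matrix(
    meta: list[IsolateMeta],
    centroids: dict[str, tuple[float, float]] | None = None,
) -> DistanceMatrix:
    """Pairwise great-circle distances between isolates (km).

    Coordinates come from per-isolate lat/lon when present, else from the
    country-centroid table, so isolates from the same country sit at
    distance 0.
    """
    if centroids is None:
        centroids = COUNTRY_CENTROIDS
    coords = []
    unresolved = []
    for m in meta:
        if m.lat is not None and m.lon is not None:
            if not (-90 <= m.lat <= 90 and -180 <= m.lon <= 180):
                raise ValueError(f"{m.isolate_id}: coordinates out of range")
            coords.append((m.lat, m.lon))
        elif m.country in centroids:
            coords.append(centroids[m.country])
        else:
            unresolved.append(m.country or "<blank>")
    if unresolved:
        raise ValueError(f"unresolvable countries: {sorted(set(unresolved))}")
    n = len(meta)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if coords[i] == coords[j]:
                continue
            d[i, j] = d[j, i] = haversine_km(*coords[i], *coords[j])
    return DistanceMatrix(ids=[m.isolate_id for m in meta], d=d)


def _wc_components(
    n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray
) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) a, b, c variance components for one allele."""
    r = len(n_i)
    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    if nbar <= 1 or nc <= 0:
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return float(a), float(b), float(c)


def fst_pair(
    core: MicrosatDataset, ids_a: list[str], ids_b: list[str]
) -> float:
    """WC theta between two populations given by isolate id lists."""
    idx = {iso: i for i, iso in enumerate(core.isolate_ids)}
    rows = [[idx[i] for i in ids_a], [idx[i] for i in ids_b]]
    num = den = 0.0
    for j in range(core.n_loci):
        # collect diploid genotypes per population at this locus
        genos = []
        for pop_rows in rows:
            g = []
            for i in pop_rows:
                cell = core.calls[i][j]
                if cell is MISSING:
                    continue
                al = sorted(cell)
                if len(al) == 1:
                    g.append((al[0], al[0]))  # single call = homozygote
                elif len(al) == 2:
                    g.append((al[0], al[1]))
            genos.append(g)
        n_i = np.array([len(g) for g in genos], dtype=float)
        if (n_i < 1).any():
            continue
        alleles = sorted({a for g in genos for pair in g for a in pair})
        if len(alleles) < 2:
            continue
        for allele in alleles:
            p_i = np.array(
                [sum(pair.count(allele) for pair in g) / (2 * len(g)) for g in genos]
            )
            h_i = np.array(
                [
                    sum(1 for pair in g if pair.count(allele) == 1) / len(g)
                    for g in genos
                ]
            )
            a, b, c = _wc_components(n_i, p_i, h_i)
            num += a
            den += a + b + c
    if den == 0.0:
        return float("nan")
    return max(num / den, 0.0)


def pairwise_fst(
    core: MicrosatDataset, pops: dict[str, str]
) -> pd.DataFrame:
    """Pairwise WC theta between all populations; NaN when undefined.

    ``pops`` maps isolate id -> population label; populations with fewer
    than 2 isolates are dropped with a warning.
    """
    members: dict[str, list[str]] = {}
    for iso in core.isolate_ids:
        members.setdefault(pops[iso], []).append(iso)
    small = [p for p, m in members.items() if len(m) < 2]
    if small:
        warnings.warn(f"pairwise_fst: dropping populations with < 2 isolates: {small}")
        for p in small:
            del members[p]
    labels = sorted(members)
    if len(labels) < 2:
        raise ValueError("need >= 2 populations with >= 2 isolates")
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for pa, pb in itertools.combinations(labels, 2):
        theta = fst_pair(core, members[pa], members[pb])
        if np.isnan(theta):
            warnings.warn(f"theta undefined for pair ({pa}, {pb}): no shared polymorphism")
        out.loc[pa, pb] = out.loc[pb, pa] = theta
    return out
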