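"""Admixture inference on core diploid genotypes.

Genotypes are encoded as allele-dosage rows (per-locus blocks summing to 1)
and factorised as X ~ Q G with Q (isolates x K ancestries) row-stochastic
and G (K x alleles) block-stochastic per locus — a simplex-constrained
non-negative factorisation fit by EM-style multiplicative updates that
monotonically decrease the masked cross-entropy.  The number of ancestral
populations K is chosen by held-out (masked) cross-entropy, smallest K
within one standard error of the minimum, mirroring the sparse-NMF
entropy-criterion workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, MicrosatDataset

__all__ = [
    "GenotypeMatrix",
    "AncestryFit",
    "encode_genotypes",
    "fit_ancestry",
    "select_k",
    "plot_ancestry_bars",
]

_EPS = 1e-12
#: Smoothing weight mixing the fitted block probabilities with the uniform
#: distribution when *scoring* held-out blocks; caps the penalty of alleles
#: a pool never saw in training without touching the fit itself.
_HOLDOUT_SMOOTH = 1e-3


@dataclass
class GenotypeMatrix:
    """Dosage matrix with a mask of observed locus blocks.

    ``x``: N x A array of relative allele dosages; ``mask``: True where the
    (isolate, locus) block was called; ``columns``: (locus, allele) per
    column; ``blocks``: column slices per locus.
    """

    x: np.ndarray
    mask: np.ndarray
    columns: list[tuple[str, int]]
    blocks: list[slice]

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def n_alleles(self) -> int:
        return self.x.shape[1]


@dataclass
class AncestryFit:
    k: int
    q: np.ndarray
    g: np.ndarray
    ce_train: float
    ce_heldout: float
    seed: int | None
    iterations: int
    converged: bool
    trace: list | None = None  # per-iteration training CE when requested


def encode_genotypes(core: MicrosatDataset) -> GenotypeMatrix:
    """One column per surviving (locus, allele); dosages sum to 1 per block.

    A two-allele call contributes 0.5 to each allele column, a single-allele
    call contributes 1.0; MISSING blocks are zero-filled and masked out.
    """
    alleles = core.observed_alleles()
    col_of = {la: c for c, la in enumerate(alleles)}
    blocks = []
    start = 0
    for locus in core.loci:
        width = sum(1 for la in alleles if la[0] == locus.name)
        blocks.append(slice(start, start + width))
        start += width
    # re-order columns so each locus block is contiguous
    ordered = sorted(alleles, key=lambda la: ([l.name for l in core.loci].index(la[0]), la[1]))
    col_of = {la: c for c, la in enumerate(ordered)}

    n = core.n_isolates
    x = np.zeros((n, len(ordered)))
    mask = np.zeros((n, len(ordered)), dtype=bool)
    for i, row in enumerate(core.calls):
        for locus, cell in zip(core.loci, row):
            if cell is MISSING:
                continue
            al = sorted(cell)
            if len(al) > 2:
                continue  # defensively treat as missing
            dose = 1.0 / len(al)
            for a in al:
                x[i, col_of[(locus.name, a)]] = dose
            blk = blocks[[l.name for l in core.loci].index(locus.name)]
            mask[i, blk] = True
    return GenotypeMatrix(x=x, mask=mask, columns=ordered, blocks=blocks)


def _normalize_rows(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return m / s


def _normalize_blocks(g: np.ndarray, blocks: list[slice]) -> np.ndarray:
    out = g.copy()
    for blk in blocks:
        s = out[:, blk].sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        out[:, blk] /= s
    return out


def _cross_entropy(x, p, where, n_blocks_per_entry) -> float:
    """Mean -sum_a x log p over the selected blocks (per-block average)."""
    ll = -(x * np.log(np.clip(p, _EPS, None)))[where].sum()
    return ll / max(n_blocks_per_entry, 1)


def _block_count(mask_blocks: np.ndarray) -> int:
    return int(mask_blocks.sum())


def fit_ancestry(
    gm: GenotypeMatrix,
    k: int,
    seed: int | None = None,
    mask_fraction: float = 0.05,
    max_iter: int = 500,
    tol: float = 1e-7,
    record_trace: bool = False,
) -> AncestryFit:
    """Fit Q and G for a given K by monotone multiplicative (EM) updates.

    A random ``mask_fraction`` of the called (isolate, locus) blocks is held
    out; training minimises the cross-entropy on the remaining blocks and
    ``ce_heldout`` reports the per-block cross-entropy on the held-out set.
    Deterministic for a given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    x, blocks = gm.x, gm.blocks
    n, a = x.shape
    nl = len(blocks)

    called = np.zeros((n, nl), dtype=bool)
    for j, blk in enumerate(blocks):
        called[:, j] = gm.mask[:, blk].any(axis=1)
    holdout_blocks = called & (rng.random((n, nl)) < mask_fraction)
    if holdout_blocks.all(axis=1).any():  # keep at least one training block per row
        for i in np.flatnonzero(holdout_blocks.all(axis=1)):
            holdout_blocks[i, rng.integers(nl)] = False
    train_blocks = called & ~holdout_blocks

    train = np.zeros((n, a), dtype=bool)
    hold = np.zeros((n, a), dtype=bool)
    for j, blk in enumerate(blocks):
        train[:, blk] = train_blocks[:, [j]]
        hold[:, blk] = holdout_blocks[:, [j]]

    q = _normalize_rows(rng.dirichlet(np.ones(k), size=n))
    g = _normalize_blocks(rng.dirichlet(np.ones(a), size=k) + _EPS, blocks)
    if k == 1:
        q = np.ones((n, 1))

    xt = np.where(train, x, 0.0)
    prev = np.inf
    iters = 0
    converged = False
    trace: list | None = [] if record_trace else None
    for it in range(max_iter):
        iters = it + 1
        p = q @ g
        w = xt / np.clip(p, _EPS, None)
        q_new = _normalize_rows(q * (w @ g.T) + _EPS)
        p = q_new @ g
        w = xt / np.clip(p, _EPS, None)
        g_new = _normalize_blocks(g * (q_new.T @ w) + _EPS, blocks)
        q, g = q_new, g_new
        ce = _cross_entropy(xt, q @ g, train, _block_count(train_blocks))
        if trace is not None:
            trace.append(ce)
        if prev - ce < tol and it > 5:
            converged = True
            prev = ce
            break
        prev = ce

    p = q @ g
    ce_train = _cross_entropy(xt, p, train, _block_count(train_blocks))
    xh = np.where(hold, x, 0.0)
    n_hold = _block_count(holdout_blocks)
    p_smooth = p.copy()
    for blk in blocks:
        width = blk.stop - blk.start
        p_smooth[:, blk] = (1 - _HOLDOUT_SMOOTH) * p[:, blk] + _HOLDOUT_SMOOTH / width
    ce_heldout = (
        _cross_entropy(xh, p_smooth, hold, n_hold) if n_hold > 0 else ce_train
    )
    return AncestryFit(
        k=k,
        q=q,
        g=g,
        ce_train=ce_train,
        ce_heldout=ce_heldout,
        seed=seed,
        iterations=iters,
        converged=converged,
        trace=trace,
    )


def select_k(
    gm: GenotypeMatrix,
    k_range=range(1, 9),
    repetitions: int = 10,
    seed: int | None = None,
    mask_fraction: float = 0.05,
    max_iter: int = 500,
) -> tuple[int, pd.DataFrame]:
    """Choose K by masked cross-entropy over repeated fits.

    Each K gets ``repetitions`` fits with fresh masks/initialisations; K* is
    the smallest K whose mean held-out cross-entropy is within one standard
    error of the minimum.  Returns (K*, curve) where the curve holds mean and
    SE per K.
    """
    ks = list(k_range)
    if not ks or repetitions < 1:
        raise ValueError("k_range non-empty and repetitions >= 1 required")
    rng = np.random.default_rng(seed)
    rows = []
    for k in ks:
        ces = [
            fit_ancestry(
                gm,
                k,
                seed=int(rng.integers(2 ** 31 - 1)),
                mask_fraction=mask_fraction,
                max_iter=max_iter,
            ).ce_heldout
            for _ in range(repetitions)
        ]
        ces = np.array(ces)
        se = ces.std(ddof=1) / np.sqrt(len(ces)) if len(ces) > 1 else 0.0
        rows.append({"k": k, "ce_mean": float(ces.mean()), "ce_se": float(se)})
    curve = pd.DataFrame(rows)
    best = curve["ce_mean"].idxmin()
    threshold = curve.loc[best, "ce_mean"] + curve.loc[best, "ce_se"]
    k_star = int(curve.loc[curve["ce_mean"] <= threshold, "k"].min())
    return k_star, curve


def plot_ancestry_bars(q: np.ndarray, path, labels=None, order=None) -> None:
    """STRUCTURE-style stacked bar plot of admixture proportions.

    One bar per isolate, one colour per ancestral component; ``order``
    optionally re-sorts isolates (e.g. by group) for display.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    q = np.asarray(q, dtype=float)
    if order is not None:
        q = q[np.asarray(order)]
    n, k = q.shape
    fig, ax = plt.subplots(figsize=(max(6, n / 25), 2.5))
    bottom = np.zeros(n)
    x = np.arange(n)
    for comp in range(k):
        ax.bar(x, q[:, comp], bottom=bottom, width=1.0)
        bottom += q[:, comp]
    ax.set_xlim(-0.5, n - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry proportion")
    ax.set_xticks([])
    if labels is not None:
        ax.set_xlabel(" / ".join(map(str, dict.fromkeys(labels))))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
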