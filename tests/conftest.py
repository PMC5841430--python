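import numpy as np
import pytest

from bruxpop.genotype_io import MISSING, IsolateMeta, LocusDef, MicrosatDataset


def make_dataset(genotypes, n_loci=None, metas=None):
    """Build a MicrosatDataset from a list of per-isolate call lists.

    Each call is an iterable of repeat counts or MISSING (None).
    """
    n_loci = n_loci or len(genotypes[0])
    loci = [LocusDef(f"L{j + 1:02d}", repeat_unit_bp=3, offset_bp=90) for j in range(n_loci)]
    isolates = []
    calls = []
    for i, row in enumerate(genotypes):
        meta = (
            metas[i]
            if metas is not None
            else IsolateMeta(isolate_id=f"I{i + 1:03d}")
        )
        isolates.append(meta)
        calls.append([MISSING if c is None else frozenset(c) for c in row])
    return MicrosatDataset(loci=loci, isolates=isolates, calls=calls)


@pytest.fixture
def rng():
    return np.random.default_rng(20180307)


@pytest.fixture
def small_ds():
    """Four isolates x three loci, mixed ploidy, one missing cell."""
    return make_dataset(
        [
            [{10, 12}, {20}, {7, 8}],
            [{10, 12}, {20}, {7, 8}],
            [{10, 12, 14}, {21, 22}, None],
            [{11}, {25, 26, 27, 28}, {9}],
        ]
    )


@pytest.fixture(scope="session")
def paper_like():
    """Scaled-down six-group diploid-triploid complex with truth (shared
    across tests; treat as read-only)."""
    import bruxpop as bp

    cfg = bp.paper_like_config(scale=0.12, seed=11)
    ds, truth = bp.simulate_complex(cfg)
    return cfg, ds, truth
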