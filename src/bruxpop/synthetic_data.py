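"""Synthetic diploid-triploid microsatellite complexes and SO2 growth curves.

The generator emulates the statistical structure the analysis assumes:
ancestral pools with locus-specific Dirichlet allele frequencies, diploid
genotypes drawn from one pool, allotriploid genotypes carrying a core
diploid genome plus one extra haploid allele set from a donor pool, clonal
expansion with stepwise mutation, missing loci, per-group country/substrate
metadata, and three-phase growth curves (lag, constant divisions/h,
plateau) whose rate/plateau/lag respond to SO2 dose according to a
tolerant or sensitive archetype.  Every draw flows from one seed, and a
truth record accompanies each emitted dataset.

Pool frequencies are hierarchical: a species-wide base shared by all pools
(the core genome common to the complex), a lineage component shared by the
pools of one main lineage, and a pool-private component.  The default
configuration mirrors the six-group diploid-triploid complex of the
B. bruxellensis collection: group sizes, genotype counts, ploidy, dominant
substrates and country spreads follow its published census, three main
lineages (two triploid, one mostly-diploid with subgroups), and clonal
multiplicities drawn from a geometric law matched to each group's
isolates-per-genotype ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .genotype_io import IsolateMeta, LocusDef, MicrosatDataset, MISSING
from .growth_so2 import GrowthCurve

__all__ = [
    "GroupSpec",
    "GrowthArchetype",
    "SimConfig",
    "TruthRecord",
    "simulate_complex",
    "simulate_growth",
    "paper_like_config",
]


@dataclass(frozen=True)
class GrowthArchetype:
    """Dose response of the three growth parameters.

    Multipliers index doses in config order; a rate multiplier of 0 means
    total growth failure at that dose.
    """

    rate_div_h: float = 0.10
    plateau_od: float = 2.0
    lag_h: float = 40.0
    od0: float = 0.1
    rate_mult: tuple = (1.0, 1.0, 1.0, 1.0)
    plateau_mult: tuple = (1.0, 1.0, 1.0, 1.0)
    lag_add_h: tuple = (0.0, 0.0, 0.0, 0.0)


TOLERANT = GrowthArchetype(
    lag_add_h=(0.0, 10.0, 30.0, 60.0),
)
SENSITIVE = GrowthArchetype(
    rate_mult=(1.0, 0.6, 0.25, 0.0),
    plateau_mult=(1.0, 0.95, 0.45, 0.0),
    lag_add_h=(0.0, 20.0, 80.0, 0.0),
)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n_isolates: int
    n_genotypes: int
    ploidy: str  # "diploid" | "triploid"
    core_pool: int
    lineage: int = 0
    donor_pool: Optional[int] = None  # triploid extra-haploid source
    admix: Optional[tuple] = None  # ((pool, weight), ...) overrides core_pool
    countries: tuple = (("France", 1.0),)
    substrates: tuple = (("wine", 1.0),)
    tolerant: bool = False


@dataclass(frozen=True)
class SimConfig:
    groups: tuple
    n_pools: int = 5
    n_lineages: int = 3
    pool_lineage: tuple = (0, 1, 2, 2, 2)
    n_donor_pools: int = 4
    n_loci: int = 12
    repeat_unit_bp: int = 3
    offset_bp: int = 90
    core_repeat_range: tuple = (5, 25)
    donor_repeat_range: tuple = (26, 40)
    dirichlet_alpha: float = 0.25  # donor-pool concentration (per allele)
    # hierarchical core frequencies: species base -> lineage -> pool,
    # each level resampled as Dirichlet(concentration * parent mean);
    # smaller concentration = more drift = higher FST at that level
    base_alpha: float = 0.5
    lineage_concentration: float = 3.0
    pool_concentration: float = 3.0
    mutation_rate: float = 0.01  # per allele per clonal copy, +/-1 repeat
    missing_rate: float = 0.02
    doses: tuple = (0.0, 0.2, 0.4, 0.6)
    n_replicates: int = 3
    t_max_h: float = 300.0
    dt_h: float = 24.0
    od_noise_sigma: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for g in self.groups:
            if abs(sum(w for _, w in g.countries) - 1.0) > 1e-9:
                raise ValueError(f"group {g.name}: country weights must sum to 1")
            if abs(sum(w for _, w in g.substrates) - 1.0) > 1e-9:
                raise ValueError(f"group {g.name}: substrate weights must sum to 1")
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.missing_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if len(self.pool_lineage) != self.n_pools:
            raise ValueError("pool_lineage must map every pool")
        lo, hi = self.core_repeat_range
        if hi - lo + 1 < 3:
            raise ValueError("allele-size range too narrow for the motif grid")


@dataclass
class TruthRecord:
    """Ground truth for one simulated isolate."""

    isolate_id: str
    group: str
    lineage: int
    population: int  # core ancestral pool index (dominant pool when admixed)
    ploidy: str
    genotype_id: str
    extra_alleles: dict  # locus name -> extra (donor) allele, triploids only


def paper_like_config(scale: float = 1.0, seed: int = 0, **overrides) -> SimConfig:
    """Six-group configuration matching the published census of the complex
    (group sizes, genotype counts, ploidy, dominant substrates), optionally
    scaled down for quick runs (counts scaled, minimum 4 isolates/group)."""

    def sc(n: int, lo: int = 4) -> int:
        return max(int(round(n * scale)), lo)

    groups = (
        GroupSpec(
            "AWRI1499-like", sc(548), sc(197), "triploid",
            core_pool=0, lineage=0, donor_pool=0,
            countries=(("France", 0.4), ("Australia", 0.25), ("Italy", 0.15),
                       ("Portugal", 0.1), ("Chile", 0.1)),
            substrates=(("wine", 0.95), ("beer", 0.05)),
            tolerant=True,
        ),
        GroupSpec(
            "AWRI1608-like", sc(210), sc(127), "triploid",
            core_pool=1, lineage=1, donor_pool=1,
            countries=(("Belgium", 0.45), ("USA", 0.35), ("UK", 0.2)),
            substrates=(("beer", 0.6), ("wine", 0.4)),
        ),
        GroupSpec(
            "CBS 2499-like", sc(573), sc(208), "diploid",
            core_pool=2, lineage=2,
            countries=(("France", 0.35), ("Spain", 0.2), ("Italy", 0.2),
                       ("USA", 0.15), ("South Africa", 0.1)),
            substrates=(("wine", 1.0),),
        ),
        GroupSpec(
            "L0308-like", sc(37), sc(26), "triploid",
            core_pool=3, lineage=2, donor_pool=2,
            countries=(("France", 1.0),),
            substrates=(("wine", 1.0),),
            tolerant=True,
        ),
        GroupSpec(
            "CBS 5512-like", sc(18), sc(16), "triploid",
            core_pool=3, lineage=2, donor_pool=3,
            admix=((3, 0.5), (4, 0.5)),  # multiple ancestries, like the
            # tequila/bioethanol group's mixed assignment
            countries=(("Brazil", 0.5), ("Mexico", 0.5)),
            substrates=(("bioethanol", 0.5), ("tequila", 0.5)),
        ),
        GroupSpec(
            "L14165-like", sc(108), sc(58), "diploid",
            core_pool=4, lineage=2,
            countries=(("France", 0.4), ("Germany", 0.3), ("Russia", 0.3)),
            substrates=(("kombucha", 1.0),),
        ),
    )
    groups = tuple(
        replace(g, n_genotypes=min(g.n_genotypes, g.n_isolates)) for g in groups
    )
    return SimConfig(groups=groups, seed=seed, **overrides)


def _drift(parent: np.ndarray, conc: float, rng: np.random.Generator) -> np.ndarray:
    """Resample frequencies around ``parent`` (Balding-Nichols-style drift);
    the implied fixation index at this level is roughly 1/(1 + conc)."""
    return rng.dirichlet(np.clip(conc * parent, 1e-6, None))


def _pool_frequencies(cfg: SimConfig, rng: np.random.Generator):
    """Hierarchical allele frequencies per (pool, locus): species base ->
    lineage -> pool.  All pools share allele support (the core genome common
    to the complex) but drift apart in frequency, so differentiation
    survives the polyploid-allele exclusion."""
    lo, hi = cfg.core_repeat_range
    core_alleles = np.arange(lo, hi + 1)
    dlo, dhi = cfg.donor_repeat_range
    donor_alleles = np.arange(dlo, dhi + 1)
    na = len(core_alleles)

    base = [rng.dirichlet(np.full(na, cfg.base_alpha)) for _ in range(cfg.n_loci)]
    lineage = [
        [_drift(base[j], cfg.lineage_concentration, rng) for j in range(cfg.n_loci)]
        for _ in range(cfg.n_lineages)
    ]
    core = [
        [
            _drift(lineage[cfg.pool_lineage[p]][j], cfg.pool_concentration, rng)
            for j in range(cfg.n_loci)
        ]
        for p in range(cfg.n_pools)
    ]
    donor = [
        [rng.dirichlet(np.full(len(donor_alleles), cfg.dirichlet_alpha))
         for _ in range(cfg.n_loci)]
        for _ in range(cfg.n_donor_pools)
    ]
    return core_alleles, core, donor_alleles, donor


def _multiplicities(n_isolates: int, n_genotypes: int, rng: np.random.Generator) -> np.ndarray:
    """Geometric clone-class sizes adjusted to the exact isolate total."""
    if n_genotypes > n_isolates:
        raise ValueError("more genotypes than isolates")
    p = n_genotypes / n_isolates
    sizes = rng.geometric(p, size=n_genotypes)
    while sizes.sum() > n_isolates:
        big = np.flatnonzero(sizes > 1)
        if len(big) == 0:
            break
        sizes[rng.choice(big)] -= 1
    while sizes.sum() < n_isolates:
        sizes[rng.integers(n_genotypes)] += 1
    return sizes


def _weighted_choice(pairs: tuple, rng: np.random.Generator) -> str:
    names = [n for n, _ in pairs]
    w = np.array([w for _, w in pairs], dtype=float)
    return str(names[rng.choice(len(names), p=w / w.sum())])


def _core_freq_for_group(g: GroupSpec, core_freq, j: int) -> np.ndarray:
    if g.admix is None:
        return core_freq[g.core_pool][j]
    f = sum(w * core_freq[p][j] for p, w in g.admix)
    return f / f.sum()


def simulate_complex(cfg: SimConfig) -> tuple[MicrosatDataset, dict[str, TruthRecord]]:
    """Draw a full diploid-triploid complex with truth records.

    Diploid genotypes take two draws per locus from their core pool;
    allotriploids add one draw per locus from the donor pool (the distinct-
    allele union forms the call, so a triploid cell shows 2 or 3 distinct
    alleles; with the default disjoint donor range, always 3).  Clonal
    copies then mutate each allele +/-1 repeat with the configured stepwise
    rate, and missing loci are punched at random.
    """
    rng = np.random.default_rng(cfg.seed)
    core_alleles, core_freq, donor_alleles, donor_freq = _pool_frequencies(cfg, rng)
    loci = [
        LocusDef(name=f"L{j + 1:02d}", repeat_unit_bp=cfg.repeat_unit_bp,
                 offset_bp=cfg.offset_bp)
        for j in range(cfg.n_loci)
    ]

    isolates: list[IsolateMeta] = []
    calls: list[list] = []
    truth: dict[str, TruthRecord] = {}
    iso_counter = 0

    for g in cfg.groups:
        sizes = _multiplicities(g.n_isolates, g.n_genotypes, rng)
        for gi, mult in enumerate(sizes):
            genotype_id = f"{g.name}:G{gi + 1:04d}"
            base: list[tuple] = []
            extra: dict[str, int] = {}
            for j in range(cfg.n_loci):
                freq = _core_freq_for_group(g, core_freq, j)
                pair = rng.choice(core_alleles, size=2, p=freq)
                alleles = [int(pair[0]), int(pair[1])]
                if g.ploidy == "triploid":
                    if g.donor_pool is None:
                        raise ValueError(f"group {g.name}: triploid without donor pool")
                    e = int(rng.choice(donor_alleles, p=donor_freq[g.donor_pool][j]))
                    alleles.append(e)
                    extra[loci[j].name] = e
                base.append(tuple(alleles))
            for _ in range(int(mult)):
                iso_counter += 1
                iso_id = f"BB{iso_counter:05d}"
                row = []
                for j in range(cfg.n_loci):
                    if rng.random() < cfg.missing_rate:
                        row.append(MISSING)
                        continue
                    mutated = [
                        a + int(rng.choice((-1, 1)))
                        if rng.random() < cfg.mutation_rate and a > 1
                        else a
                        for a in base[j]
                    ]
                    row.append(frozenset(mutated))
                country = _weighted_choice(g.countries, rng)
                substrate = _weighted_choice(g.substrates, rng)
                isolates.append(
                    IsolateMeta(
                        isolate_id=iso_id,
                        country=country,
                        substrate=substrate,
                        group=g.name,
                    )
                )
                calls.append(row)
                truth[iso_id] = TruthRecord(
                    isolate_id=iso_id,
                    group=g.name,
                    lineage=g.lineage,
                    population=g.core_pool,
                    ploidy=g.ploidy,
                    genotype_id=genotype_id,
                    extra_alleles=dict(extra) if g.ploidy == "triploid" else {},
                )

    ds = MicrosatDataset(loci=loci, isolates=isolates, calls=calls)
    return ds, truth


def simulate_growth(
    cfg: SimConfig, strains: list[tuple[str, bool]]
) -> tuple[list[GrowthCurve], dict[str, str]]:
    """Simulate dose-response growth curves for (strain id, tolerant?) pairs.

    Returns the curves plus the truth map strain -> "T"/"S".  Curves follow
    the three-phase model: flat at od0 through the lag, exponential at the
    archetype's divisions/h, clipped at the plateau; Gaussian OD noise on
    top; rate multiplier 0 means no growth at that dose.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    times = np.arange(0.0, cfg.t_max_h + cfg.dt_h / 2, cfg.dt_h)
    curves: list[GrowthCurve] = []
    truth: dict[str, str] = {}
    for strain, tolerant in strains:
        arch = TOLERANT if tolerant else SENSITIVE
        truth[strain] = "T" if tolerant else "S"
        for di, dose in enumerate(cfg.doses):
            rate = arch.rate_div_h * arch.rate_mult[di]
            plateau = arch.plateau_od * arch.plateau_mult[di]
            lag = arch.lag_h + arch.lag_add_h[di]
            for rep in range(cfg.n_replicates):
                if rate <= 0 or plateau <= arch.od0:
                    od = np.full_like(times, arch.od0)
                else:
                    od = arch.od0 * 2.0 ** (rate * np.clip(times - lag, 0.0, None))
                    od = np.minimum(od, plateau)
                noisy = od + rng.normal(0.0, cfg.od_noise_sigma, size=len(times))
                noisy = np.clip(noisy, 0.01, None)
                noisy[0] = max(od[0], 0.01)  # inoculation density is set, not read
                curves.append(
                    GrowthCurve(
                        strain=strain,
                        dose=dose,
                        replicate=f"r{rep + 1}",
                        times=times.copy(),
                        od=noisy,
                    )
                )
    return curves, truth
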