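"""End-to-end workflow: genotypes -> structure -> core genotype -> statistics.

``run_pipeline`` chains the library modules in the order of the published
workflow: ploidy inference and clone collapse, Bruvo distance matrix, the
five clustering views (NJ, UPGMA, MDS, successive K-means, partition
reliability), core-diploid extraction, AMOVA / Mantel / pairwise FST,
ancestry inference with entropy-based K selection, and (optionally) SO2
growth classification.  Every stage's artifact can be written to an output
directory and a machine-readable summary is returned.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import ancestry as anc
from . import bruvo, clustering, core_genotype, genotype_io, growth_so2, popgen_stats

__all__ = ["run_pipeline"]


def _write(outdir: Optional[Path], name: str, writer) -> None:
    if outdir is None:
        return
    outdir.mkdir(parents=True, exist_ok=True)
    writer(outdir / name)


def run_pipeline(
    ds: genotype_io.MicrosatDataset,
    growth_curves: Optional[list] = None,
    outdir=None,
    seed: int = 0,
    kmax: int = 8,
    tau: float = 0.05,
    reliability_R: int = 1000,
    nperm: int = 999,
    k_range=range(1, 9),
    k_repetitions: int = 5,
    alpha_assoc: float = 0.01,
    alpha_growth: float = 0.05,
    with_reliability: bool = True,
) -> dict:
    """Run the full analysis; returns a JSON-serialisable summary."""
    rng = np.random.default_rng(seed)
    outdir = Path(outdir) if outdir is not None else None
    summary: dict = {"seed": seed, "n_isolates": ds.n_isolates, "n_loci": ds.n_loci}

    # --- ploidy census and clone collapse --------------------------------
    ploidy = genotype_io.infer_ploidy(ds)
    census = {"2n": 0, "3n": 0, "4n/5n": 0, "undefined": 0}
    for p in ploidy:
        census[p.klass or "undefined"] += 1
    summary["ploidy_census"] = census
    genotypes = genotype_io.collapse_clones(ds)
    summary["n_genotypes"] = int(len(genotypes))
    _write(outdir, "genotypes.csv", lambda p: genotypes.to_csv(p, index=False))

    # --- distance and the five clustering views --------------------------
    D = bruvo.distance_matrix(ds)
    _write(outdir, "bruvo_distance.csv", D.to_csv)
    nj_tree = clustering.nj(D)
    upgma_tree = clustering.upgma(D)
    _write(outdir, "nj.nwk", lambda p: nj_tree.write(path=str(p), schema="newick"))
    _write(outdir, "upgma.nwk", lambda p: upgma_tree.write(path=str(p), schema="newick"))

    coords = clustering.mds_variance_coords(D)
    _write(
        outdir,
        "mds_coords.csv",
        lambda p: pd.DataFrame(coords, index=ds.isolate_ids).to_csv(p),
    )
    assign = clustering.find_clusters(
        coords, kmax=kmax, seed=int(rng.integers(2 ** 31 - 1)), tau=tau
    )
    summary["n_clusters"] = assign.k
    summary["wss_curve"] = {str(k): v for k, v in assign.wss_curve.items()}
    _write(
        outdir,
        "wss_curve.csv",
        lambda p: pd.DataFrame(
            sorted(assign.wss_curve.items()), columns=["k", "wss"]
        ).to_csv(p, index=False),
    )
    _write(
        outdir,
        "clusters.csv",
        lambda p: pd.DataFrame(
            {"isolate_id": ds.isolate_ids, "cluster": assign.label_array()}
        ).to_csv(p, index=False),
    )
    if with_reliability:
        clustering.partition_reliability(
            nj_tree, D, R=reliability_R, seed=int(rng.integers(2 ** 31 - 1))
        )
        rels = [
            nd.reliability
            for nd in nj_tree.preorder_internal_node_iter()
            if getattr(nd, "reliability", None) is not None
        ]
        summary["n_reliable_nodes"] = int(sum(r > 0.90 for r in rels))
        _write(
            outdir, "nj_reliability.nwk",
            lambda p: nj_tree.write(path=str(p), schema="newick"),
        )

    # --- core genotype ----------------------------------------------------
    assocs = core_genotype.triploid_associated_alleles(ds, ploidy, alpha=alpha_assoc)
    excluded = [(a.locus, a.allele) for a in assocs if a.excluded]
    summary["n_alleles_total"] = len(assocs)
    summary["n_alleles_excluded"] = len(excluded)
    _write(
        outdir, "allele_associations.csv",
        lambda p: core_genotype.association_frame(assocs).to_csv(p, index=False),
    )
    core = core_genotype.build_core_dataset(ds, excluded)
    # census of isolates with <=2 alleles everywhere before the masking step
    excluded_set = set(excluded)
    le2 = 0
    for row in ds.calls:
        ok = True
        for l, cell in zip(ds.loci, row):
            if cell is genotype_io.MISSING:
                continue
            kept = sum(1 for a in cell if (l.name, a) not in excluded_set)
            if kept > 2:
                ok = False
                break
        le2 += ok
    summary["n_isolates_le2_after_exclusion"] = int(le2)
    _write(
        outdir, "core_genotypes.csv",
        lambda p: core.to_frame().to_csv(p, index=False),
    )

    # --- structure statistics ---------------------------------------------
    factors = {
        "country": {m.isolate_id: m.country for m in ds.isolates},
        "substrate": {m.isolate_id: m.substrate for m in ds.isolates},
        "ploidy": {p.isolate_id: (p.klass or "NA") for p in ploidy},
    }
    summary["amova"] = {}
    for name, labels in factors.items():
        try:
            res = popgen_stats.amova(
                D, labels, nperm=nperm, seed=int(rng.integers(2 ** 31 - 1)),
                factor=name,
            )
            summary["amova"][name] = {
                "pct_variance": res.pct_variance,
                "p": res.p,
            }
        except ValueError as err:
            summary["amova"][name] = {"error": str(err)}
    # geography restricted to non-wine isolates, mirroring the published contrast
    non_wine = [m.isolate_id for m in ds.isolates if m.substrate != "wine"]
    if len(non_wine) >= 4:
        try:
            res = popgen_stats.amova(
                D.submatrix(non_wine),
                factors["country"],
                nperm=nperm,
                seed=int(rng.integers(2 ** 31 - 1)),
                factor="country_non_wine",
            )
            summary["amova"]["country_non_wine"] = {
                "pct_variance": res.pct_variance,
                "p": res.p,
            }
        except ValueError as err:
            summary["amova"]["country_non_wine"] = {"error": str(err)}

    try:
        G = popgen_stats.haversine_matrix(ds.isolates)
        mres = popgen_stats.mantel(
            D, G, nperm=nperm, seed=int(rng.integers(2 ** 31 - 1))
        )
        summary["mantel"] = {"r": mres.r, "p": mres.p}
    except ValueError as err:
        summary["mantel"] = {"error": str(err)}

    groups = {m.isolate_id: (m.group or "ungrouped") for m in ds.isolates}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fst = popgen_stats.pairwise_fst(core, groups)
        summary["fst"] = {
            f"{a}|{b}": (None if np.isnan(fst.loc[a, b]) else float(fst.loc[a, b]))
            for i, a in enumerate(fst.index)
            for b in fst.index[i + 1:]
        }
        _write(outdir, "fst.csv", lambda p: fst.to_csv(p))
    except (ValueError, KeyError) as err:
        summary["fst"] = {"error": str(err)}

    # --- ancestry ----------------------------------------------------------
    gm = anc.encode_genotypes(core)
    k_star, curve = anc.select_k(
        gm, k_range=k_range, repetitions=k_repetitions,
        seed=int(rng.integers(2 ** 31 - 1)),
    )
    summary["k_star"] = int(k_star)
    _write(outdir, "entropy_curve.csv", lambda p: curve.to_csv(p, index=False))
    fit = anc.fit_ancestry(gm, k_star, seed=int(rng.integers(2 ** 31 - 1)))
    _write(
        outdir, "ancestry_Q.csv",
        lambda p: pd.DataFrame(
            fit.q, index=core.isolate_ids,
            columns=[f"K{i + 1}" for i in range(k_star)],
        ).to_csv(p),
    )

    # --- growth ------------------------------------------------------------
    if growth_curves is not None:
        params = [growth_so2.growth_params(c) for c in growth_curves]
        by_strain: dict[str, list] = {}
        for p in params:
            by_strain.setdefault(p.strain, []).append(p)
        calls = {
            s: growth_so2.classify_tolerance(ps, alpha=alpha_growth)
            for s, ps in sorted(by_strain.items())
        }
        summary["tolerance"] = {s: c.klass for s, c in calls.items()}
        _write(
            outdir, "growth_params.csv",
            lambda p: growth_so2.params_table(params).to_csv(p, index=False),
        )
        _write(
            outdir, "tolerance_calls.csv",
            lambda p: pd.DataFrame(
                [
                    {"strain": s, "klass": c.klass, "notes": c.notes,
                     "effect_size_flag": c.effect_size_flag}
                    for s, c in calls.items()
                ]
            ).to_csv(p, index=False),
        )
    else:
        summary["tolerance"] = None

    _write(
        outdir, "summary.json",
        lambda p: Path(p).write_text(json.dumps(summary, indent=2, default=float)),
    )
    return summary
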