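"""Core-diploid genotype extraction.

Mixed ploidy defeats most classical population-genetic machinery, so the
polyploid-specific signal is stripped: every (locus, allele) whose carriage
is significantly associated with the polyploid class (Pearson chi-square on
the 2x2 carrier table, p < alpha) is removed from every call, and any
remaining call with more than two alleles is masked as missing.  What is
left approximates the diploid genome shared across the complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import chi2_contingency

from .genotype_io import MISSING, MicrosatDataset, PloidyCall

__all__ = ["AlleleAssociation", "triploid_associated_alleles", "build_core_dataset"]


@dataclass
class AlleleAssociation:
    locus: str
    allele: int
    poly_carriers: int
    poly_noncarriers: int
    dip_carriers: int
    dip_noncarriers: int
    chi2: float
    p: float
    excluded: bool


def triploid_associated_alleles(
    ds: MicrosatDataset,
    ploidy: list[PloidyCall],
    alpha: float = 0.01,
    min_alleles_poly: int = 3,
) -> list[AlleleAssociation]:
    """Test each observed allele for association with the polyploid class.

    The polyploid class is every isolate showing >= ``min_alleles_poly``
    distinct alleles at >= 1 locus (ploidy 3n or 4n/5n by default).  For each
    distinct (locus, allele) a 2x2 carrier/non-carrier x class table is
    scored with Pearson chi-square, 1 df, no continuity correction; alleles
    carried at a higher rate in the polyploid class with p < alpha are
    flagged excluded (the exclusion targets alleles specific to the
    polyploids, so diploid-enriched alleles stay).  Isolates with undefined
    ploidy are left out of the table.
    """
    by_id = {p.isolate_id: p for p in ploidy}
    if set(by_id) < set(ds.isolate_ids):
        raise ValueError("ploidy calls do not cover all isolates")
    is_poly = {}
    for iso in ds.isolate_ids:
        call = by_id[iso]
        if call.klass is None:
            continue
        is_poly[iso] = call.max_alleles >= min_alleles_poly

    out = []
    for locus_name, allele in ds.observed_alleles():
        j = ds.locus_names.index(locus_name)
        pc = pn = dc = dn = 0
        for meta, row in zip(ds.isolates, ds.calls):
            if meta.isolate_id not in is_poly:
                continue
            cell = row[j]
            if cell is MISSING:
                continue
            carrier = allele in cell
            if is_poly[meta.isolate_id]:
                pc += carrier
                pn += not carrier
            else:
                dc += carrier
                dn += not carrier
        if pc + dc == 0:
            continue  # carried by nobody scored
        table = [[pc, pn], [dc, dn]]
        if min(pc + pn, dc + dn) == 0 or pc + dc == 0 or pn + dn == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, expected = chi2_contingency(table, correction=False)
            if (expected < 5).any():
                warnings.warn(
                    f"locus {locus_name} allele {allele}: chi-square expected "
                    f"count < 5; approximation is coarse"
                )
        out.append(
            AlleleAssociation(
                locus=locus_name,
                allele=allele,
                poly_carriers=pc,
                poly_noncarriers=pn,
                dip_carriers=dc,
                dip_noncarriers=dn,
                chi2=float(chi2),
                p=float(p),
                excluded=bool(
                    p < alpha
                    and (pc + pn) > 0
                    and (dc + dn) > 0
                    and pc / (pc + pn) > dc / (dc + dn)
                ),
            )
        )
    return out


def association_frame(assocs: list[AlleleAssociation]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in assocs])


def build_core_dataset(
    ds: MicrosatDataset, excluded: list[tuple[str, int]]
) -> MicrosatDataset:
    """Strip excluded alleles and mask residual multi-allelic calls.

    Excluded (locus, allele) pairs are removed from every call; calls left
    empty become MISSING, and calls still holding more than 2 alleles are
    treated as missing data.
    """
    observed = set(ds.observed_alleles())
    bad = [e for e in excluded if tuple(e) not in observed]
    if bad:
        raise ValueError(f"excluded alleles not present in dataset: {bad[:5]}")
    drop: dict[str, set[int]] = {}
    for locus, allele in excluded:
        drop.setdefault(locus, set()).add(allele)
    out = ds.copy()
    for row in out.calls:
        for j, locus in enumerate(out.loci):
            cell = row[j]
            if cell is MISSING:
                continue
            kept = frozenset(a for a in cell if a not in drop.get(locus.name, ()))
            if len(kept) == 0 or len(kept) > 2:
                row[j] = MISSING
            else:
                row[j] = kept
    return out
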