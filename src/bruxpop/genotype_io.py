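"""Mixed-ploidy microsatellite datasets: parsing, validation, ploidy inference,
and clone collapse.

A dataset is a matrix of isolates x loci where each cell holds the *set* of
distinct allele repeat counts observed at that locus (microsatellite loci in a
diploid-triploid complex can show 1-5 distinct alleles).  Fragment sizes in bp
are converted to repeat counts via the locus motif length and a reference
offset; a cell with no amplification is MISSING (``None``).

Ploidy is inferred from the maximum number of distinct alleles seen at any
locus: up to 2 -> diploid (2n), up to 3 -> triploid (3n), 4 or 5 -> 4n/5n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "MISSING",
    "LocusDef",
    "IsolateMeta",
    "MicrosatDataset",
    "PloidyCall",
    "read_genotypes",
    "infer_ploidy",
    "collapse_clones",
]

#: Sentinel for a locus with no allele call.
MISSING = None

#: Maximum number of distinct alleles a single cell may carry.
MAX_ALLELES = 5

#: Conversion deviation (in repeat units) beyond which an off-grid warning fires.
OFF_GRID_TOL = 0.34


@dataclass(frozen=True)
class LocusDef:
    """A microsatellite locus: motif length and reference offset (both bp)."""

    name: str
    repeat_unit_bp: int
    offset_bp: int = 0

    def __post_init__(self) -> None:
        if self.repeat_unit_bp < 1:
            raise ValueError(f"locus {self.name}: repeat_unit_bp must be >= 1")
        if self.offset_bp < 0:
            raise ValueError(f"locus {self.name}: offset_bp must be >= 0")

    def size_to_repeats(self, size_bp: float) -> int:
        """Convert a fragment size in bp to a repeat count (nearest integer)."""
        raw = (size_bp - self.offset_bp) / self.repeat_unit_bp
        repeats = round(raw)
        if abs(raw - repeats) > OFF_GRID_TOL:
            warnings.warn(
                f"locus {self.name}: fragment size {size_bp} is off the motif "
                f"grid by {abs(raw - repeats):.2f} repeat units",
                stacklevel=2,
            )
        if repeats < 0:
            raise ValueError(
                f"locus {self.name}: fragment size {size_bp} converts to a "
                f"negative repeat count"
            )
        return int(repeats)

    def repeats_to_size(self, repeats: int) -> int:
        return self.offset_bp + repeats * self.repeat_unit_bp


@dataclass
class IsolateMeta:
    isolate_id: str
    country: str = ""
    substrate: str = ""
    group: Optional[str] = None
    lat: Optional[float] = None
    lon: Optional[float] = None


def _as_allele_set(repeats: Iterable[int]) -> frozenset:
    s = frozenset(int(r) for r in repeats)
    if not s:
        raise ValueError("empty allele set; use MISSING instead")
    if len(s) > MAX_ALLELES:
        raise ValueError(f"more than {MAX_ALLELES} distinct alleles in one cell")
    if any(r < 0 for r in s):
        raise ValueError("negative repeat count")
    return s


@dataclass
class MicrosatDataset:
    """Isolates x loci allele-set matrix with per-isolate metadata.

    ``calls[i][l]`` is the frozenset of repeat counts for isolate ``i`` at
    locus ``l`` (indices follow ``isolates`` / ``loci`` order), or MISSING.
    """

    loci: list[LocusDef]
    isolates: list[IsolateMeta]
    calls: list[list[Optional[frozenset]]] = field(repr=False)

    def __post_init__(self) -> None:
        ids = [m.isolate_id for m in self.isolates]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate isolate ids")
        if len(self.calls) != len(self.isolates):
            raise ValueError("calls row count != isolate count")
        for row in self.calls:
            if len(row) != len(self.loci):
                raise ValueError("calls column count != locus count")
        # normalise cells to frozensets
        for row in self.calls:
            for j, cell in enumerate(row):
                if cell is not MISSING:
                    row[j] = _as_allele_set(cell)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_isolates(self) -> int:
        return len(self.isolates)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def isolate_ids(self) -> list[str]:
        return [m.isolate_id for m in self.isolates]

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def call(self, isolate_id: str, locus: str) -> Optional[frozenset]:
        i = self.isolate_ids.index(isolate_id)
        j = self.locus_names.index(locus)
        return self.calls[i][j]

    def observed_alleles(self) -> list[tuple[str, int]]:
        """All distinct (locus name, repeat count) pairs present in the data."""
        out = set()
        for row in self.calls:
            for locus, cell in zip(self.loci, row):
                if cell is not MISSING:
                    out.update((locus.name, r) for r in cell)
        return sorted(out)

    # -- serialisation -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format dump: one row per isolate x locus."""
        rows = []
        for meta, row in zip(self.isolates, self.calls):
            for locus, cell in zip(self.loci, row):
                rows.append(
                    {
                        "isolate_id": meta.isolate_id,
                        "locus": locus.name,
                        "repeats": ""
                        if cell is MISSING
                        else ";".join(str(r) for r in sorted(cell)),
                    }
                )
        return pd.DataFrame(rows)

    def to_allele_table(self, in_bp: bool = False) -> pd.DataFrame:
        """Wide isolate x locus table of ';'-joined calls (repeats or bp)."""
        data = {}
        for j, locus in enumerate(self.loci):
            col = []
            for row in self.calls:
                cell = row[j]
                if cell is MISSING:
                    col.append("")
                else:
                    vals = sorted(
                        locus.repeats_to_size(r) if in_bp else r for r in cell
                    )
                    col.append(";".join(str(v) for v in vals))
            data[locus.name] = col
        return pd.DataFrame(data, index=pd.Index(self.isolate_ids, name="isolate_id"))

    def copy(self) -> "MicrosatDataset":
        return MicrosatDataset(
            loci=list(self.loci),
            isolates=[IsolateMeta(**vars(m)) for m in self.isolates],
            calls=[list(row) for row in self.calls],
        )


@dataclass
class PloidyCall:
    isolate_id: str
    max_alleles: int
    n_loci_ge3: int
    klass: Optional[str]  # "2n" | "3n" | "4n/5n" | None when all loci MISSING


def _read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", dtype=str, **kw)


def read_genotypes(allele_table, locus_table, meta_table) -> MicrosatDataset:
    """Assemble a dataset from three delimited text files.

    ``allele_table``: wide table, first column isolate id, one column per
    locus, cells ';'-separated fragment sizes in bp (blank = MISSING).
    ``locus_table``: columns name, repeat_unit_bp, offset_bp.
    ``meta_table``: columns isolate_id, country, substrate and optionally
    group, lat, lon.
    """
    loci_df = _read_table(locus_table)
    loci = [
        LocusDef(
            name=str(r["name"]),
            repeat_unit_bp=int(r["repeat_unit_bp"]),
            offset_bp=int(r.get("offset_bp", 0) or 0),
        )
        for _, r in loci_df.iterrows()
    ]
    locus_by_name = {l.name: l for l in loci}

    meta_df = _read_table(meta_table)
    metas = {}
    for _, r in meta_df.iterrows():
        m = IsolateMeta(
            isolate_id=str(r["isolate_id"]),
            country=str(r.get("country", "") or ""),
            substrate=str(r.get("substrate", "") or ""),
            group=(str(r["group"]) if "group" in r and pd.notna(r["group"]) else None),
            lat=(float(r["lat"]) if "lat" in r and pd.notna(r["lat"]) else None),
            lon=(float(r["lon"]) if "lon" in r and pd.notna(r["lon"]) else None),
        )
        metas[m.isolate_id] = m

    alleles_df = _read_table(allele_table, index_col=0)
    unknown_loci = [c for c in alleles_df.columns if c not in locus_by_name]
    if unknown_loci:
        raise ValueError(f"allele table columns not in locus table: {unknown_loci}")
    unknown_isolates = [i for i in alleles_df.index if str(i) not in metas]
    if unknown_isolates:
        raise ValueError(
            f"allele table rows not in metadata table: {unknown_isolates[:5]}"
        )

    isolates = [metas[str(i)] for i in alleles_df.index]
    ordered_loci = [locus_by_name[c] for c in alleles_df.columns]
    calls: list[list[Optional[frozenset]]] = []
    for iso_id, row in alleles_df.iterrows():
        call_row = []
        for locus, cell in zip(ordered_loci, row):
            if pd.isna(cell) or str(cell).strip() == "":
                call_row.append(MISSING)
                continue
            try:
                sizes = [float(tok) for tok in str(cell).split(";") if tok.strip()]
                repeats = {locus.size_to_repeats(s) for s in sizes}
            except ValueError as err:
                raise ValueError(
                    f"isolate {iso_id}, locus {locus.name}: {err}"
                ) from err
            call_row.append(frozenset(repeats))
        calls.append(call_row)

    return MicrosatDataset(loci=ordered_loci, isolates=isolates, calls=calls)


def infer_ploidy(ds: MicrosatDataset) -> list[PloidyCall]:
    """Classify each isolate as 2n, 3n or 4n/5n from its per-locus allele counts.

    MISSING loci are ignored; an isolate with every locus MISSING gets
    ``klass=None`` (flagged undefined).
    """
    if ds.n_isolates == 0:
        raise ValueError("empty dataset")
    out = []
    for meta, row in zip(ds.isolates, ds.calls):
        counts = [len(cell) for cell in row if cell is not MISSING]
        if not counts:
            out.append(PloidyCall(meta.isolate_id, 0, 0, None))
            continue
        mx = max(counts)
        ge3 = sum(1 for c in counts if c >= 3)
        if mx <= 2:
            klass = "2n"
        elif mx == 3:
            klass = "3n"
        else:
            klass = "4n/5n"
        out.append(PloidyCall(meta.isolate_id, mx, ge3, klass))
    return out


def collapse_clones(ds: MicrosatDataset) -> pd.DataFrame:
    """Collapse isolates sharing an identical multilocus genotype.

    Two isolates share a genotype iff every locus (including MISSING status)
    is identical.  Returns a table with columns genotype_id, multiplicity,
    members (';'-joined isolate ids), ordered by first occurrence.
    """
    seen: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for meta, row in zip(ds.isolates, ds.calls):
        key = tuple(
            tuple(sorted(cell)) if cell is not MISSING else None for cell in row
        )
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(meta.isolate_id)
    rows = [
        {
            "genotype_id": f"MLG{g + 1:04d}",
            "multiplicity": len(seen[key]),
            "members": ";".join(seen[key]),
        }
        for g, key in enumerate(order)
    ]
    return pd.DataFrame(rows)
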