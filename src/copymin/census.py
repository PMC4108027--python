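"""Per-family, per-species gene census tables and summary statistics.

A family table counts gene identifiers per (family, species), attaches
the inferred minimum ancestral copy number per family (or ND where one
side of the focal split has no members), and summarises: per-species
totals, the ancestral-copy total (ND families contribute 0, with their
count footnoted), and how many families have at least one member in a
focal species (by default the moss).

A reference census of the 16 pectin-related gene families — *Arabidopsis
thaliana* and *Physcomitrella patens* gene counts and the minimum copy
number at the moss–tracheophyte ancestor, as established in the plant
cell-wall literature — ships with the package so the census path can be
exercised without any external data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .ancestral_inference import AncestralCountResult
from .tree_io import TaxonMap, TaxonMapError

log = logging.getLogger(__name__)

__all__ = [
    "FamilyTable",
    "CensusSummary",
    "build_family_table",
    "summarize",
    "load_reference_census",
    "gene_lists_from_census",
]

ND = "ND"


@dataclass
class FamilyTable:
    """Census: per-species counts plus the ancestral-copy column.

    ``counts`` is families x species (non-negative ints); ``ancestral``
    maps family -> int or the string ``"ND"``.
    """

    counts: pd.DataFrame
    ancestral: pd.Series

    def detected_in(self, species: str) -> pd.Series:
        """Boolean per family: >= 1 gene in ``species``."""
        if species not in self.counts.columns:
            return pd.Series(False, index=self.counts.index)
        return self.counts[species] > 0

    def to_frame(self) -> pd.DataFrame:
        df = self.counts.copy()
        df["min_ancestral_copies"] = self.ancestral
        return df

    def to_tsv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index_label="family")
        return path

    def to_markdown(self) -> str:
        df = self.to_frame().reset_index()
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join("---" for _ in df.columns) + "|"
        body = [
            "| " + " | ".join(str(v) for v in row) + " |"
            for row in df.itertuples(index=False)
        ]
        return "\n".join([header, sep, *body])


@dataclass
class CensusSummary:
    species_totals: dict
    ancestral_total: int
    n_nd: int
    n_families: int
    focal_species: str
    n_detected_in_focal: int


def _ancestral_value(res) -> object:
    if res is None:
        return ND
    if isinstance(res, AncestralCountResult):
        return ND if res.nd else int(res.min_copies)
    if isinstance(res, str):
        if res.upper() == ND:
            return ND
        return int(res)
    return int(res)


def build_family_table(
    gene_lists: Union[pd.DataFrame, Mapping[str, list]],
    taxon_map: TaxonMap,
    results: Optional[Mapping[str, object]] = None,
    species: Optional[list] = None,
    strict: bool = True,
) -> FamilyTable:
    """Count genes per (family, species) and attach ancestral-copy results.

    ``gene_lists`` is a DataFrame with columns (family, gene_id) or a
    mapping family -> iterable of gene ids. Duplicate ids within a family
    are dropped with a warning; ids no rule matches raise in strict mode.
    ``results`` maps family -> AncestralCountResult, int, or "ND"; missing
    families get ND.
    """
    seen: set = set()
    counts: dict = {}
    families: list = []
    if isinstance(gene_lists, pd.DataFrame):
        pairs = list(gene_lists[["family", "gene_id"]].itertuples(index=False))
    else:
        pairs = [(fam, gid) for fam, gids in gene_lists.items() for gid in gids]
        for fam in gene_lists:  # keep empty families as all-zero rows
            counts[fam] = {}
            families.append(fam)
    for fam, gid in pairs:
        if fam not in counts:
            counts[fam] = {}
            families.append(fam)
        if (fam, gid) in seen:
            log.warning("duplicate gene id %r in family %r dropped", gid, fam)
            continue
        seen.add((fam, gid))
        sp = taxon_map.resolve(gid)
        if sp is None:
            if strict:
                raise TaxonMapError(f"gene id {gid!r} (family {fam!r}) matches no rule")
            sp = "unknown"
        counts[fam][sp] = counts[fam].get(sp, 0) + 1

    columns = species or sorted({sp for row in counts.values() for sp in row})
    table = pd.DataFrame(
        [[counts[f].get(sp, 0) for sp in columns] for f in families],
        index=pd.Index(families, name="family"),
        columns=columns,
        dtype=int,
    )
    results = results or {}
    ancestral = pd.Series(
        [_ancestral_value(results.get(f)) for f in families],
        index=table.index,
        dtype=object,
        name="min_ancestral_copies",
    )
    return FamilyTable(counts=table, ancestral=ancestral)


def summarize(
    table: FamilyTable, focal_species: str = "physcomitrella"
) -> CensusSummary:
    """Totals row plus the detected-in-focal-species family count.

    ND ancestral entries are never summed as numbers: they contribute 0
    to ``ancestral_total`` and are footnoted via ``n_nd``.
    """
    numeric = [v for v in table.ancestral if v != ND]
    return CensusSummary(
        species_totals={sp: int(t) for sp, t in table.counts.sum().items()},
        ancestral_total=int(sum(numeric)),
        n_nd=int(sum(1 for v in table.ancestral if v == ND)),
        n_families=int(len(table.counts)),
        focal_species=focal_species,
        n_detected_in_focal=int(table.detected_in(focal_species).sum()),
    )


def load_reference_census() -> pd.DataFrame:
    """The packaged 16-family pectin census (arabidopsis & physcomitrella
    gene counts, minimum ancestral copies with ND where the moss side has
    no members). Index: family key; ancestral column is int-or-"ND"."""
    with resources.files("copymin.data").joinpath("pectin_family_census.tsv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, sep="\t", index_col="family", dtype=str)
    for col in ("arabidopsis", "physcomitrella"):
        df[col] = df[col].astype(int)
    return df


def gene_lists_from_census(
    census: pd.DataFrame, species_columns: Optional[list] = None
) -> pd.DataFrame:
    """Expand a count table into synthetic per-gene rows (family, gene_id).

    Identifiers are generated as ``<species>_<family>_<i>`` so the default
    taxon map resolves them; only the counts are meaningful.
    """
    species_columns = species_columns or [
        c for c in census.columns if c not in ("ancestral",)
    ]
    rows = []
    for fam, row in census.iterrows():
        for sp in species_columns:
            for i in range(int(row[sp])):
                rows.append((fam, f"{sp}_{fam}_{i + 1}"))
    return pd.DataFrame(rows, columns=["family", "gene_id"])
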