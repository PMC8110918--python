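"""Cell-type -> marker-gene catalogs.

A catalog is an ordered collection of cell-type definitions. Three catalogs
ship with the package:

``pdac_cmg``
    The 90-gene candidate set covering 23 immune cell types assembled for
    pancreatic ductal adenocarcinoma (PDAC) from a prior pan-cancer marker
    study plus additional literature genes.
``pdac_mgic``
    The 55-gene selected marker set covering 22 cell types that passed the
    pairwise-similarity filter on TCGA PAAD expression data.
``nsolver_default``
    The default cell-type profiling gene sets of the nSolver Advanced
    Analysis module, for comparison.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .errors import CatalogError
from .matrix import normalize_symbol

BUNDLED_CATALOGS = ("pdac_cmg", "pdac_mgic", "nsolver_default")


@dataclass
class CellTypeDef:
    """One cell type: its label, candidate/marker genes, optional parent."""

    name: str
    genes: list[str]
    parent: str | None = None
    source: str = ""
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = [normalize_symbol(g) for g in self.genes]
        if not self.genes:
            raise CatalogError(f"cell type {self.name!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise CatalogError(f"cell type {self.name!r} lists duplicate genes")
        self.provenance = {normalize_symbol(g): p for g, p in self.provenance.items()}


@dataclass
class GeneSetCatalog:
    entries: list[CellTypeDef]
    catalog_name: str = "catalog"
    version: str = "1"

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise CatalogError("duplicate cell-type names in catalog")
        known = set(names)
        for e in self.entries:
            if e.parent is not None and e.parent not in known:
                raise CatalogError(f"parent {e.parent!r} of {e.name!r} not in catalog")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> CellTypeDef:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def cell_types(self) -> list[str]:
        return [e.name for e in self.entries]

    def unique_genes(self) -> list[str]:
        """All genes in catalog order, deduplicated."""
        seen: dict[str, None] = {}
        for e in self.entries:
            for g in e.genes:
                seen.setdefault(g)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_type": e.name,
                "gene": g,
                "provenance": e.provenance.get(g, ""),
                "parent": e.parent or "",
            }
            for e in self.entries
            for g in e.genes
        ]
        return pd.DataFrame(rows, columns=["cell_type", "gene", "provenance", "parent"])


# -- reading and writing -------------------------------------------------------


def _catalog_from_frame(df: pd.DataFrame, name: str, version: str = "1") -> GeneSetCatalog:
    required = {"cell_type", "gene"}
    if not required.issubset(df.columns):
        raise CatalogError(f"catalog table needs columns {sorted(required)}")
    entries = []
    for ct, sub in df.groupby("cell_type", sort=False):
        parents = set(sub["parent"].dropna()) - {""} if "parent" in sub else set()
        if len(parents) > 1:
            raise CatalogError(f"cell type {ct!r} has conflicting parents {sorted(parents)}")
        prov = {}
        if "provenance" in sub:
            prov = {g: p for g, p in zip(sub["gene"], sub["provenance"].fillna("")) if p}
        entries.append(
            CellTypeDef(
                name=str(ct),
                genes=list(sub["gene"]),
                parent=next(iter(parents)) if parents else None,
                provenance=prov,
            )
        )
    return GeneSetCatalog(entries, catalog_name=name, version=version)


def read_catalog_tsv(path) -> GeneSetCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return _catalog_from_frame(df, name=_stem(path))


def write_catalog_tsv(catalog: GeneSetCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep="\t", index=False)


def read_catalog_yaml(path) -> GeneSetCatalog:
    """Read a catalog from structured text: mapping cell type -> fields.

    Each value is either a plain gene list or a mapping with keys
    ``genes`` (required), ``parent`` and ``source``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise CatalogError("catalog YAML must map cell-type names to definitions")
    entries = []
    for name, spec in doc.items():
        if isinstance(spec, list):
            entries.append(CellTypeDef(name=str(name), genes=spec))
        elif isinstance(spec, dict):
            entries.append(
                CellTypeDef(
                    name=str(name),
                    genes=spec.get("genes", []),
                    parent=spec.get("parent"),
                    source=spec.get("source", ""),
                )
            )
        else:
            raise CatalogError(f"cell type {name!r}: definition must be a list or mapping")
    return GeneSetCatalog(entries, catalog_name=_stem(path))


def write_catalog_yaml(catalog: GeneSetCatalog, path) -> None:
    doc = {}
    for e in catalog:
        spec: dict = {"genes": list(e.genes)}
        if e.parent:
            spec["parent"] = e.parent
        if e.source:
            spec["source"] = e.source
        doc[e.name] = spec
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_catalog(path) -> GeneSetCatalog:
    """Dispatch on extension: .tsv/.txt tabular, .yaml/.yml structured."""
    p = str(path)
    if p.endswith((".yaml", ".yml")):
        return read_catalog_yaml(path)
    return read_catalog_tsv(path)


def load_catalog(name: str) -> GeneSetCatalog:
    """Load one of the bundled catalogs by name.

    >>> load_catalog("pdac_mgic")["B cells"].genes
    ['BLK', 'CD19', 'CD22', 'CR2', 'MS4A1']
    """
    if name not in BUNDLED_CATALOGS:
        raise CatalogError(f"unknown catalog {name!r}; bundled: {', '.join(BUNDLED_CATALOGS)}")
    ref = resources.files("pdacmarkers.resources").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return _catalog_from_frame(df, name=name)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
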