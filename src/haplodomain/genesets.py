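"""Gene-set collections: GMT parsing, set means, and pathway x domain intersections.

A collection is a flat mapping of set name -> member gene ids with an optional
two-level hierarchy (subdomain -> parent domain), which is how the AD Biodomain
annotation is organized (19 domains, 80 subdomains).  KEGG pathways load as a
flat collection.  Intersection sets between a pathway collection and a domain
collection are the unit of the intersection trend analysis; only intersections
with at least ``min_size`` annotated genes are retained.

In GMT files the description field is ordinarily free text; this module uses
the convention ``parent=<domain>`` in the description of a subdomain line to
carry the hierarchy, and writes it back the same way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


class GmtFormatError(ValueError):
    """Raised for malformed GMT input."""


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional subdomain -> domain hierarchy."""

    sets: dict[str, list[str]]
    hierarchy: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(set(genes)) != len(genes):
                raise ValueError(f"set {name!r} contains duplicate gene ids")
        for sub, parent in self.hierarchy.items():
            if parent not in self.sets:
                raise ValueError(
                    f"hierarchy parent {parent!r} of {sub!r} is not a set in the collection"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def domains(self) -> list[str]:
        """Top-level sets (those that are a parent, or have no parent)."""
        parents = set(self.hierarchy.values())
        return [n for n in self.sets if n in parents or n not in self.hierarchy]

    @property
    def subdomains(self) -> list[str]:
        return list(self.hierarchy)


@dataclass(frozen=True)
class IntersectionSet:
    """Genes shared by one KEGG pathway and one Biodomain."""

    pathway: str
    domain: str
    genes: tuple[str, ...]

    @property
    def id(self) -> str:
        return f"{self.pathway} x {self.domain}"

    @property
    def size(self) -> int:
        return len(self.genes)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated member ids).

    Duplicate members within a line are deduplicated with a warning; empty
    sets are dropped with a warning.  Lines with fewer than three fields are
    an error reported with their line number.
    """
    sets: dict[str, list[str]] = {}
    hierarchy: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtFormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc = fields[0], fields[1]
            members = [g for g in fields[2:] if g]
            uniq = list(dict.fromkeys(members))
            if len(uniq) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} had duplicate members; deduplicated",
                    stacklevel=2,
                )
            if not uniq:
                warnings.warn(f"{path}:{lineno}: set {name!r} is empty; dropped", stacklevel=2)
                continue
            sets[name] = uniq
            if desc.startswith("parent="):
                hierarchy[name] = desc[len("parent="):]
    return GeneSetCollection(sets=sets, hierarchy=hierarchy, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection back to GMT, encoding hierarchy in the description."""
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = (
                f"parent={collection.hierarchy[name]}"
                if name in collection.hierarchy
                else "na"
            )
            fh.write("\t".join([name, desc, *genes]) + "\n")


def set_mean_expression(expr, genes, set_name: str = "") -> pd.Series:
    """Per-sample unweighted mean expression over a set's genes.

    Genes absent from the matrix are dropped (their count is logged); zero
    present genes is an error naming the set.  ``expr`` may be an
    ExpressionMatrix or a bare genes x samples DataFrame.
    """
    data = expr.data if hasattr(expr, "data") else expr
    present = [g for g in genes if g in data.index]
    n_missing = len(genes) - len(present)
    if not present:
        raise KeyError(
            f"set {set_name!r}: none of its {len(genes)} genes are in the expression matrix"
        )
    if n_missing:
        logger.info("set %r: %d of %d genes absent from matrix", set_name, n_missing, len(genes))
    return data.loc[present].mean(axis=0)


def set_mean_matrix(expr, collection_or_sets, names=None) -> pd.DataFrame:
    """Stack set means into a sets x samples DataFrame.

    Accepts a GeneSetCollection (optionally restricted to ``names``), a list
    of IntersectionSet, or a plain mapping name -> gene list.
    """
    if isinstance(collection_or_sets, GeneSetCollection):
        items = [(n, collection_or_sets.sets[n]) for n in (names or collection_or_sets.sets)]
    elif isinstance(collection_or_sets, dict):
        items = list(collection_or_sets.items())
    else:  # iterable of IntersectionSet
        items = [(s.id, list(s.genes)) for s in collection_or_sets]
    rows = {name: set_mean_expression(expr, genes, name) for name, genes in items}
    data = expr.data if hasattr(expr, "data") else expr
    return pd.DataFrame(rows).T.reindex(columns=data.columns)


def build_intersections(
    kegg: GeneSetCollection,
    biodomains: GeneSetCollection,
    min_size: int = 10,
) -> list[IntersectionSet]:
    """All pathway x domain intersections with at least ``min_size`` genes.

    Every pair is evaluated; retained intersections are ordered by pathway
    name then domain name.  The size filter applies to the annotated
    intersection (not to expression-present genes).
    """
    if not kegg.sets or not biodomains.sets:
        raise ValueError("both collections must be nonempty")
    out: list[IntersectionSet] = []
    for pathway in sorted(kegg.sets):
        pgenes = set(kegg.sets[pathway])
        for domain in sorted(biodomains.sets):
            shared = tuple(sorted(pgenes.intersection(biodomains.sets[domain])))
            if len(shared) >= min_size:
                out.append(IntersectionSet(pathway=pathway, domain=domain, genes=shared))
    return out


def intersection_catalog(intersections: list[IntersectionSet]) -> pd.DataFrame:
    """Tabular view of an intersection list (pathway, domain, size, genes)."""
    return pd.DataFrame(
        {
            "pathway": [s.pathway for s in intersections],
            "domain": [s.domain for s in intersections],
            "size": [s.size for s in intersections],
            "genes": [";".join(s.genes) for s in intersections],
        }
    )
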