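"""Catalog benchmarking: reference pre-processing, recall, and family parity.

A produced TF catalog is compared with curated reference catalogs at the
gene level: recall is |catalog ∩ reference| / |reference|, reported as a
percentage to one decimal (round half away from zero). Per-family parity
asks, for each structural family, whether the catalog assigns exactly as
many genes to the family as the reference does (the 1:1 line on a per-family
scatter). Three-way overlaps are reported as the seven disjoint regions of a
Venn partition.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Set

import pandas as pd

from tfcat.tf_catalog import TFCatalog

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def normalize_identifier(identifier: str, alias_map: Optional[Mapping[str, str]] = None) -> str:
    """Case-fold a gene identifier and strip a trailing version suffix.

    An optional alias table (old → canonical, applied after normalization)
    handles symbol synonymy between catalogs.
    """
    norm = _VERSION_SUFFIX.sub("", identifier.strip()).upper()
    if alias_map:
        norm = alias_map.get(norm, norm)
    return norm


def normalize_identifiers(
    identifiers: Iterable[str], alias_map: Optional[Mapping[str, str]] = None
) -> set[str]:
    return {normalize_identifier(i, alias_map) for i in identifiers if str(i).strip()}


@dataclass
class ReferenceCatalog:
    """A curated reference TF catalog (gene identifiers or symbols)."""

    name: str
    entries: set[str]
    family_of: Optional[dict[str, str]] = None
    dbd_known: Optional[dict[str, bool]] = None

    def __len__(self) -> int:
        return len(self.entries)


def read_reference_catalog(path, name: Optional[str] = None,
                           alias_map: Optional[Mapping[str, str]] = None) -> ReferenceCatalog:
    """Read a reference catalog TSV: identifier, optional family, optional dbd_known.

    A header row is used when the first line names an ``identifier``/``gene``
    column; otherwise columns are positional. The dbd_known column accepts
    true/false, yes/no, 1/0.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str, keep_default_na=False)
    first = [c.strip().lower() for c in df.iloc[0]] if len(df) else []
    if first and first[0] in ("identifier", "gene", "symbol", "gene_symbol", "id"):
        df.columns = first
        df = df.iloc[1:]
        id_col = df.columns[0]
        fam_col = "family" if "family" in df.columns else None
        dbd_col = "dbd_known" if "dbd_known" in df.columns else None
    else:
        id_col = 0
        fam_col = 1 if df.shape[1] > 1 else None
        dbd_col = 2 if df.shape[1] > 2 else None
    entries: set[str] = set()
    family_of: dict[str, str] = {}
    dbd_known: dict[str, bool] = {}
    for _, row in df.iterrows():
        ident = normalize_identifier(str(row[id_col]), alias_map)
        if not ident:
            continue
        entries.add(ident)
        if fam_col is not None and str(row[fam_col]).strip():
            family_of[ident] = str(row[fam_col]).strip()
        if dbd_col is not None and str(row[dbd_col]).strip():
            dbd_known[ident] = str(row[dbd_col]).strip().lower() in ("1", "true", "yes", "y")
    return ReferenceCatalog(
        name=name or str(path),
        entries=entries,
        family_of=family_of or None,
        dbd_known=dbd_known or None,
    )


def filter_reference_known_dbd(reference: ReferenceCatalog) -> ReferenceCatalog:
    """Retain only reference entries with a known TF DNA-binding domain."""
    if reference.dbd_known is None:
        raise ValueError(f"reference {reference.name!r} has no dbd_known flags")
    kept = {e for e in reference.entries if reference.dbd_known.get(e, False)}
    if not kept:
        warnings.warn(f"no entries of {reference.name!r} have a known DBD", UserWarning)
    return ReferenceCatalog(
        name=reference.name,
        entries=kept,
        family_of={k: v for k, v in (reference.family_of or {}).items() if k in kept} or None,
        dbd_known={k: True for k in kept},
    )


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (what '91.6%'-style printed figures use)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CatalogComparison:
    """Set-overlap summary between a produced catalog and one reference."""

    query_name: str
    reference_name: str
    n_query: int
    n_reference: int
    n_intersection: int
    recall_pct: Optional[float]
    query_only: set[str] = field(default_factory=set)
    reference_only: set[str] = field(default_factory=set)


def compare_catalogs(
    query: Set[str],
    reference: ReferenceCatalog,
    query_name: str = "catalog",
) -> CatalogComparison:
    """Exact set arithmetic between a query identifier set and a reference.

    ``recall_pct`` = 100 · |query ∩ reference| / |reference|, to one decimal,
    rounding half away from zero; it is ``None`` (with a warning) for an
    empty reference.
    """
    qset, rset = set(query), set(reference.entries)
    inter = qset & rset
    if rset:
        recall = round_half_away(100.0 * len(inter) / len(rset), 1)
    else:
        warnings.warn(f"reference {reference.name!r} is empty; recall undefined", UserWarning)
        recall = None
    return CatalogComparison(
        query_name=query_name,
        reference_name=reference.name,
        n_query=len(qset),
        n_reference=len(rset),
        n_intersection=len(inter),
        recall_pct=recall,
        query_only=qset - rset,
        reference_only=rset - qset,
    )


#: default harmonization between registry family labels and reference
#: vocabularies; user-extensible (two-column map: their label → ours).
DEFAULT_FAMILY_HARMONIZATION = {
    "C2H2 ZF": "zf-C2H2",
    "C2H2 zinc finger": "zf-C2H2",
    "Homeobox": "Homeodomain",
    "bHLH": "bHLH",
    "bZIP": "bZIP",
    "Forkhead": "Forkhead",
    "Nuclear receptor": "zf-C4",
    "AT hook": "AT_hook",
    "HMG/Sox": "HMG_box",
}


def per_family_parity(
    catalog: TFCatalog,
    reference: ReferenceCatalog,
    harmonization: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-family count comparison between a catalog and a reference.

    One row per family in the union of (harmonized) family vocabularies,
    with ``parity`` true when the two counts are equal. Families whose
    labels do not harmonize count as distinct.
    """
    if reference.family_of is None:
        raise ValueError(f"reference {reference.name!r} has no family labels")
    harm = dict(harmonization) if harmonization is not None else dict(DEFAULT_FAMILY_HARMONIZATION)

    def canon(label: str) -> str:
        return harm.get(label, label)

    q_counts: dict[str, int] = {}
    for a in catalog.assignments:
        fam = canon(a.primary_family)
        q_counts[fam] = q_counts.get(fam, 0) + 1
    r_counts: dict[str, int] = {}
    for fam in reference.family_of.values():
        fam = canon(fam)
        r_counts[fam] = r_counts.get(fam, 0) + 1
    rows = []
    for fam in sorted(set(q_counts) | set(r_counts)):
        nq, nr = q_counts.get(fam, 0), r_counts.get(fam, 0)
        rows.append({"family": fam, "n_query": nq, "n_reference": nr, "parity": nq == nr})
    return pd.DataFrame(rows, columns=["family", "n_query", "n_reference", "parity"])


THREE_WAY_REGIONS = (
    "query_only",
    "ref1_only",
    "ref2_only",
    "query_ref1_only",
    "query_ref2_only",
    "ref1_ref2_only",
    "all_three",
)


def three_way_overlap(query: Set[str], ref1: Set[str], ref2: Set[str]) -> dict[str, int]:
    """Counts of the seven disjoint regions of a three-set Venn partition.

    The counts always sum to |query ∪ ref1 ∪ ref2|.
    """
    a, b, c = set(query), set(ref1), set(ref2)
    abc = a & b & c
    return {
        "query_only": len(a - b - c),
        "ref1_only": len(b - a - c),
        "ref2_only": len(c - a - b),
        "query_ref1_only": len((a & b) - c),
        "query_ref2_only": len((a & c) - b),
        "ref1_ref2_only": len((b & c) - a),
        "all_three": len(abc),
    }


def comparison_to_frame(comparisons: Sequence[CatalogComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "query": c.query_name,
                "reference": c.reference_name,
                "n_query": c.n_query,
                "n_reference": c.n_reference,
                "n_intersection": c.n_intersection,
                "recall_pct": c.recall_pct if c.recall_pct is not None else "NONE",
            }
            for c in comparisons
        ]
    )
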