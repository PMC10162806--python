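"""Turn filtered domain hits into a TF catalog.

A protein with at least one surviving DBD hit becomes a putative TF. Its
candidate families are ranked by best (lowest) per-domain independent
E-value, ties broken by higher bit score then alphabetical label; the top
family is the protein's primary structural family. The catalog unit is the
gene: after primary-isoform filtering seq_id ↔ gene_id is one-to-one, and if
filtering was skipped assignments are collapsed to gene level keeping the
best-scoring isoform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from tfcat.domain_search import DomainHit, ModelRegistry
from tfcat.sequence_io import ProteinRecord, Proteome, write_fasta


@dataclass
class TFAssignment:
    """Per-protein TF family classification.

    ``all_families`` is an ordered list of ``(family_label, best_i_evalue,
    n_domains)`` with the primary family first; each family appears once.
    """

    seq_id: str
    gene_id: Optional[str]
    all_families: list[tuple[str, float, int]]
    supporting_hits: list[DomainHit] = field(default_factory=list)

    @property
    def primary_family(self) -> str:
        return self.all_families[0][0]

    @property
    def best_i_evalue(self) -> float:
        return self.all_families[0][1]

    @property
    def n_domains(self) -> int:
        return sum(n for _, _, n in self.all_families)


@dataclass
class TFCatalog:
    """The catalog of putative TFs for one proteome."""

    species: str
    assignments: list[TFAssignment]
    n_input_sequences: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.seq_id for a in self.assignments]
        if len(ids) != len(set(ids)):
            raise ValueError("catalog contains duplicate seq_id assignments")
        if len(self.assignments) > self.n_input_sequences:
            raise ValueError("more assignments than input sequences")

    def __len__(self) -> int:
        return len(self.assignments)

    def seq_ids(self) -> list[str]:
        return [a.seq_id for a in self.assignments]

    def gene_ids(self) -> list[str]:
        return [a.gene_id if a.gene_id is not None else a.seq_id for a in self.assignments]

    def tf_fraction(self) -> float:
        """Fraction of input sequences classified as putative TFs."""
        if self.n_input_sequences == 0:
            return math.nan
        return len(self.assignments) / self.n_input_sequences


def assign_families(
    hits: Iterable[DomainHit],
    registry: ModelRegistry,
    proteome: Proteome,
) -> list[TFAssignment]:
    """Classify each protein with surviving hits into ranked TF families.

    Families are ranked by best (lowest) domain i-Evalue, ties by higher bit
    score then alphabetical family label. Proteins with no hits receive no
    assignment. The result is independent of the order of ``hits`` and
    follows proteome order. A hit referencing an unknown seq_id or an
    unmapped model is an error.
    """
    by_seq: dict[str, list[DomainHit]] = {}
    for h in hits:
        if h.seq_id not in proteome:
            raise ValueError(f"hit references seq_id {h.seq_id!r} not present in the proteome")
        by_seq.setdefault(h.seq_id, []).append(h)

    assignments: list[TFAssignment] = []
    for rec in proteome:
        seq_hits = by_seq.get(rec.seq_id)
        if not seq_hits:
            continue
        per_family: dict[str, list[DomainHit]] = {}
        for h in seq_hits:
            fam = registry.family_of(h.model_accession, h.model_name)
            if fam is None:
                raise ValueError(
                    f"hit model {h.model_name!r}/{h.model_accession!r} does not resolve "
                    "to a family in the registry"
                )
            per_family.setdefault(fam, []).append(h)
        ranked = sorted(
            per_family.items(),
            key=lambda kv: (
                min(h.domain_i_evalue for h in kv[1]),
                -max(h.bit_score for h in kv[1]),
                kv[0],
            ),
        )
        all_families = [
            (fam, min(h.domain_i_evalue for h in fhits), len(fhits)) for fam, fhits in ranked
        ]
        supporting = sorted(
            seq_hits, key=lambda h: (h.env_from, h.env_to, h.model_accession, h.model_name)
        )
        assignments.append(
            TFAssignment(
                seq_id=rec.seq_id,
                gene_id=rec.gene_id,
                all_families=all_families,
                supporting_hits=supporting,
            )
        )
    return assignments


def build_catalog(
    assignments: Sequence[TFAssignment],
    proteome: Proteome,
    species: Optional[str] = None,
    parameters: Optional[Mapping] = None,
) -> TFCatalog:
    """Assemble a gene-level :class:`TFCatalog`.

    If several assignments share a gene_id (primary-isoform filtering was
    skipped), only the best-scoring isoform per gene is kept, with a logged
    warning.
    """
    by_gene: dict[str, TFAssignment] = {}
    order: list[str] = []
    collapsed = 0
    for a in assignments:
        key = a.gene_id if a.gene_id is not None else a.seq_id
        if key not in by_gene:
            by_gene[key] = a
            order.append(key)
        else:
            collapsed += 1
            prev = by_gene[key]
            if (a.best_i_evalue, a.seq_id) < (prev.best_i_evalue, prev.seq_id):
                by_gene[key] = a
    if collapsed:
        warnings.warn(
            f"collapsed {collapsed} isoform assignment(s) to gene level "
            "(kept the best-scoring isoform per gene)",
            UserWarning,
        )
    return TFCatalog(
        species=species or proteome.species,
        assignments=[by_gene[k] for k in order],
        n_input_sequences=len(proteome),
        parameters=dict(parameters or {}),
    )


def family_distribution(catalog: TFCatalog, counting: str = "primary_only") -> pd.DataFrame:
    """Tabulate TF counts per family, sorted by count descending then label.

    ``primary_only`` counts each TF once under its best-scoring family, so
    counts sum to the catalog size; ``all_families`` counts every family
    membership, so counts sum to the total number of memberships.
    """
    if counting not in ("primary_only", "all_families"):
        raise ValueError("counting must be 'primary_only' or 'all_families'")
    counts: dict[str, int] = {}
    for a in catalog.assignments:
        fams = [a.primary_family] if counting == "primary_only" else [f for f, _, _ in a.all_families]
        for fam in fams:
            counts[fam] = counts.get(fam, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["family", "count"])


def write_putative_tf_fasta(catalog: TFCatalog, proteome: Proteome, path) -> None:
    """Export the putative-TF sequences, one record per assignment.

    The header carries ``family=`` and (when known) ``gene=`` tags in the
    key=value scheme, so the export is re-readable by
    :func:`tfcat.sequence_io.read_fasta`.
    """
    records: list[ProteinRecord] = []
    for a in catalog.assignments:
        try:
            rec = proteome.get(a.seq_id)
        except KeyError:
            raise ValueError(f"assignment seq_id {a.seq_id!r} not found in the proteome") from None
        tags = [f"family={a.primary_family}"]
        if a.gene_id is not None:
            tags.append(f"gene={a.gene_id}")
        records.append(
            ProteinRecord(
                seq_id=rec.seq_id,
                sequence=rec.sequence,
                gene_id=a.gene_id,
                description=" ".join(tags),
            )
        )
    if not records:
        warnings.warn(f"catalog is empty; writing empty FASTA to {path}", UserWarning)
    write_fasta(records, path)


CUSTOM_HIT_COLUMNS = ("seq_id", "model_accession", "i_evalue", "bit_score", "env_from", "env_to")


def import_custom_hits(path, registry: ModelRegistry) -> list[DomainHit]:
    """Ingest an externally produced hit table (TSV) into the standard path.

    Required columns: seq_id, model_accession, i_evalue, bit_score,
    env_from, env_to. Optional columns hmm_from/hmm_to and model_length
    refine model coverage; when absent they fall back to the registry's
    model length, then to full coverage over the envelope (the table is
    trusted to be pre-filtered). Extra columns are ignored. Rows whose
    accession is unknown to the registry are dropped with a warning,
    mirroring scan behaviour.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"seq_id": str, "model_accession": str})
    missing = [c for c in CUSTOM_HIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"custom hit table {path} is missing required column(s): {missing}")
    hits: list[DomainHit] = []
    dropped = 0
    for idx, row in df.iterrows():
        env_from, env_to = int(row["env_from"]), int(row["env_to"])
        if env_from < 1 or env_to < 1:
            raise ValueError(f"{path}: row {idx + 1}: negative or zero coordinate")
        model = registry.resolve(str(row["model_accession"]))
        if model is None:
            dropped += 1
            continue
        model_length = model.model_length
        if "model_length" in df.columns and pd.notna(row.get("model_length")):
            model_length = int(row["model_length"])
        hmm_from = int(row["hmm_from"]) if "hmm_from" in df.columns and pd.notna(row.get("hmm_from")) else 1
        if "hmm_to" in df.columns and pd.notna(row.get("hmm_to")):
            hmm_to = int(row["hmm_to"])
        else:
            hmm_to = model_length or (env_to - env_from + 1)
        hits.append(
            DomainHit(
                seq_id=str(row["seq_id"]),
                model_name=str(row.get("model_name", model.model_name)),
                model_accession=model.model_accession,
                full_seq_evalue=float(row.get("full_seq_evalue", row["i_evalue"])),
                domain_i_evalue=float(row["i_evalue"]),
                bit_score=float(row["bit_score"]),
                env_from=env_from,
                env_to=env_to,
                hmm_from=hmm_from,
                hmm_to=hmm_to,
                model_length=model_length,
            )
        )
    if dropped:
        warnings.warn(f"dropped {dropped} row(s) with accessions unknown to the registry", UserWarning)
    return hits


def catalog_to_frame(catalog: TFCatalog) -> pd.DataFrame:
    """Flatten a catalog to a table (one row per assignment)."""
    rows = []
    for a in catalog.assignments:
        rows.append(
            {
                "seq_id": a.seq_id,
                "gene_id": a.gene_id if a.gene_id is not None else "",
                "primary_family": a.primary_family,
                "all_families": ";".join(f"{f}:{e:g}:{n}" for f, e, n in a.all_families),
                "best_i_evalue": a.best_i_evalue,
                "n_domains": a.n_domains,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["seq_id", "gene_id", "primary_family", "all_families", "best_i_evalue", "n_domains"],
    )


def write_catalog_tsv(catalog: TFCatalog, path) -> None:
    catalog_to_frame(catalog).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> pd.DataFrame:
    """Read a catalog TSV back as a table (e.g. to extract annotation queries)."""
    return pd.read_csv(path, sep="\t", dtype={"seq_id": str, "gene_id": str}, keep_default_na=False)


def plot_family_distribution(distribution: pd.DataFrame, path, title: str = "TF family distribution") -> None:
    """Render the distribution table as a horizontal bar chart (thin, untested layer)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = distribution.sort_values("count")
    fig, ax = plt.subplots(figsize=(7, max(2, 0.25 * len(df))))
    ax.barh(df["family"], df["count"], color="#4878a8")
    ax.set_xlabel("putative TFs")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
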