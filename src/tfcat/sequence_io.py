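"""Protein FASTA I/O, header parsing, and proteome pre-processing filters.

Proteomes typically ship one record per transcript isoform; downstream TF
cataloguing is gene-level, so the standard pre-processing is (i) keep a
single primary isoform per gene and (ii) drop sequences derived from
alternative genome mappings (haplotype / patch scaffolds). Both filters are
implemented here, together with the header schemes that recover the gene
identity from FASTA descriptions.

Coordinates everywhere downstream are 1-based, inclusive, residue-indexed.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

#: residues accepted in input sequences (canonical 20 + ambiguity/rare codes);
#: a terminal stop '*' is tolerated but only as the last character.
AMINO_ACID_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZJUO")

HEADER_SCHEMES = ("key_value", "pipe", "opaque")

_KEY_VALUE_TOKEN = re.compile(r"^([A-Za-z_][\w.-]*)[=:](.+)$")


@dataclass
class ProteinRecord:
    """One amino-acid sequence with its parsed gene/transcript identity.

    ``seq_id`` is unique within a proteome (typically the transcript or
    protein accession); ``gene_id`` is shared across isoforms of one gene and
    may be ``None`` under the opaque header scheme. ``attributes`` holds the
    remaining parsed header fields (scheme-dependent).
    """

    seq_id: str
    sequence: str
    gene_id: Optional[str] = None
    description: str = ""
    attributes: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not self.seq_id:
            raise ValueError("record has an empty seq_id")
        if not self.sequence:
            raise ValueError(f"record {self.seq_id!r} has an empty sequence")
        body, stop = self.sequence[:-1], self.sequence[-1]
        if "*" in body:
            raise ValueError(
                f"record {self.seq_id!r}: stop '*' permitted only as last character"
            )
        residues = set(body) | ({stop} - {"*"})
        bad = residues - AMINO_ACID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.seq_id!r}: invalid residue(s) {sorted(bad)}"
            )


@dataclass
class Proteome:
    """An ordered collection of :class:`ProteinRecord` with a filter log.

    ``provenance`` records the source path and one ``(step, n_in, n_out)``
    triple per applied filter, written out by :meth:`write_filter_log`.
    """

    species: str = "unknown"
    records: list[ProteinRecord] = field(default_factory=list)
    source: Optional[str] = None
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def get(self, seq_id: str) -> ProteinRecord:
        try:
            return self._index[seq_id]
        except AttributeError:
            self._index = {r.seq_id: r for r in self.records}
            return self._index[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        try:
            self.get(seq_id)
            return True
        except KeyError:
            return False

    def seq_ids(self) -> list[str]:
        return [r.seq_id for r in self.records]

    def _derive(self, records: list[ProteinRecord], step: str) -> "Proteome":
        out = Proteome(
            species=self.species,
            records=records,
            source=self.source,
            provenance=list(self.provenance) + [(step, len(self.records), len(records))],
        )
        return out

    def write_filter_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tn_in\tn_out\n")
            for step, n_in, n_out in self.provenance:
                fh.write(f"{step}\t{n_in}\t{n_out}\n")


def _parse_header(
    seq_id: str, description: str, header_scheme: str, gene_key: str, pipe_gene_index: int
) -> tuple[Optional[str], dict]:
    """Extract (gene_id, attributes) from a FASTA header under a scheme."""
    if header_scheme == "opaque":
        return None, {}
    if header_scheme == "pipe":
        fields = seq_id.split("|")
        attributes = {f"field{i}": f for i, f in enumerate(fields)}
        gene_id = fields[pipe_gene_index] if 0 <= pipe_gene_index < len(fields) else None
        return gene_id, attributes
    if header_scheme == "key_value":
        # key=value or key:value tokens in the description (Ensembl-style
        # headers use the colon form, e.g. "gene:ENSG... chromosome:GRCh38:1:...").
        attributes: dict = {}
        for token in description.split():
            m = _KEY_VALUE_TOKEN.match(token)
            if m:
                attributes.setdefault(m.group(1), m.group(2))
        return attributes.get(gene_key), attributes
    raise ValueError(f"unknown header scheme {header_scheme!r}; expected one of {HEADER_SCHEMES}")


def read_fasta(
    path,
    header_scheme: str = "key_value",
    gene_key: str = "gene",
    pipe_gene_index: int = 1,
    species: str = "unknown",
) -> Proteome:
    """Read an amino-acid FASTA file (optionally gzip-compressed) into a Proteome.

    Sequences are uppercased and line folds removed; input order is
    preserved. ``header_scheme`` selects how gene identity is recovered:
    ``key_value`` (``gene=X`` / ``gene:X`` tokens in the description),
    ``pipe`` (positional ``|``-delimited fields of the id), or ``opaque``
    (no gene_id).

    Raises on empty sequences, duplicate seq_ids, or unknown scheme; an
    empty file yields an empty Proteome with a warning.
    """
    if header_scheme not in HEADER_SCHEMES:
        raise ValueError(
            f"unknown header scheme {header_scheme!r}; expected one of {HEADER_SCHEMES}"
        )
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if rec.id in seen:
                raise ValueError(f"duplicate seq_id {rec.id!r} in {path}")
            seen.add(rec.id)
            # description as emitted by Biopython includes the id; strip it
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id):].strip()
            gene_id, attributes = _parse_header(
                rec.id, desc, header_scheme, gene_key, pipe_gene_index
            )
            record = ProteinRecord(
                seq_id=rec.id,
                sequence=seq,
                gene_id=gene_id,
                description=desc,
                attributes=attributes,
            )
            if not record.sequence:
                raise ValueError(f"empty sequence for header {rec.description!r}")
            record.validate()
            records.append(record)
    if not records:
        warnings.warn(f"no FASTA records found in {path}", UserWarning)
    proteome = Proteome(
        species=species,
        records=records,
        source=str(path),
        provenance=[("read_fasta", len(records), len(records))],
    )
    return proteome


def write_fasta(proteome_or_records, path, line_width: int = 60) -> None:
    """Write records to FASTA, wrapping sequence lines at ``line_width``."""
    records: Iterable[ProteinRecord]
    records = proteome_or_records.records if isinstance(proteome_or_records, Proteome) else proteome_or_records
    with open(path, "w") as fh:
        for rec in records:
            header = rec.seq_id if not rec.description else f"{rec.seq_id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


PRIMARY_STRATEGIES = ("longest", "tagged_primary", "first_seen")


def _pick_primary(isoforms: list[ProteinRecord], strategy: str, primary_key: str) -> ProteinRecord:
    if strategy == "first_seen":
        return isoforms[0]
    candidates = isoforms
    if strategy == "tagged_primary":
        tagged = [
            r
            for r in isoforms
            if str(r.attributes.get(primary_key, "")).lower() in ("1", "true", "yes", "primary")
        ]
        if tagged:
            candidates = tagged
        # no tagged isoform: fall back to the longest rule among all
    # longest, ties broken by lexicographically smaller seq_id
    return min(candidates, key=lambda r: (-r.length, r.seq_id))


def select_primary_isoforms(
    proteome: Proteome,
    strategy: str = "longest",
    primary_key: str = "primary",
) -> Proteome:
    """Keep exactly one record per gene_id.

    ``longest`` (default) keeps the longest isoform, breaking length ties by
    lexicographically smaller seq_id — reproducible with no external
    annotation. ``tagged_primary`` prefers isoforms whose header carries a
    primary flag (``primary_key``), falling back to the longest rule.
    ``first_seen`` keeps the first record per gene in input order.

    Records without a gene_id are passed through unchanged with a warning.
    Idempotent: a second application is the identity.
    """
    if strategy not in PRIMARY_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {PRIMARY_STRATEGIES}")
    groups: dict[str, list[ProteinRecord]] = {}
    n_missing = 0
    for rec in proteome.records:
        if rec.gene_id is None:
            n_missing += 1
        else:
            groups.setdefault(rec.gene_id, []).append(rec)
    if n_missing:
        warnings.warn(
            f"{n_missing} record(s) without gene_id passed through unfiltered", UserWarning
        )
    keep = {
        _pick_primary(isoforms, strategy, primary_key).seq_id for isoforms in groups.values()
    }
    kept = [r for r in proteome.records if r.gene_id is None or r.seq_id in keep]
    return proteome._derive(kept, f"select_primary_isoforms[{strategy}]")


#: substrings that flag alternative genome mappings (haplotype/patch
#: scaffolds) in Ensembl-style region tags.
DEFAULT_ALT_MAPPING_SUBSTRINGS = ("PATCH", "HSCHR", "alt")


def default_alternative_mapping_rules(fld: str = "chromosome") -> list[tuple[str, str]]:
    """Build the default exclusion rules against a given header field."""
    return [(fld, s) for s in DEFAULT_ALT_MAPPING_SUBSTRINGS]


def remove_alternative_mappings(
    proteome: Proteome,
    exclusion_rules: Sequence[tuple[str, str]],
) -> Proteome:
    """Drop records whose header field matches any (field, substring) rule.

    A rule referencing a field present in no record's parsed attributes is
    an error (before any filtering): it indicates a scheme mismatch rather
    than an absence of alternative mappings. An empty rule list is the
    identity.
    """
    rules = list(exclusion_rules)
    if not rules:
        return proteome._derive(list(proteome.records), "remove_alternative_mappings")
    available = set()
    for rec in proteome.records:
        available.update(rec.attributes)
    for fld, _ in rules:
        if proteome.records and fld not in available:
            raise ValueError(
                f"exclusion rule references field {fld!r} absent from all headers "
                f"(available: {sorted(available)})"
            )

    def matches(rec: ProteinRecord) -> bool:
        return any(sub in str(rec.attributes.get(fld, "")) for fld, sub in rules)

    kept = [r for r in proteome.records if not matches(r)]
    if proteome.records and not kept:
        warnings.warn("all records matched alternative-mapping rules; proteome is empty", UserWarning)
    return proteome._derive(kept, "remove_alternative_mappings")
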