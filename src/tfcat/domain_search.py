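"""Profile-HMM domain search against a DNA-binding-domain model registry.

The registry couples a profile-HMM database (HMMER3 text format) with a
two-column mapping table from model accession to TF family label. Hits can
be produced three ways with an identical downstream contract: an in-process
scan (pyhmmer), ingestion of precomputed HMMER3 per-domain tabular output
(``domtblout``), or a user-supplied custom hit table (see
:mod:`tfcat.tf_catalog`).

E-values scale with the number of models searched, so the registry size is
logged with every scan; thresholds tuned on one registry are not directly
portable to another.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pyhmmer

from tfcat.sequence_io import Proteome

logger = logging.getLogger(__name__)

#: default per-domain independent E-value ceiling for hit filtering
DEFAULT_MAX_IEVALUE = 1e-3
#: default minimum fraction of model match states a hit must span
DEFAULT_MIN_COVERAGE = 0.30

_VERSION_SUFFIX = re.compile(r"\.\d+$")


def _strip_version(accession: str) -> str:
    return _VERSION_SUFFIX.sub("", accession)


@dataclass(frozen=True)
class DBDModel:
    """One curated DNA-binding-domain profile model.

    ``model_length`` (number of match states) is ``None`` when the registry
    was built from a family map alone, without the HMM database.
    """

    model_name: str
    model_accession: str
    family_label: str
    model_length: Optional[int] = None


@dataclass
class ModelRegistry:
    """The set of DBD models searched, with their family labels."""

    models: list[DBDModel] = field(default_factory=list)
    hmm_db_path: Optional[str] = None
    family_map_path: Optional[str] = None

    def __post_init__(self) -> None:
        self._by_accession = {}
        self._by_name = {}
        for m in self.models:
            key = _strip_version(m.model_accession)
            if key in self._by_accession:
                raise ValueError(f"duplicate model accession {m.model_accession!r} in registry")
            self._by_accession[key] = m
            self._by_name[m.model_name] = m

    def __len__(self) -> int:
        return len(self.models)

    def resolve(self, accession: Optional[str] = None, name: Optional[str] = None) -> Optional[DBDModel]:
        """Look a model up by accession (version-insensitive), else by name."""
        if accession and accession != "-":
            m = self._by_accession.get(_strip_version(accession))
            if m is not None:
                return m
        if name:
            return self._by_name.get(name)
        return None

    def family_of(self, accession: Optional[str] = None, name: Optional[str] = None) -> Optional[str]:
        m = self.resolve(accession, name)
        return m.family_label if m else None

    def model_lengths(self) -> dict[str, Optional[int]]:
        return {m.model_accession: m.model_length for m in self.models}

    @classmethod
    def from_family_map(cls, family_map_path) -> "ModelRegistry":
        """A length-less registry from a family map alone (no HMM database)."""
        mapping = read_family_map(family_map_path)
        return cls(
            models=[DBDModel(acc, acc, fam) for acc, fam in mapping.items()],
            family_map_path=str(family_map_path),
        )


def read_family_map(path) -> dict[str, str]:
    """Read a 2-column TSV (model_accession, family_label); '#' comments allowed."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated columns")
            acc, fam = parts[0].strip(), parts[1].strip()
            if acc in mapping:
                raise ValueError(f"{path}:{ln}: duplicate accession {acc!r} in family map")
            mapping[acc] = fam
    if not mapping:
        raise ValueError(f"family map {path} contains no entries")
    return mapping


def load_registry(hmm_db_path, family_map_path) -> ModelRegistry:
    """Build a :class:`ModelRegistry` from a profile-HMM database and a family map.

    The registry contains one :class:`DBDModel` per mapped model found in the
    database. Map rows whose accession is absent from the database are
    skipped with a warning; database models absent from the map are listed
    in a warning (they will never contribute hits downstream).
    """
    family_map = read_family_map(family_map_path)
    by_stripped = {_strip_version(a): (a, f) for a, f in family_map.items()}
    models: list[DBDModel] = []
    seen_keys: set[str] = set()
    unmapped_db: list[str] = []
    with pyhmmer.plan7.HMMFile(str(hmm_db_path)) as hmm_file:
        for hmm in hmm_file:
            name = hmm.name
            acc = hmm.accession or name
            key = _strip_version(acc)
            if key in by_stripped:
                _, fam = by_stripped[key]
                models.append(
                    DBDModel(
                        model_name=name,
                        model_accession=acc,
                        family_label=fam,
                        model_length=hmm.M,
                    )
                )
                seen_keys.add(key)
            else:
                unmapped_db.append(acc)
    missing = [by_stripped[k][0] for k in by_stripped if k not in seen_keys]
    if missing:
        warnings.warn(
            f"{len(missing)} family-map accession(s) absent from HMM database, skipped: "
            f"{sorted(missing)}",
            UserWarning,
        )
    if unmapped_db:
        warnings.warn(
            f"{len(unmapped_db)} database model(s) have no family mapping and are ignored: "
            f"{sorted(unmapped_db)}",
            UserWarning,
        )
    return ModelRegistry(
        models=models, hmm_db_path=str(hmm_db_path), family_map_path=str(family_map_path)
    )


@dataclass(frozen=True)
class DomainHit:
    """One per-domain profile-HMM match.

    Envelope coordinates (``env_from``/``env_to``) are 1-based inclusive
    residue positions on the protein; ``hmm_from``/``hmm_to`` are 1-based
    inclusive match-state positions on the model. ``bit_score`` and
    ``domain_i_evalue`` are the per-domain score and independent E-value.
    """

    seq_id: str
    model_name: str
    model_accession: str
    full_seq_evalue: float
    domain_i_evalue: float
    bit_score: float
    env_from: int
    env_to: int
    hmm_from: int
    hmm_to: int
    model_length: Optional[int] = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.env_from > self.env_to:
            raise ValueError(f"{self.seq_id}/{self.model_name}: env_from > env_to")
        if self.hmm_from > self.hmm_to:
            raise ValueError(f"{self.seq_id}/{self.model_name}: hmm_from > hmm_to")
        if self.domain_i_evalue < 0 or self.full_seq_evalue < 0:
            raise ValueError(f"{self.seq_id}/{self.model_name}: negative E-value")

    @property
    def env_length(self) -> int:
        return self.env_to - self.env_from + 1

    def model_coverage(self, model_length: Optional[int] = None) -> float:
        m = model_length or self.model_length
        if not m:
            raise ValueError(
                f"model length unavailable for {self.model_name}; cannot compute coverage"
            )
        return (self.hmm_to - self.hmm_from + 1) / m


@dataclass
class EngineConfig:
    """How to obtain hits: precomputed table, or an in-process pyhmmer scan."""

    domtblout_path: Optional[str] = None
    bit_cutoffs: Optional[str] = None  # e.g. "gathering" to use curated GA thresholds
    cpus: int = 1
    report_evalue: float = 10.0


def _drop_unmapped(hits: Iterable[DomainHit], registry: ModelRegistry) -> list[DomainHit]:
    kept, dropped = [], 0
    for h in hits:
        if registry.resolve(h.model_accession, h.model_name) is not None:
            kept.append(h)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} hit(s) against models absent from the registry", UserWarning)
    return kept


def scan_proteins(
    proteome: Proteome,
    registry: ModelRegistry,
    engine_config: Optional[EngineConfig] = None,
) -> list[DomainHit]:
    """Scan proteome sequences against the registry's profile-HMM database.

    With ``engine_config.domtblout_path`` set, precomputed HMMER3 per-domain
    output is ingested instead of running a scan; otherwise an in-process
    pyhmmer ``hmmscan`` is run over ``registry.hmm_db_path``. Either way,
    hits against models without a family mapping are dropped with a count,
    and the result is a pure function of (sequences, models, thresholds).
    """
    cfg = engine_config or EngineConfig()
    logger.info("scanning %d sequence(s) against registry of %d model(s)", len(proteome), len(registry))
    if cfg.domtblout_path is not None:
        hits = [h for h in parse_domtblout(cfg.domtblout_path) if h.seq_id in proteome]
        return _drop_unmapped(hits, registry)
    if registry.hmm_db_path is None or not Path(registry.hmm_db_path).exists():
        raise RuntimeError(
            "no profile-HMM engine input available: either load the registry with a "
            "readable HMM database for an in-process scan, or point "
            "EngineConfig.domtblout_path at precomputed per-domain output"
        )
    if len(proteome) == 0:
        return []
    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [
        pyhmmer.easel.TextSequence(
            name=rec.seq_id, sequence=rec.sequence.rstrip("*")
        ).digitize(alphabet)
        for rec in proteome
    ]
    with pyhmmer.plan7.HMMFile(registry.hmm_db_path) as hmm_file:
        hmms = list(hmm_file)
    lengths = {h.name: h.M for h in hmms}
    kwargs = {"cpus": cfg.cpus, "E": cfg.report_evalue}
    if cfg.bit_cutoffs:
        kwargs = {"cpus": cfg.cpus, "bit_cutoffs": cfg.bit_cutoffs}
    hits: list[DomainHit] = []
    for top_hits in pyhmmer.hmmer.hmmscan(seqs, hmms, **kwargs):
        seq_id = top_hits.query.name
        for hit in top_hits.reported:
            model_name = hit.name
            accession = hit.accession or model_name
            for dom in hit.domains.reported:
                hits.append(
                    DomainHit(
                        seq_id=seq_id,
                        model_name=model_name,
                        model_accession=accession,
                        full_seq_evalue=hit.evalue,
                        domain_i_evalue=dom.i_evalue,
                        bit_score=dom.score,
                        env_from=dom.env_from,
                        env_to=dom.env_to,
                        hmm_from=dom.alignment.hmm_from,
                        hmm_to=dom.alignment.hmm_to,
                        model_length=lengths.get(model_name),
                    )
                )
    return _drop_unmapped(hits, registry)


# --- HMMER3 per-domain tabular ("domtblout") dialect -----------------------
# whitespace-delimited; '#' comment lines; 22 fixed columns, then the free-
# text target description as the final column (may contain spaces, '-' if
# absent). hmmscan convention: target = model, query = sequence.

_N_FIXED_COLS = 22


def parse_domtblout(path) -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output into :class:`DomainHit` records."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, _N_FIXED_COLS)
            if len(parts) < _N_FIXED_COLS:
                raise ValueError(
                    f"{path}:{ln}: expected {_N_FIXED_COLS} columns plus description, "
                    f"got {len(parts)}"
                )
            desc = parts[22] if len(parts) > _N_FIXED_COLS else "-"
            try:
                hit = DomainHit(
                    seq_id=parts[3],
                    model_name=parts[0],
                    model_accession=parts[1] if parts[1] != "-" else parts[0],
                    full_seq_evalue=float(parts[6]),
                    domain_i_evalue=float(parts[12]),
                    bit_score=float(parts[13]),
                    env_from=int(parts[19]),
                    env_to=int(parts[20]),
                    hmm_from=int(parts[15]),
                    hmm_to=int(parts[16]),
                    model_length=int(parts[2]),
                    description="" if desc == "-" else desc,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
            hits.append(hit)
    return hits


def write_domtblout(hits: Sequence[DomainHit], path) -> None:
    """Serialize hits in the per-domain tabular dialect readable by :func:`parse_domtblout`.

    Numeric fields are written with full precision so that a
    parse → serialize → parse round-trip is the identity on the hit fields.
    """
    with open(path, "w") as fh:
        fh.write("# target name\taccession\ttlen\tquery name\t...\n")
        for h in hits:
            cols = [
                h.model_name,
                h.model_accession or "-",
                str(h.model_length if h.model_length is not None else 0),
                h.seq_id,
                "-",
                "0",
                repr(h.full_seq_evalue),
                repr(h.bit_score),
                "0.0",
                "1",
                "1",
                repr(h.domain_i_evalue),
                repr(h.domain_i_evalue),
                repr(h.bit_score),
                "0.0",
                str(h.hmm_from),
                str(h.hmm_to),
                str(h.env_from),
                str(h.env_to),
                str(h.env_from),
                str(h.env_to),
                "0.00",
                h.description or "-",
            ]
            fh.write(" ".join(cols) + "\n")


def filter_hits(
    hits: Sequence[DomainHit],
    max_domain_ievalue: float = DEFAULT_MAX_IEVALUE,
    min_model_coverage: float = DEFAULT_MIN_COVERAGE,
    model_lengths: Union[ModelRegistry, Mapping[str, int], None] = None,
) -> list[DomainHit]:
    """Keep hits passing both the i-Evalue ceiling and the model-coverage floor.

    Coverage is (hmm_to - hmm_from + 1) / model_length; the length comes from
    the hit itself or from ``model_lengths`` (a registry or accession→length
    mapping). Order is preserved. ``filter_hits(h, inf, 0)`` is the identity.
    """
    if not (max_domain_ievalue >= 0):
        raise ValueError("max_domain_ievalue must be non-negative and not NaN")
    if not (0.0 <= min_model_coverage <= 1.0):
        raise ValueError("min_model_coverage must lie in [0, 1]")
    kept = []
    for h in hits:
        if h.domain_i_evalue > max_domain_ievalue:
            continue
        if min_model_coverage > 0:
            m = h.model_length
            if m is None and model_lengths is not None:
                if isinstance(model_lengths, ModelRegistry):
                    mod = model_lengths.resolve(h.model_accession, h.model_name)
                    m = mod.model_length if mod else None
                else:
                    m = model_lengths.get(h.model_accession)
            if h.model_coverage(m) < min_model_coverage:
                continue
        kept.append(h)
    return kept


def _overlap_len(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.env_to, b.env_to) - max(a.env_from, b.env_from) + 1)


def resolve_overlaps(
    hits: Sequence[DomainHit], max_overlap_fraction: float = 0.2
) -> list[DomainHit]:
    """Greedy overlap resolution among hits of a single protein.

    Candidates are taken in order of descending bit score (ties: lower
    i-Evalue, then lower env_from, then accession); a candidate is rejected
    when it overlaps an already-accepted hit over more than
    ``max_overlap_fraction`` of the shorter envelope. The result is a subset
    of the input, overlap-free at the configured fraction, and independent
    of input order.
    """
    seq_ids = {h.seq_id for h in hits}
    if len(seq_ids) > 1:
        raise ValueError(f"resolve_overlaps expects hits of one protein, got {sorted(seq_ids)}")
    ordered = sorted(
        hits,
        key=lambda h: (-h.bit_score, h.domain_i_evalue, h.env_from, h.model_accession),
    )
    accepted: list[DomainHit] = []
    for cand in ordered:
        ok = True
        for acc in accepted:
            shorter = min(cand.env_length, acc.env_length)
            if _overlap_len(cand, acc) / shorter > max_overlap_fraction:
                ok = False
                break
        if ok:
            accepted.append(cand)
    accepted.sort(key=lambda h: (h.env_from, h.env_to, h.model_accession))
    return accepted
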