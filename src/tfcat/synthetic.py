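"""Synthetic fixtures with known ground truth for every pipeline stage.

Everything here is generated, never downloaded: toy proteomes with planted
DBD motif architectures (plus a mock hit table consistent with the planted
truth, and optionally real toy profile HMMs built from noisy motif
alignments), random gene trees with a planted strictly-nearest annotated
relative, and the matching metadata tables. All generators are deterministic
functions of (parameters, seed).

Background residues are drawn uniformly over the 20 canonical amino acids —
simplicity beats realism for planted-truth tests; see the package methods
note for what that does and does not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from tfcat.domain_search import DBDModel, ModelRegistry
from tfcat.sequence_io import ProteinRecord, Proteome, write_fasta
from tfcat.tree_annotation import (
    GeneTree,
    LeafMetadata,
    TreeNode,
    _distances_from,
    to_newick,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ToyFamily:
    """One toy DBD family: a fixed ≥15-residue motif standing in for a model."""

    family_label: str
    model_name: str
    model_accession: str
    motif: str


#: four mutually dissimilar 20-residue motifs, each echoing the flavour of a
#: real DBD family (C2H2 zinc finger, homeodomain, bHLH, forkhead).
DEFAULT_TOY_FAMILIES = (
    ToyFamily("zf-C2H2", "TOY_zf-C2H2", "TOY001", "CPECGKSFSQKSDLVKHQRT"),
    ToyFamily("Homeodomain", "TOY_Homeodomain", "TOY002", "RKKRTSIENRVRWFQNRRMK"),
    ToyFamily("bHLH", "TOY_bHLH", "TOY003", "ANDRERRRMQSINAGFQALR"),
    ToyFamily("Forkhead", "TOY_Forkhead", "TOY004", "KPPYSYISLITMAIQQSPNK"),
)


def toy_registry(families: Sequence[ToyFamily] = DEFAULT_TOY_FAMILIES) -> ModelRegistry:
    """A ModelRegistry over the toy families (no HMM database attached)."""
    return ModelRegistry(
        models=[
            DBDModel(
                model_name=f.model_name,
                model_accession=f.model_accession,
                family_label=f.family_label,
                model_length=len(f.motif),
            )
            for f in families
        ]
    )


def write_family_map(families: Sequence[ToyFamily], path) -> None:
    with open(path, "w") as fh:
        fh.write("# model_accession\tfamily_label\n")
        for f in families:
            fh.write(f"{f.model_accession}\t{f.family_label}\n")


@dataclass
class PlantedTruth:
    """Ground truth of a toy proteome: which primary isoforms carry which motifs.

    ``tf_assignments`` maps the primary seq_id of each planted TF gene to its
    family label and the 1-based inclusive motif intervals; ``isoform_groups``
    maps each gene to its isoform seq_ids and the designated (longest)
    primary.
    """

    tf_assignments: dict[str, tuple[str, list[tuple[int, int]]]] = field(default_factory=dict)
    isoform_groups: dict[str, tuple[list[str], str]] = field(default_factory=dict)
    seed: int = 0

    def tf_seq_ids(self) -> set[str]:
        return set(self.tf_assignments)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for fam, _ in self.tf_assignments.values():
            counts[fam] = counts.get(fam, 0) + 1
        return counts


def _random_peptide(rng: np.random.Generator, length: int) -> list[str]:
    return [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=length)]


def generate_toy_proteome(
    n_genes: int = 20,
    tf_fraction: float = 0.3,
    families: Sequence[ToyFamily] = DEFAULT_TOY_FAMILIES,
    isoforms_per_gene: tuple[int, int] = (1, 3),
    seed: int = 0,
    min_length: int = 120,
    max_length: int = 400,
) -> tuple[Proteome, PlantedTruth, pd.DataFrame]:
    """Generate a toy proteome with planted domain architectures.

    Exactly ``round(n_genes * tf_fraction)`` genes are TFs: their primary
    (longest) isoform carries 1–2 copies of one family's motif embedded in
    uniform-random background; all other sequences are pure background. The
    returned mock hit table lists exactly the planted (seq_id, model,
    interval) records in the custom-hit TSV schema, so the mock-hit pipeline
    path must recover the planted truth exactly.
    """
    if not (0.0 <= tf_fraction <= 1.0):
        raise ValueError("tf_fraction must lie in [0, 1]")
    lo, hi = isoforms_per_gene
    if lo < 1 or hi < lo:
        raise ValueError("isoforms_per_gene must be a (low, high) range with low >= 1")
    rng = np.random.default_rng(seed)
    n_tf = int(round(n_genes * tf_fraction))
    width = max(4, len(str(n_genes)))
    truth = PlantedTruth(seed=seed)
    records: list[ProteinRecord] = []
    hit_rows: list[dict] = []
    for g in range(n_genes):
        gene_id = f"g{g + 1:0{width}d}"
        n_iso = int(rng.integers(lo, hi + 1))
        lengths = sorted(
            set(int(x) for x in rng.integers(min_length, max_length + 1, size=4 * n_iso))
        )
        while len(lengths) < n_iso:  # pragma: no cover - astronomically unlikely
            lengths.append(lengths[-1] + 1)
        lengths = sorted(rng.choice(lengths, size=n_iso, replace=False).tolist())
        primary_idx = n_iso - 1  # distinct lengths: the longest isoform is unambiguous
        seq_ids = [f"{gene_id}.t{j + 1}" for j in range(n_iso)]
        is_tf = g < n_tf
        for j in range(n_iso):
            residues = _random_peptide(rng, lengths[j])
            if is_tf and j == primary_idx:
                fam = families[int(rng.integers(0, len(families)))]
                n_copies = int(rng.integers(1, 3))
                motif_len = len(fam.motif)
                intervals: list[tuple[int, int]] = []
                occupied: list[tuple[int, int]] = []
                for _ in range(n_copies):
                    for _attempt in range(100):
                        start = int(rng.integers(0, lengths[j] - motif_len + 1))
                        if all(
                            start + motif_len <= a or start >= b for a, b in occupied
                        ):
                            break
                    else:
                        continue
                    occupied.append((start, start + motif_len))
                    residues[start : start + motif_len] = list(fam.motif)
                    intervals.append((start + 1, start + motif_len))
                intervals.sort()
                truth.tf_assignments[seq_ids[j]] = (fam.family_label, intervals)
                for k, (a, b) in enumerate(intervals):
                    hit_rows.append(
                        {
                            "seq_id": seq_ids[j],
                            "model_name": fam.model_name,
                            "model_accession": fam.model_accession,
                            "i_evalue": float(f"{10 ** rng.uniform(-30.0, -10.0):.3e}"),
                            "bit_score": round(float(rng.uniform(60.0, 220.0)), 1),
                            "env_from": a,
                            "env_to": b,
                            "hmm_from": 1,
                            "hmm_to": motif_len,
                            "model_length": motif_len,
                        }
                    )
            records.append(
                ProteinRecord(
                    seq_id=seq_ids[j],
                    sequence="".join(residues),
                    gene_id=gene_id,
                    description=f"gene={gene_id}",
                    attributes={"gene": gene_id},
                )
            )
        truth.isoform_groups[gene_id] = (seq_ids, seq_ids[primary_idx])
    proteome = Proteome(
        species="toy", records=records, provenance=[("generate_toy_proteome", len(records), len(records))]
    )
    mock_hits = pd.DataFrame(
        hit_rows,
        columns=[
            "seq_id", "model_name", "model_accession", "i_evalue",
            "bit_score", "env_from", "env_to", "hmm_from", "hmm_to", "model_length",
        ],
    )
    return proteome, truth, mock_hits


def build_toy_hmm_inputs(
    families: Sequence[ToyFamily] = DEFAULT_TOY_FAMILIES,
    n_variants: int = 8,
    max_sub_fraction: float = 0.2,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Noisy ungapped alignments per family, suitable for building toy profile HMMs.

    Each alignment has ``n_variants`` rows of motif length; every variant row
    differs from the motif in at most ``max_sub_fraction`` of columns, and
    per-column substitutions are capped so the column consensus always equals
    the planted motif.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for fam in families:
        motif = fam.motif
        L = len(motif)
        per_row = int(max_sub_fraction * L)
        col_cap = (n_variants - 1) // 2  # strict majority stays with the motif residue
        col_counts = [0] * L
        rows = [motif]
        for _ in range(n_variants - 1):
            residues = list(motif)
            positions = rng.permutation(L)
            mutated = 0
            for pos in positions:
                if mutated >= per_row:
                    break
                if col_counts[pos] >= col_cap:
                    continue
                choices = [a for a in AMINO_ACIDS if a != motif[pos]]
                residues[pos] = choices[int(rng.integers(0, len(choices)))]
                col_counts[pos] += 1
                mutated += 1
            rows.append("".join(residues))
        out[fam.family_label] = rows
    return out


def build_toy_hmm_db(
    path,
    families: Sequence[ToyFamily] = DEFAULT_TOY_FAMILIES,
    n_variants: int = 8,
    seed: int = 0,
) -> None:
    """Build real profile HMMs from the toy alignments and write an HMMER3 db."""
    import pyhmmer

    alphabet = pyhmmer.easel.Alphabet.amino()
    builder = pyhmmer.plan7.Builder(alphabet)
    background = pyhmmer.plan7.Background(alphabet)
    alignments = build_toy_hmm_inputs(families, n_variants=n_variants, seed=seed)
    with open(path, "wb") as fh:
        for fam in families:
            seqs = [
                pyhmmer.easel.TextSequence(name=f"{fam.model_name}_v{i}", sequence=row)
                for i, row in enumerate(alignments[fam.family_label])
            ]
            msa = pyhmmer.easel.TextMSA(name=fam.model_name, sequences=seqs)
            hmm, _, _ = builder.build_msa(msa.digitize(alphabet), background)
            hmm.accession = fam.model_accession
            hmm.write(fh)


# --- Annotation fixtures -----------------------------------------------------


@dataclass(frozen=True)
class TreeTruth:
    """Planted annotation truth for one query in one generated tree.

    ``margin`` is the gap between the best and second-best candidate
    distances; it is strictly positive for unambiguous fixtures and exactly
    zero for tie fixtures (where ``tie_symbols`` lists both candidates).
    """

    query_id: str
    tree_file: str
    donor_leaf: str
    donor_symbol: str
    margin: float
    tie_symbols: tuple[str, ...] = ()


@dataclass
class AnnotationCase:
    """A bundle of generated gene trees, metadata, and planted truth."""

    trees: list[tuple[str, GeneTree]]
    metadata: LeafMetadata
    truth: list[TreeTruth]

    def write(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, tree in self.trees:
            (out_dir / fname).write_text(to_newick(tree) + "\n")
        with open(out_dir / "metadata.tsv", "w") as fh:
            fh.write("seq_id\tgene_symbol\tsource\n")
            for leaf_id, (symbol, tag) in sorted(self.metadata.mapping.items()):
                fh.write(f"{leaf_id}\t{symbol}\t{tag or ''}\n")
        return out_dir


def _random_background_tree(labels: list[str], rng: np.random.Generator) -> TreeNode:
    """Random binary topology by sequential joins; lengths 0.5 + Exp(1)."""

    def edge() -> float:
        return float(0.5 + rng.exponential(1.0))

    subtrees = [TreeNode(label=l, length=edge()) for l in labels]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False).tolist())
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        node = TreeNode(length=edge(), children=[a, b])
        a.parent = node
        b.parent = node
        subtrees.append(node)
    root = subtrees[0]
    root.length = None
    return root


def generate_annotation_case(
    n_leaves: int = 8,
    n_queries: int = 2,
    tie_case: bool = False,
    seed: int = 0,
) -> AnnotationCase:
    """Random gene trees with one query leaf each and a planted nearest donor.

    Each of the ``n_queries`` trees has ``n_leaves`` leaves. The query and
    its donor(s) form a shallow clade (pendant edges ~0.01) grafted onto a
    random edge of a background tree whose branch lengths are all ≥ 0.5, so
    the donor is strictly nearest by construction. With ``tie_case``, two
    donors sit at exactly equal distance (margin 0) and the truth records
    both symbols; the lexicographic tie-break should then pick the smaller
    symbol.
    """
    n_special = 3 if tie_case else 2
    if n_queries >= n_leaves:
        raise ValueError("n_queries must be smaller than n_leaves")
    if n_leaves < n_special + 1:
        raise ValueError(f"need at least {n_special + 1} leaves per tree")
    rng = np.random.default_rng(seed)
    trees: list[tuple[str, GeneTree]] = []
    truth: list[TreeTruth] = []
    mapping: dict[str, tuple[str, Optional[str]]] = {}
    for q in range(n_queries):
        query_id = f"QUERY_{q}"
        n_bg = n_leaves - n_special
        bg_labels = [f"t{q}_L{i + 1}" for i in range(n_bg)]
        root = _random_background_tree(bg_labels, rng)
        # graft the (query, donor[, donor2]) clade onto a random non-root edge
        tree_tmp = GeneTree(root)
        graftable = [n for n in tree_tmp._postorder() if n is not root]
        host = graftable[int(rng.integers(0, len(graftable)))]
        split = float(rng.uniform(0.2, 0.8)) * host.length
        graft = TreeNode(length=host.length - split)
        parent = host.parent
        parent.children[parent.children.index(host)] = graft
        graft.parent = parent
        host.length = split
        host.parent = graft
        graft.children.append(host)
        eps_q, eps_d = 0.01, 0.005
        query = TreeNode(label=query_id, length=eps_q)
        donors = [TreeNode(label=f"t{q}_D1", length=eps_d)]
        if tie_case:
            donors.append(TreeNode(label=f"t{q}_D2", length=eps_d))
        clade = TreeNode(length=float(0.5 + rng.exponential(1.0)), children=[query] + donors)
        for child in clade.children:
            child.parent = clade
        clade.parent = graft
        graft.children.append(clade)
        tree = GeneTree(root, source=f"tree_{q}.nwk")
        # metadata covers every non-query leaf; donor symbols sort before the rest
        donor_symbols = (
            (f"AAA_SYM_{q}", f"BBB_SYM_{q}") if tie_case else (f"DONOR_SYM_{q}",)
        )
        for d, sym in zip(donors, donor_symbols):
            mapping[d.label] = (sym, "donor_species")
        for l in bg_labels:
            mapping[l] = (f"ZZZ_{l}", "background_species")
        dist = _distances_from(tree, tree.leaf(query_id))
        cand = sorted(
            (dist[leaf], leaf.label) for leaf in tree.leaves if leaf.label != query_id
        )
        margin = cand[1][0] - cand[0][0]
        truth.append(
            TreeTruth(
                query_id=query_id,
                tree_file=tree.source,
                donor_leaf=donors[0].label,
                donor_symbol=donor_symbols[0],
                margin=margin,
                tie_symbols=donor_symbols if tie_case else (),
            )
        )
        trees.append((tree.source, tree))
    return AnnotationCase(trees=trees, metadata=LeafMetadata(mapping), truth=truth)


def write_toy_fixture_dir(
    out_dir,
    n_genes: int = 20,
    tf_fraction: float = 0.3,
    seed: int = 0,
    tie_case: bool = False,
    with_hmm_db: bool = True,
) -> Path:
    """Write a complete fixture set (FASTA, hit TSV, family map, trees, metadata)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome, truth, mock_hits = generate_toy_proteome(
        n_genes=n_genes, tf_fraction=tf_fraction, seed=seed
    )
    write_fasta(proteome, out_dir / "proteome.fasta")
    mock_hits.to_csv(out_dir / "mock_hits.tsv", sep="\t", index=False)
    write_family_map(DEFAULT_TOY_FAMILIES, out_dir / "family_map.tsv")
    if with_hmm_db:
        build_toy_hmm_db(out_dir / "toy_dbd.hmm", seed=seed)
    case = generate_annotation_case(tie_case=tie_case, seed=seed)
    case.write(out_dir / "trees")
    with open(out_dir / "planted_truth.tsv", "w") as fh:
        fh.write("seq_id\tfamily\tintervals\n")
        for seq_id, (fam, ivals) in sorted(truth.tf_assignments.items()):
            fh.write(f"{seq_id}\t{fam}\t{';'.join(f'{a}-{b}' for a, b in ivals)}\n")
    return out_dir
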