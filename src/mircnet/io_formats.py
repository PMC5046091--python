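"""Readers/writers for the pipeline's external formats plus preprocessing.

Expression matrices are tab-separated feature × sample tables of normalized
linear-scale intensities; sample group labels (case/control) come from a
two-column companion file.  Preprocessing follows two policies: technical
replicates are collapsed by arithmetic mean, and assay identifiers are
mapped to canonical names (miRBase-style miRNA names, or uppercase gene
symbols with probe-level averaging).
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

GROUP_LABELS = ("case", "control")


class FormatError(ValueError):
    """A file does not follow its declared format; message names the spot."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ExpressionDataset:
    """A feature × sample intensity table with case/control labels.

    ``values`` rows are features (the platform universe), columns samples.
    Intensities are non-negative, linear scale.
    """

    dataset_id: str
    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def universe(self) -> list[str]:
        return list(self.values.index)

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == "control"]

    def validate(self) -> None:
        dup = self.values.index[self.values.index.duplicated()].unique()
        if len(dup):
            raise FormatError(
                f"{self.dataset_id}: duplicate feature names {list(dup)[:5]}; "
                "resolve duplicates via map_feature_ids"
            )
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise FormatError(
                f"{self.dataset_id}: samples missing a group label: {missing[:5]}"
            )
        bad = {s: g for s, g in self.groups.items() if g not in GROUP_LABELS}
        if bad:
            raise FormatError(f"{self.dataset_id}: invalid group labels {bad}")
        for label in GROUP_LABELS:
            n = sum(1 for s in self.values.columns if self.groups[s] == label)
            if n < 2:
                raise FormatError(
                    f"{self.dataset_id}: need >= 2 '{label}' samples, found {n}"
                )


@dataclass
class FeatureIdMap:
    """Assay identifier → canonical name mapping, for one namespace."""

    entries: dict[str, str]
    namespace: str  # "mirna" | "gene"

    def __post_init__(self) -> None:
        if self.namespace not in ("mirna", "gene"):
            raise ValueError(f"unknown namespace {self.namespace!r}")

    def is_one_to_one(self, assay_id: str) -> bool:
        """True iff assay_id maps to a name no other assay id maps to."""
        name = self.entries.get(assay_id)
        if name is None:
            return False
        return self._name_multiplicity()[name] == 1

    def _name_multiplicity(self) -> Counter:
        return Counter(self.entries.values())


@dataclass
class Motif:
    name: str
    matrix: np.ndarray  # length × 4, columns A C G T, rows sum to 1

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifSet:
    motifs: list[Motif]
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # P(A), P(C), P(G), P(T)

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise FormatError("background frequencies do not sum to 1")
        for m in self.motifs:
            if m.length < 1:
                raise FormatError(f"motif {m.name}: zero length")
            sums = m.matrix.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
            if len(bad):
                raise FormatError(
                    f"motif {m.name}: probability row {bad[0]} sums to "
                    f"{sums[bad[0]]:.4g}, expected 1"
                )

    def __iter__(self):
        return iter(self.motifs)


@dataclass
class GeneSetCollection:
    """term-id → (term name, member gene symbols), symbols uppercased."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {term} is empty")

    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(
    path: str | Path,
    groups_path: str | Path,
    dataset_id: str | None = None,
    log2_input: bool = False,
    include_samples: Sequence[str] | None = None,
) -> ExpressionDataset:
    """Read a TSV expression matrix and its sample group file.

    First column holds feature names, the header row sample ids.  The group
    file has two tab-separated columns: sample id, label in {case, control}.
    ``log2_input=True`` exponentiates (2**x) so downstream fold-changes are
    ratios of linear-scale means.  ``include_samples`` restricts to a subset
    (e.g. one time point of a longitudinal design).
    """
    path = Path(path)
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse as TSV matrix: {exc}") from exc
    if values.columns.size == 0:
        raise FormatError(f"{path}: malformed header (no sample columns)")
    non_num = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(non_num):
        col = non_num[0]
        bad_rows = values.index[pd.to_numeric(values[col], errors="coerce").isna()]
        raise FormatError(
            f"{path}: non-numeric cell in column {col!r}"
            + (f", row {bad_rows[0]!r}" if len(bad_rows) else "")
        )
    groups = _read_groups(groups_path)
    if include_samples is not None:
        keep = [s for s in values.columns if s in set(include_samples)]
        values = values[keep]
    missing = [s for s in values.columns if s not in groups]
    if missing:
        raise FormatError(
            f"{path}: sample {missing[0]!r} absent from group file {groups_path}"
        )
    if log2_input:
        values = np.power(2.0, values)
    values.index = values.index.astype(str)
    return ExpressionDataset(
        dataset_id=dataset_id or path.stem,
        values=values.astype(float),
        groups={s: groups[s] for s in values.columns},
    )


def _read_groups(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sample, label = parts
            if label not in GROUP_LABELS:
                raise FormatError(
                    f"{path}:{lineno}: label {label!r} not in {GROUP_LABELS}"
                )
            out[sample] = label
    return out


def collapse_replicates(
    ds: ExpressionDataset, replicate_groups: Mapping[str, str]
) -> ExpressionDataset:
    """Average technical replicate columns (one output column per group)."""
    missing = [s for s in ds.values.columns if s not in replicate_groups]
    if missing:
        raise FormatError(
            f"{ds.dataset_id}: sample {missing[0]!r} has no replicate group"
        )
    by_rep: dict[str, list[str]] = {}
    for s in ds.values.columns:
        by_rep.setdefault(replicate_groups[s], []).append(s)
    new_groups: dict[str, str] = {}
    cols = {}
    for rep_id, members in by_rep.items():
        labels = {ds.groups[s] for s in members}
        if len(labels) > 1:
            raise FormatError(
                f"{ds.dataset_id}: replicate group {rep_id!r} spans case and control"
            )
        new_groups[rep_id] = labels.pop()
        cols[rep_id] = ds.values[members].mean(axis=1)
    values = pd.DataFrame(cols, index=ds.values.index)
    return ExpressionDataset(ds.dataset_id, values, new_groups)


def map_feature_ids(ds: ExpressionDataset, idmap: FeatureIdMap) -> ExpressionDataset:
    """Map assay identifiers to canonical names.

    miRNA namespace: only assay ids with a one-to-one relationship to a
    miRNA name (in both directions) are kept.  Gene namespace: unmapped ids
    are dropped, then rows assigned the same gene symbol are averaged per
    sample.
    """
    if idmap.namespace == "mirna":
        keep = [a for a in ds.values.index if idmap.is_one_to_one(a)]
        values = ds.values.loc[keep].rename(index=idmap.entries)
    else:
        keep = [a for a in ds.values.index if a in idmap.entries]
        values = ds.values.loc[keep].rename(
            index={a: idmap.entries[a].upper() for a in keep}
        )
        values = values.groupby(level=0, sort=False).mean()
    if values.empty:
        raise FormatError(f"{ds.dataset_id}: no mappable features")
    return ExpressionDataset(ds.dataset_id, values, dict(ds.groups))


# ---------------------------------------------------------------------------
# motifs (MEME minimal), gene sets (GMT), FASTA

# Bio.motifs' "minimal" reader renormalizes probability rows, which would
# hide malformed matrices; this parser validates them as written.


def read_motifs_meme(path: str | Path) -> MotifSet:
    """Parse the MEME minimal motif format into a validated MotifSet."""
    path = Path(path)
    lines = path.read_text().splitlines()
    background = np.full(4, 0.25)
    motifs: list[Motif] = []
    i = 0
    if not any(l.startswith("MEME version") for l in lines[:5]):
        raise FormatError(f"{path}:1: missing 'MEME version' header")
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            try:
                freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
                background = np.array([freq[b] for b in "ACGT"])
            except (IndexError, KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{i + 1}: bad background line") from exc
        elif line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name}: matrix header missing")
            header = lines[i]
            width = None
            toks = header.replace("=", " = ").split()
            for j, t in enumerate(toks):
                if t == "w" and toks[j + 1] == "=":
                    width = int(toks[j + 2])
            if width is None:
                raise FormatError(f"{path}: motif {name}: no 'w=' in matrix header")
            rows = []
            for k in range(width):
                i += 1
                try:
                    row = [float(x) for x in lines[i].split()]
                except (IndexError, ValueError) as exc:
                    raise FormatError(
                        f"{path}:{i + 1}: motif {name}: bad matrix row"
                    ) from exc
                if len(row) != 4:
                    raise FormatError(
                        f"{path}:{i + 1}: motif {name}: expected 4 columns"
                    )
                rows.append(row)
            motifs.append(Motif(name, np.array(rows)))
        i += 1
    return MotifSet(motifs=motifs, background=background)


def write_motifs_meme(motifset: MotifSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {0:.6f} C {1:.6f} G {2:.6f} T {3:.6f}\n\n".format(*motifset.background)
        )
        for m in motifset:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= 20 E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term \\t description \\t gene1 \\t gene2 ..."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, name = parts[0], parts[1]
            genes = frozenset(g.upper() for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {term} is empty")
            sets[term] = (name, genes)
    return GeneSetCollection(sets)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA → name → sequence (case preserved; lowercase marks masking)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# interaction / network tables


def read_edge_table(path: str | Path) -> list[dict]:
    """Read a TSV with header into a list of record dicts (strings kept)."""
    records: list[dict] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        for lineno, row in enumerate(reader, 2):
            if any(v is None for v in row.values()):
                raise FormatError(f"{path}:{lineno}: short row")
            records.append(dict(row))
    return records


def write_network(net, outdir: str | Path) -> dict[str, Path]:
    """Write a RegNetwork as SIF + edge/node attribute TSVs.

    SIF relation column carries the sign (+1/-1) so the file is directly
    loadable by standard network viewers.  ``edges.tsv`` is re-readable by
    :func:`read_edge_table` (round trip on src, dst, sign, category).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges = sorted(net.edges, key=lambda e: (e.src, e.dst))
    sif = outdir / "network.sif"
    with open(sif, "w") as fh:
        for e in edges:
            fh.write(f"{e.src}\t{'+1' if e.sign > 0 else '-1'}\t{e.dst}\n")
    edges_tsv = outdir / "edges.tsv"
    with open(edges_tsv, "w") as fh:
        fh.write("src\tdst\tsign\tcategory\tevidence\n")
        for e in edges:
            fh.write(f"{e.src}\t{e.dst}\t{e.sign:+d}\t{e.category}\t{e.evidence}\n")
    nodes_tsv = outdir / "nodes.tsv"
    with open(nodes_tsv, "w") as fh:
        fh.write("id\troles\n")
        for node in sorted(net.nodes):
            fh.write(f"{node}\t{','.join(sorted(net.nodes[node]))}\n")
    return {"sif": sif, "edges": edges_tsv, "nodes": nodes_tsv}


def write_expression_dataset(
    ds: ExpressionDataset, matrix_path: str | Path, groups_path: str | Path
) -> None:
    ds.values.to_csv(matrix_path, sep="\t", index_label="feature")
    with open(groups_path, "w") as fh:
        for s in ds.values.columns:
            fh.write(f"{s}\t{ds.groups[s]}\n")
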