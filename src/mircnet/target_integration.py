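"""Filtering and merging of miRNA-target and TF-miRNA interaction records.

Validated targets: TarBase-style records are kept only when confirmed by a
reporter gene assay (expression-correlation methods like microarray or
sequencing are discarded); miRTarBase-style records are dropped when their
support type is "weak".  Predicted targets: per-database score filters
(TargetScan context score <= −0.19, microT-CDS miTG >= 0.993, miRDB >= 84,
all boundaries inclusive) followed by the three-way database intersection.
Curated TF→miRNA regulations carry an activation/repression sign and an
optional feedback flag; flagged records contribute the reciprocal
miRNA→TF repression as an additional miRNA-target edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from mircnet.network_loops import REPRESSION, SignedEdge, _coerce_sign

TARGETSCAN_MAX_CONTEXT = -0.19
MICROT_MIN_SCORE = 0.993
MIRDB_MIN_SCORE = 84.0

VALIDATED_DATABASES = ("tarbase", "mirtarbase")
PREDICTED_DATABASES = ("targetscan", "mirdb", "microt_cds")


@dataclass(frozen=True)
class ValidatedTargetRecord:
    mirna: str
    gene: str
    database: str  # tarbase | mirtarbase
    method: str = ""  # tarbase: validation assay
    support: str = ""  # mirtarbase: strong / weak / NA

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna, self.gene.upper())


@dataclass(frozen=True)
class PredictedTargetRecord:
    mirna: str
    gene: str
    database: str  # targetscan | mirdb | microt_cds
    score: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna, self.gene.upper())


@dataclass(frozen=True)
class TFRegRecord:
    tf: str
    mirna: str
    sign: int  # +1 activation / -1 repression
    feedback: bool = False

    @staticmethod
    def from_raw(tf: str, mirna: str, sign, feedback) -> "TFRegRecord":
        fb = str(feedback).strip().lower() in ("1", "true", "yes", "x")
        return TFRegRecord(tf.upper(), mirna, _coerce_sign(sign), fb)


# ---------------------------------------------------------------------------
# record constructors from raw TSV dicts (io_formats.read_edge_table output)


def validated_records_from_table(rows: Iterable[dict]) -> list[ValidatedTargetRecord]:
    return [
        ValidatedTargetRecord(
            mirna=r["mirna"],
            gene=r["gene"],
            database=r["database"].strip().lower(),
            method=r.get("method", "") or "",
            support=r.get("support", "") or "",
        )
        for r in rows
    ]


def predicted_records_from_table(rows: Iterable[dict]) -> list[PredictedTargetRecord]:
    return [
        PredictedTargetRecord(
            mirna=r["mirna"],
            gene=r["gene"],
            database=r["database"].strip().lower(),
            score=float(r["score"]),
        )
        for r in rows
    ]


def tf_records_from_table(rows: Iterable[dict]) -> list[TFRegRecord]:
    return [
        TFRegRecord.from_raw(r["tf"], r["mirna"], r["sign"], r.get("feedback", ""))
        for r in rows
    ]


# ---------------------------------------------------------------------------
# filters


def filter_validated(
    records: Iterable[ValidatedTargetRecord],
) -> set[tuple[str, str]]:
    """Pairs surviving the per-database validation-quality filters."""
    out: set[tuple[str, str]] = set()
    for rec in records:
        if rec.database == "tarbase":
            if rec.method.strip().lower() == "reporter gene assay":
                out.add(rec.pair)
        elif rec.database == "mirtarbase":
            if rec.support.strip().lower() != "weak":
                out.add(rec.pair)
        else:
            raise ValueError(f"unknown validated-target database {rec.database!r}")
    return out


def passes_score_filter(rec: PredictedTargetRecord) -> bool:
    if rec.database == "targetscan":
        return rec.score <= TARGETSCAN_MAX_CONTEXT
    if rec.database == "microt_cds":
        return rec.score >= MICROT_MIN_SCORE
    if rec.database == "mirdb":
        return rec.score >= MIRDB_MIN_SCORE
    raise ValueError(f"unknown prediction database {rec.database!r}")


def filter_predicted(
    records: Iterable[PredictedTargetRecord],
) -> set[tuple[str, str]]:
    """Three-way intersection of per-database score-passing pair sets."""
    pass_sets: dict[str, set[tuple[str, str]]] = {
        db: set() for db in PREDICTED_DATABASES
    }
    for rec in records:
        if passes_score_filter(rec):
            pass_sets[rec.database].add(rec.pair)
    return set.intersection(*pass_sets.values())


def merge_target_edges(
    validated: set[tuple[str, str]], predicted: set[tuple[str, str]]
) -> list[SignedEdge]:
    """Union of validated and predicted miRNA-target pairs as repression edges."""
    edges = []
    for mirna, gene in sorted(validated | predicted):
        if (mirna, gene) in validated and (mirna, gene) in predicted:
            ev = "both"
        elif (mirna, gene) in validated:
            ev = "validated"
        else:
            ev = "predicted"
        edges.append(
            SignedEdge(
                src=mirna, dst=gene, sign=REPRESSION,
                category="mirna_target", evidence=ev,
            )
        )
    return edges


def feedback_partner_edges(
    tfregs: Iterable[TFRegRecord], target_edges: Sequence[SignedEdge]
) -> list[SignedEdge]:
    """Add the reciprocal miRNA→TF repression for feedback-flagged records.

    A TF–miRNA regulation flagged as a feedback loop implies the miRNA
    also represses the TF; those miRNA→TF edges are merged into the
    miRNA-target edge list (deduplicated against pairs already present).
    """
    existing = {(e.src, e.dst): e for e in target_edges}
    out = list(target_edges)
    seen = set(existing)
    for rec in tfregs:
        if not rec.feedback:
            continue
        key = (rec.mirna, rec.tf)
        if key in seen:
            continue
        seen.add(key)
        out.append(
            SignedEdge(
                src=rec.mirna, dst=rec.tf, sign=REPRESSION,
                category="mirna_target", evidence="validated",
            )
        )
    return out


def tf_edges_from_records(tfregs: Iterable[TFRegRecord]) -> list[SignedEdge]:
    """Curated TF→miRNA regulations as signed tf_mirna edges."""
    seen = {}
    for rec in tfregs:
        key = (rec.tf, rec.mirna)
        if key in seen and seen[key].sign != rec.sign:
            raise ValueError(f"contradictory signs for TF regulation {key}")
        seen[key] = SignedEdge(
            src=rec.tf, dst=rec.mirna, sign=rec.sign,
            category="tf_mirna", evidence="validated",
        )
    return [seen[k] for k in sorted(seen)]
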