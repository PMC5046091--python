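"""Synthetic multi-dataset expression studies with recorded ground truth.

The generator emulates the structure of a blood microarray compendium:
four case/control datasets per molecule type with unbalanced group sizes
((20,21), (59,37), (23,70), (8,8) by default), partially overlapping
platform universes of ~850 features (shared core + platform-private
features), and planted differential-expression signals of three classes —
*consensus* (DE in >= 3 datasets, consistent direction), *inconsistent*
(DE in >= 3 datasets, conflicting directions) and *sporadic* (DE in <= 2
datasets).  Intensities are lognormal: a per-feature baseline mean times a
lognormal noise term; case samples of a planted feature are additionally
multiplied (direction up) or divided (down) by the effect size δ, so the
ratio-of-means fold-change targets δ in expectation.

Companion generators emit interaction-database fixtures whose records
straddle the target-filter cutoffs (with truth flags recording which must
survive each filter), and promoter/motif fixtures with planted consensus
binding sites at recorded offsets.  All outputs are pure functions of
(spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mircnet.io_formats import (
    ExpressionDataset,
    Motif,
    MotifSet,
    write_expression_dataset,
    write_fasta,
    write_motifs_meme,
)
from mircnet.target_integration import (
    MICROT_MIN_SCORE,
    MIRDB_MIN_SCORE,
    TARGETSCAN_MAX_CONTEXT,
    PredictedTargetRecord,
    TFRegRecord,
    ValidatedTargetRecord,
)

CONSENSUS, INCONSISTENT, SPORADIC = "consensus", "inconsistent", "sporadic"

# default per-dataset (case, control) sample counts, one tuple per dataset
DEFAULT_GROUP_SIZES = ((20, 21), (59, 37), (23, 70), (8, 8))


@dataclass
class SimulationSpec:
    """Study design of a synthetic expression compendium.

    universe_size: features measured per platform (~850, emulating mature
    miRNA panels of fewer than 900 identifiers).
    universe_overlap_fraction: fraction of each platform universe drawn
    from the cross-platform shared core.
    effect_size: multiplicative case-mean shift δ > 1.
    noise_sd: standard deviation of the natural-log lognormal noise.
    """

    n_datasets: int = 4
    universe_size: int = 850
    universe_overlap_fraction: float = 0.6
    group_sizes: Sequence[tuple[int, int]] = DEFAULT_GROUP_SIZES
    n_true_consensus: int = 18
    n_inconsistent: int = 10
    n_sporadic: int = 20
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_log_mean: float = 6.0
    baseline_log_sd: float = 1.0
    k_min: int = 3
    namespace: str = "mirna"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if not 0 < self.universe_overlap_fraction <= 1:
            raise ValueError("universe_overlap_fraction must be in (0, 1]")
        if min(self.n_true_consensus, self.n_inconsistent, self.n_sporadic) < 0:
            raise ValueError("planted counts must be >= 0")
        if len(self.group_sizes) != self.n_datasets:
            raise ValueError(
                f"group_sizes has {len(self.group_sizes)} entries for "
                f"{self.n_datasets} datasets"
            )
        if any(min(c, h) < 2 for c, h in self.group_sizes):
            raise ValueError("need >= 2 samples per group in every dataset")
        planted = self.n_true_consensus + self.n_inconsistent + self.n_sporadic
        if planted > self.core_size:
            raise ValueError(
                f"{planted} planted features exceed the shared core "
                f"({self.core_size} features)"
            )

    @property
    def core_size(self) -> int:
        return round(self.universe_overlap_fraction * self.universe_size)

    def feature_name(self, i: int) -> str:
        if self.namespace == "mirna":
            return f"miR-sim-{i + 1:04d}"
        return f"GSIM{i + 1:04d}"


@dataclass
class TruthFeature:
    feature: str
    klass: str  # consensus | inconsistent | sporadic
    directions: dict[str, str]  # dataset id -> "up"/"down" where planted


@dataclass
class TruthSite:
    tf: str
    promoter: str
    offset: int  # footprint start in window coordinates
    strand: str


@dataclass
class SyntheticTruth:
    """Ground truth of all planted signals, reproducible from (spec, seed)."""

    features: dict[str, TruthFeature] = field(default_factory=dict)
    sites: list[TruthSite] = field(default_factory=list)
    validated_flags: list[bool] = field(default_factory=list)
    predicted_flags: list[bool] = field(default_factory=list)
    validated_pairs: set[tuple[str, str]] = field(default_factory=set)
    predicted_pairs: set[tuple[str, str]] = field(default_factory=set)

    def features_of_class(self, klass: str) -> list[str]:
        return sorted(f for f, t in self.features.items() if t.klass == klass)


# ---------------------------------------------------------------------------
# expression


def simulate_expression_datasets(
    spec: SimulationSpec,
) -> tuple[list[ExpressionDataset], SyntheticTruth]:
    """Generate the per-dataset intensity tables and the planted truth."""
    rng = np.random.default_rng(spec.seed)
    core = [spec.feature_name(i) for i in range(spec.core_size)]
    n_private = spec.universe_size - spec.core_size
    universes = []
    idx = spec.core_size
    for _ in range(spec.n_datasets):
        private = [spec.feature_name(idx + j) for j in range(n_private)]
        idx += n_private
        universes.append(core + private)

    all_features = sorted({f for u in universes for f in u})
    baseline = pd.Series(
        np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd,
                          len(all_features))),
        index=all_features,
    )

    ds_ids = [f"sim{d + 1}" for d in range(spec.n_datasets)]
    truth = SyntheticTruth()
    planted_pool = list(rng.permutation(core))
    take = lambda n: [planted_pool.pop() for _ in range(n)]

    for feat in take(spec.n_true_consensus):
        n_sup = int(rng.integers(spec.k_min, spec.n_datasets + 1))
        sup = rng.choice(spec.n_datasets, size=n_sup, replace=False)
        direction = "up" if rng.random() < 0.5 else "down"
        truth.features[feat] = TruthFeature(
            feat, CONSENSUS, {ds_ids[d]: direction for d in sup}
        )
    for feat in take(spec.n_inconsistent):
        n_sup = int(rng.integers(spec.k_min, spec.n_datasets + 1))
        sup = sorted(rng.choice(spec.n_datasets, size=n_sup, replace=False))
        dirs = {ds_ids[d]: "up" for d in sup}
        dirs[ds_ids[sup[0]]] = "down"  # guarantee a conflict
        truth.features[feat] = TruthFeature(feat, INCONSISTENT, dirs)
    for feat in take(spec.n_sporadic):
        n_sup = int(rng.integers(1, min(3, spec.k_min)))  # 1 or 2 datasets
        sup = rng.choice(spec.n_datasets, size=n_sup, replace=False)
        direction = "up" if rng.random() < 0.5 else "down"
        truth.features[feat] = TruthFeature(
            feat, SPORADIC, {ds_ids[d]: direction for d in sup}
        )

    datasets = []
    for d, ds_id in enumerate(ds_ids):
        uni = universes[d]
        n_case, n_ctrl = spec.group_sizes[d]
        n = n_case + n_ctrl
        mu = baseline[uni].to_numpy()[:, None]
        noise = np.exp(rng.normal(0.0, spec.noise_sd, (len(uni), n)))
        values = mu * noise
        shift = np.ones(len(uni))
        for i, feat in enumerate(uni):
            tf = truth.features.get(feat)
            if tf and ds_id in tf.directions:
                shift[i] = (
                    spec.effect_size
                    if tf.directions[ds_id] == "up"
                    else 1.0 / spec.effect_size
                )
        values[:, :n_case] *= shift[:, None]
        samples = [f"{ds_id}_case{j + 1}" for j in range(n_case)] + [
            f"{ds_id}_ctrl{j + 1}" for j in range(n_ctrl)
        ]
        groups = {s: ("case" if j < n_case else "control")
                  for j, s in enumerate(samples)}
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_id,
                values=pd.DataFrame(values, index=uni, columns=samples),
                groups=groups,
            )
        )
    return datasets, truth


# ---------------------------------------------------------------------------
# interaction databases

_TARBASE_METHODS = ("reporter gene assay", "microarray", "sequencing")
_PREDICTED_SCORES = {
    # (passing score, failing score) per database; boundaries are inclusive,
    # so the exact cutoff value appears on the passing side
    "targetscan": (TARGETSCAN_MAX_CONTEXT, -0.18),
    "microt_cds": (MICROT_MIN_SCORE, 0.992),
    "mirdb": (MIRDB_MIN_SCORE, 83.9),
}


def simulate_interaction_databases(
    truth: SyntheticTruth,
    mirnas: Sequence[str],
    n_genes: int = 60,
    n_validated: int = 40,
    n_predicted: int = 40,
    n_tfs: int = 6,
    seed: int = 0,
) -> dict:
    """Interaction-table fixtures with per-record retention truth.

    Validated records cycle through TarBase assay methods and miRTarBase
    support classes; predicted records cover every pattern of database
    membership and above/below-cutoff scores, including scores exactly at
    the cutoffs.  TF–miRNA records carry activation/repression signs with
    a subset flagged as feedback loops.  Truth flags are assigned by
    construction (scenario choice), not by running the filters.
    """
    rng = np.random.default_rng(seed)
    genes = [f"TG{i + 1:03d}" for i in range(n_genes)]
    validated: list[ValidatedTargetRecord] = []
    for i in range(n_validated):
        mirna = mirnas[int(rng.integers(len(mirnas)))]
        gene = genes[int(rng.integers(len(genes)))]
        if i % 2 == 0:
            method = _TARBASE_METHODS[(i // 2) % 3]
            rec = ValidatedTargetRecord(mirna, gene, "tarbase", method=method)
            keep = method == "reporter gene assay"
        else:
            support = ("strong", "weak", "NA")[(i // 2) % 3]
            rec = ValidatedTargetRecord(mirna, gene, "mirtarbase", support=support)
            keep = support != "weak"
        validated.append(rec)
        truth.validated_flags.append(keep)
        if keep:
            truth.validated_pairs.add(rec.pair)

    predicted: list[PredictedTargetRecord] = []
    dbs = list(_PREDICTED_SCORES)
    # membership pattern: which databases list the pair, and pass/fail there
    patterns = [
        (frozenset(dbs), (True, True, True)),    # in all 3, all pass -> kept
        (frozenset(dbs), (True, True, False)),   # in all 3, one fails
        (frozenset(dbs[:2]), (True, True, None)),  # in only 2
        (frozenset(dbs[:1]), (True, None, None)),  # in only 1
    ]
    for i in range(n_predicted):
        mirna = mirnas[int(rng.integers(len(mirnas)))]
        gene = f"PG{i + 1:03d}"  # unique gene per pattern instance
        member, passes = patterns[i % len(patterns)]
        kept = member == frozenset(dbs) and all(p for p in passes if p is not None)
        for db, ok in zip(dbs, passes):
            if db not in member or ok is None:
                continue
            good, bad = _PREDICTED_SCORES[db]
            rec = PredictedTargetRecord(mirna, gene, db, good if ok else bad)
            predicted.append(rec)
            truth.predicted_flags.append(ok)
        if kept:
            truth.predicted_pairs.add((mirna, gene.upper()))

    tf_names = [f"TFSIM{i + 1}" for i in range(n_tfs)]
    tfregs: list[TFRegRecord] = []
    for i, tf in enumerate(tf_names):
        mirna = mirnas[i % len(mirnas)]
        sign = 1 if i % 3 else -1
        tfregs.append(TFRegRecord(tf, mirna, sign, feedback=(i % 2 == 0)))
    return {
        "validated": validated,
        "predicted": predicted,
        "tf_mirna": tfregs,
        "genes": genes,
    }


# ---------------------------------------------------------------------------
# promoters and motifs


def default_motifs(n_motifs: int = 3, length: int = 8,
                   dominance: float = 0.85, seed: int = 0,
                   names: Sequence[str] | None = None) -> MotifSet:
    """Sharp synthetic PWMs: one dominant base per position."""
    rng = np.random.default_rng(seed)
    motifs = []
    for i in range(n_motifs):
        mat = np.full((length, 4), (1 - dominance) / 3)
        for pos in range(length):
            mat[pos, int(rng.integers(4))] = dominance
        name = names[i] if names else f"TFSIM{i + 1}"
        motifs.append(Motif(name, mat))
    return MotifSet(motifs=motifs, background=np.full(4, 0.25))


def simulate_promoters(
    motifs: MotifSet,
    n_promoters: int = 20,
    plant_fraction: float = 0.5,
    seed: int = 0,
    length: int = 2000,
    masked_fraction: float = 0.1,
    promoter_names: Sequence[str] | None = None,
) -> tuple[dict[str, str], pd.DataFrame, list[TruthSite]]:
    """Background promoter windows with planted motif consensus sites.

    Background bases are i.i.d. from the motif background; a
    ``plant_fraction`` of promoters receives the maximal-probability
    consensus string of a random motif at a recorded offset, on either
    strand.  A ``masked_fraction`` of promoters gets a run of N.  Returns
    (name → sequence, TSS table, planted sites); the TSS table places every
    window at tss=1500 on its own sequence, '+' strand, so
    :func:`mircnet.motif_scan.extract_promoter` reproduces the window.
    """
    rng = np.random.default_rng(seed)
    if any(m.length >= length for m in motifs):
        raise ValueError("motif longer than the promoter window")
    names = list(promoter_names) if promoter_names else [
        f"PROM{i + 1:03d}" for i in range(n_promoters)
    ]
    from mircnet.motif_scan import reverse_complement

    seqs: dict[str, str] = {}
    sites: list[TruthSite] = []
    motif_list = list(motifs)
    for i, name in enumerate(names):
        bases = rng.choice(list("ACGT"), size=length, p=motifs.background)
        seq = list("".join(bases))
        if rng.random() < masked_fraction:
            start = int(rng.integers(0, length - 50))
            seq[start : start + 50] = "N" * 50
        if rng.random() < plant_fraction and motif_list:
            m = motif_list[int(rng.integers(len(motif_list)))]
            site = m.consensus()
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = site if strand == "+" else reverse_complement(site)
            off = int(rng.integers(0, length - m.length))
            seq[off : off + m.length] = inserted
            sites.append(TruthSite(tf=m.name, promoter=name, offset=off,
                                   strand=strand))
        seqs[name] = "".join(seq)
    tss = pd.DataFrame(
        {"target": names, "seq_name": names,
         "tss": [1500] * len(names), "strand": ["+"] * len(names)}
    )
    return seqs, tss, sites


# ---------------------------------------------------------------------------
# complete study directory


def write_study_fixtures(
    outdir: str | Path,
    spec: SimulationSpec | None = None,
    seed: int | None = None,
) -> dict:
    """Write a complete synthetic study (all pipeline inputs) to ``outdir``.

    Emits expression matrices + group files, interaction tables, a MEME
    motif file, promoter FASTA + TSS table, a GMT gene-set collection, and
    ``truth.json``.  Returns a manifest of paths plus the truth object.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or SimulationSpec()
    if seed is not None:
        spec.seed = seed
    datasets, truth = simulate_expression_datasets(spec)
    paths: dict[str, object] = {"datasets": []}
    for ds in datasets:
        m = outdir / f"expr_{ds.dataset_id}.tsv"
        g = outdir / f"groups_{ds.dataset_id}.tsv"
        write_expression_dataset(ds, m, g)
        paths["datasets"].append({"id": ds.dataset_id, "matrix": str(m),
                                  "groups": str(g)})

    consensus_mirnas = truth.features_of_class(CONSENSUS) or [
        spec.feature_name(i) for i in range(5)
    ]
    fixtures = simulate_interaction_databases(
        truth, consensus_mirnas, seed=spec.seed + 1
    )
    vt = outdir / "validated_targets.tsv"
    with open(vt, "w") as fh:
        fh.write("mirna\tgene\tdatabase\tmethod\tsupport\n")
        for r in fixtures["validated"]:
            fh.write(f"{r.mirna}\t{r.gene}\t{r.database}\t{r.method}\t{r.support}\n")
    pt = outdir / "predicted_targets.tsv"
    with open(pt, "w") as fh:
        fh.write("mirna\tgene\tdatabase\tscore\n")
        for r in fixtures["predicted"]:
            fh.write(f"{r.mirna}\t{r.gene}\t{r.database}\t{r.score}\n")
    tt = outdir / "tf_mirna.tsv"
    with open(tt, "w") as fh:
        fh.write("tf\tmirna\tsign\tfeedback\n")
        for r in fixtures["tf_mirna"]:
            sign = "activation" if r.sign > 0 else "repression"
            fh.write(f"{r.tf}\t{r.mirna}\t{sign}\t{'x' if r.feedback else ''}\n")

    tf_names = [r.tf for r in fixtures["tf_mirna"]]
    motifs = default_motifs(n_motifs=min(3, len(tf_names)), seed=spec.seed + 2,
                            names=tf_names)
    mm = outdir / "motifs.meme"
    write_motifs_meme(motifs, mm)
    # promoters of the miRNAs and of their target genes
    promoter_names = consensus_mirnas[:6] + fixtures["genes"][:10]
    seqs, tss, sites = simulate_promoters(
        motifs, n_promoters=len(promoter_names), plant_fraction=0.5,
        seed=spec.seed + 3, promoter_names=promoter_names,
    )
    truth.sites = sites
    fa = outdir / "promoters.fasta"
    write_fasta(seqs, fa)
    tss_path = outdir / "tss.tsv"
    tss.to_csv(tss_path, sep="\t", index=False)

    gmt = outdir / "gene_sets.gmt"
    _write_gene_sets(gmt, fixtures["genes"], seed=spec.seed + 4)

    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth_to_dict(truth), fh, indent=1)
    paths.update(
        validated_targets=str(vt), predicted_targets=str(pt), tf_mirna=str(tt),
        motifs=str(mm), promoters=str(fa), tss=str(tss_path),
        gene_sets=str(gmt), truth=str(truth_path),
    )
    return {"paths": paths, "truth": truth, "spec": spec}


def _write_gene_sets(path: Path, genes: Sequence[str], seed: int,
                     n_terms: int = 8, term_size: int = 12) -> None:
    rng = np.random.default_rng(seed)
    extra = [f"BG{i + 1:03d}" for i in range(200)]
    pool = list(genes) + extra
    with open(path, "w") as fh:
        for t in range(n_terms):
            members = rng.choice(pool, size=term_size, replace=False)
            fh.write(f"TERM{t + 1:02d}\tsynthetic term {t + 1}\t"
                     + "\t".join(members) + "\n")


def truth_to_dict(truth: SyntheticTruth) -> dict:
    return {
        "features": {f: asdict(t) for f, t in truth.features.items()},
        "sites": [asdict(s) for s in truth.sites],
        "validated_pairs": sorted(map(list, truth.validated_pairs)),
        "predicted_pairs": sorted(map(list, truth.predicted_pairs)),
        "validated_flags": truth.validated_flags,
        "predicted_flags": truth.predicted_flags,
    }
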