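"""Per-dataset differential expression, cross-dataset consensus, permutation tests.

The consensus call uses two criteria: a feature must be differentially
expressed (two-sample t-test p <= alpha) in at least ``k_min`` of the
datasets (overlap criterion), and the fold-change direction must agree in
every supporting dataset (directional criterion).  Because each dataset uses
a raw per-feature p <= alpha with no multiplicity correction, error control
comes from the consensus requirement itself, whose significance is assessed
by a permutation test: per dataset, a random subset of the platform universe
of the observed DE size is drawn, and the consensus count of the random
draw is compared with the observed one over B replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mircnet.io_formats import ExpressionDataset

logger = logging.getLogger(__name__)

UP, DOWN, UNCHANGED = "up", "down", "unchanged"


@dataclass
class ConsensusConfig:
    """Thresholds of the two-criterion consensus.

    alpha: per-dataset significance level for calling a feature DE.
    k_min: minimum number of supporting datasets.
    require_direction: apply the directional criterion.
    """

    alpha: float = 0.05
    k_min: int = 3
    require_direction: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.k_min < 1:
            raise ValueError(f"k_min must be >= 1, got {self.k_min}")


@dataclass
class ConsensusCall:
    feature: str
    supporting_datasets: frozenset[str]
    directions: dict[str, str]  # dataset -> up/down/unchanged (supporting only)
    passes_overlap: bool
    passes_direction: bool


@dataclass
class PermutationResult:
    """Outcome of a permutation consensus test.

    ``p_report`` follows the bound convention: r/B when at least one null
    replicate reaches the observed statistic, otherwise the bound 1/B
    (read "p < 1/B"); ``is_bound`` flags the latter.  The conservative
    (r+1)/(B+1) estimator is available via ``p_convention='plus_one'``.
    """

    observed: int
    null_counts: np.ndarray
    exceedances: int
    B: int
    p_report: float
    seed: int | None
    is_bound: bool = False

    @property
    def ties(self) -> int:
        return int(np.sum(self.null_counts == self.observed))

    def uniformized_p(self, rng: np.random.Generator | None = None) -> float:
        """Randomized PIT p-value (r' + V*ties)/B with V ~ U(0,1).

        r' counts strict exceedances.  Exactly Uniform(0,1) when the
        observed statistic is exchangeable with the null replicates; used
        for calibration diagnostics, not for reporting.
        """
        rng = rng or np.random.default_rng()
        strict = int(np.sum(self.null_counts > self.observed))
        return (strict + rng.uniform() * self.ties) / self.B


# ---------------------------------------------------------------------------
# per-dataset differential expression


def differential_expression(
    ds: ExpressionDataset, test: str = "welch"
) -> pd.DataFrame:
    """Two-sided two-sample t-test and fold-change per feature.

    Fold-change is mean(case)/mean(control); direction is up (>1),
    down (<1) or unchanged (=1).  Zero-variance features with equal group
    means get p = 1; features with zero control mean are excluded (flagged
    in the log) because their fold-change is undefined.

    Returns a DataFrame indexed by feature with columns
    ``p_value, fold_change, direction``.
    """
    if test not in ("welch", "student"):
        raise ValueError(f"test must be 'welch' or 'student', got {test!r}")
    case = ds.values[ds.case_samples].to_numpy(float)
    ctrl = ds.values[ds.control_samples].to_numpy(float)
    mean_case = case.mean(axis=1)
    mean_ctrl = ctrl.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(
            case, ctrl, axis=1, equal_var=(test == "student")
        )
    # degenerate features: both groups constant -> scipy yields nan
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(mean_case, mean_ctrl)
        p = np.where(degenerate & equal, 1.0, p)
        p = np.where(degenerate & ~equal, 0.0, p)

    zero_ctrl = mean_ctrl == 0
    if zero_ctrl.any():
        excluded = list(np.asarray(ds.universe)[zero_ctrl])
        logger.warning(
            "%s: excluding %d feature(s) with zero control mean: %s",
            ds.dataset_id,
            len(excluded),
            excluded[:5],
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_case / mean_ctrl
    out = pd.DataFrame(
        {
            "p_value": p,
            "fold_change": fc,
            "direction": np.where(fc > 1, UP, np.where(fc < 1, DOWN, UNCHANGED)),
        },
        index=pd.Index(ds.universe, name="feature"),
    )
    return out[~zero_ctrl]


# ---------------------------------------------------------------------------
# consensus across datasets


def consensus_select(
    de_tables: Mapping[str, pd.DataFrame], cfg: ConsensusConfig | None = None
) -> list[ConsensusCall]:
    """Apply the two-criterion consensus across per-dataset DE tables.

    One call per feature appearing in at least one table; features absent
    from a platform simply lack that dataset's vote.  ``passes_overlap``
    means p <= alpha in >= k_min datasets; ``passes_direction`` additionally
    requires all supporting directions to agree and not be 'unchanged'.
    """
    cfg = cfg or ConsensusConfig()
    if len(de_tables) < cfg.k_min:
        raise ValueError(
            f"k_min={cfg.k_min} exceeds the number of datasets ({len(de_tables)})"
        )
    features: set[str] = set()
    for tbl in de_tables.values():
        features.update(tbl.index)
    calls = []
    for feat in sorted(features):
        supporting = {}
        for ds_id, tbl in de_tables.items():
            if feat in tbl.index and tbl.at[feat, "p_value"] <= cfg.alpha:
                supporting[ds_id] = tbl.at[feat, "direction"]
        overlap = len(supporting) >= cfg.k_min
        dirs = set(supporting.values())
        direction_ok = overlap and len(dirs) == 1 and UNCHANGED not in dirs
        calls.append(
            ConsensusCall(
                feature=feat,
                supporting_datasets=frozenset(supporting),
                directions=supporting,
                passes_overlap=overlap,
                passes_direction=direction_ok,
            )
        )
    return calls


def consensus_features(
    calls: Iterable[ConsensusCall], require_direction: bool = True
) -> list[str]:
    """Features passing the consensus (both criteria, or overlap only)."""
    key = "passes_direction" if require_direction else "passes_overlap"
    return [c.feature for c in calls if getattr(c, key)]


def calls_to_frame(calls: Iterable[ConsensusCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        dirs = set(c.directions.values())
        rows.append(
            {
                "feature": c.feature,
                "n_supporting": len(c.supporting_datasets),
                "supporting_datasets": ",".join(sorted(c.supporting_datasets)),
                "direction": dirs.pop() if len(dirs) == 1 else "mixed",
                "passes_overlap": c.passes_overlap,
                "passes_direction": c.passes_direction,
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def mean_fold_change(
    de_tables: Mapping[str, pd.DataFrame], feature: str
) -> float:
    """Arithmetic mean of the feature's per-dataset fold-changes."""
    fcs = [
        float(tbl.at[feature, "fold_change"])
        for tbl in de_tables.values()
        if feature in tbl.index
    ]
    return float(np.mean(fcs))


# ---------------------------------------------------------------------------
# permutation tests

_DIR_CODE = {UP: 1, DOWN: -1, UNCHANGED: 0}


def observed_consensus_count(
    de_sets: Mapping[str, Mapping[str, str]], k_min: int, require_direction: bool
) -> int:
    """Count features DE in >= k_min datasets (directions agreeing if asked).

    ``de_sets`` maps dataset -> {feature -> direction} for its DE features.
    """
    votes: dict[str, list[str]] = {}
    for per_ds in de_sets.values():
        for feat, d in per_ds.items():
            votes.setdefault(feat, []).append(d)
    n = 0
    for dirs in votes.values():
        if len(dirs) < k_min:
            continue
        if require_direction:
            if len(set(dirs)) == 1 and dirs[0] != UNCHANGED:
                n += 1
        else:
            n += 1
    return n


def permutation_consensus_test(
    universes: Mapping[str, Sequence[str]],
    de_sets: Mapping[str, Mapping[str, str]],
    cfg: ConsensusConfig | None = None,
    B: int = 5000,
    seed: int | None = None,
    directions: Mapping[str, Mapping[str, str]] | None = None,
    direction_mode: str = "observed",
    p_convention: str = "bound",
) -> PermutationResult:
    """Permutation null for the consensus count.

    Each replicate draws, for every dataset d, a uniform random subset of
    ``universes[d]`` of size |de_sets[d]|; the statistic T is the number of
    features drawn in >= k_min datasets.  With ``cfg.require_direction``,
    a drawn feature inherits the dataset's observed direction for it
    (``direction_mode='observed'``, taken from ``directions`` or, for DE
    features, from ``de_sets``) — membership alone is randomized — and T
    counts only features whose supporting directions all agree.
    ``direction_mode='random_sign'`` instead assigns i.i.d. ±1 signs.

    p_report is r/B (r = #{T_b >= T_obs}), reported as the bound 1/B when
    r = 0; ``p_convention='plus_one'`` uses (r+1)/(B+1).
    """
    cfg = cfg or ConsensusConfig()
    if B <= 0:
        raise ValueError(f"B must be positive, got {B}")
    if direction_mode not in ("observed", "random_sign"):
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    if p_convention not in ("bound", "plus_one"):
        raise ValueError(f"unknown p_convention {p_convention!r}")
    ds_ids = list(universes)
    for d in ds_ids:
        if len(de_sets.get(d, {})) > len(universes[d]):
            raise ValueError(f"dataset {d}: more DE features than universe")

    t_obs = observed_consensus_count(de_sets, cfg.k_min, cfg.require_direction)

    # global feature index across all platform universes
    all_features = sorted({f for u in universes.values() for f in u})
    feat_idx = {f: i for i, f in enumerate(all_features)}
    n_global = len(all_features)
    rng = np.random.default_rng(seed)

    sel_counts = np.zeros((B, n_global), dtype=np.int16)
    if cfg.require_direction:
        up_counts = np.zeros((B, n_global), dtype=np.int16)

    for d in ds_ids:
        uni = list(universes[d])
        m = len(de_sets.get(d, {}))
        if m == 0:
            continue
        uni_idx = np.fromiter((feat_idx[f] for f in uni), dtype=np.int64)
        # per replicate: a uniform m-subset of the universe via argpartition
        u = rng.random((B, len(uni)))
        chosen = np.argpartition(u, m - 1, axis=1)[:, :m]  # B × m local indices
        cols = uni_idx[chosen]
        rows = np.repeat(np.arange(B), m)
        np.add.at(sel_counts, (rows, cols.ravel()), 1)
        if cfg.require_direction:
            if direction_mode == "observed":
                dir_map = dict(directions.get(d, {})) if directions else {}
                for f, dd in de_sets.get(d, {}).items():
                    dir_map.setdefault(f, dd)
                codes = np.fromiter(
                    (_DIR_CODE[dir_map.get(f, UP)] for f in uni), dtype=np.int16
                )
                is_up = (codes[chosen] == 1).astype(np.int16)
            else:
                is_up = (rng.random((B, m)) < 0.5).astype(np.int16)
            np.add.at(up_counts, (rows, cols.ravel()), is_up.ravel())

    if cfg.require_direction:
        agree = (up_counts == sel_counts) | (up_counts == 0)
        null_counts = np.sum((sel_counts >= cfg.k_min) & agree, axis=1)
    else:
        null_counts = np.sum(sel_counts >= cfg.k_min, axis=1)
    null_counts = null_counts.astype(np.int64)

    r = int(np.sum(null_counts >= t_obs))
    if p_convention == "plus_one":
        p, bound = (r + 1) / (B + 1), False
    elif r == 0:
        p, bound = 1.0 / B, True
    else:
        p, bound = r / B, False
    return PermutationResult(
        observed=t_obs,
        null_counts=null_counts,
        exceedances=r,
        B=B,
        p_report=p,
        seed=seed,
        is_bound=bound,
    )


def de_sets_from_tables(
    de_tables: Mapping[str, pd.DataFrame], alpha: float = 0.05
) -> tuple[dict[str, dict[str, str]], dict[str, dict[str, str]]]:
    """Split DE tables into (significant feature→direction, all directions)."""
    de_sets, directions = {}, {}
    for ds_id, tbl in de_tables.items():
        sig = tbl[tbl["p_value"] <= alpha]
        de_sets[ds_id] = dict(zip(sig.index, sig["direction"]))
        directions[ds_id] = dict(zip(tbl.index, tbl["direction"]))
    return de_sets, directions
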