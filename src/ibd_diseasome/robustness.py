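"""Community-robustness machinery for Louvain partitions.

Two detected partitions are compared by *matched Dice-Sørensen overlap*:
communities are paired one-to-one by the assignment maximizing total Dice
(optimal bipartite matching, not greedy), the smaller partition padded
with empty communities (scoring 0 against anything non-empty, penalizing
disagreement in community count), and the mean Dice over matched pairs is
reported.

Three experiments probe robustness:

* **edge-shuffle** — repeated Louvain on the full graph with independently
  shuffled edge input orders quantifies the algorithm's greedy order
  sensitivity;
* **split-sample** — repeated random halvings of the patients, with a graph
  built and Louvain run (fixed alphabetical edge order) per half, quantify
  sampling variability;
* **random null** — two independent uniform random assignments of the code
  set to k communities per trial give the chance level of matched overlap.

Overlap can be restricted to codes whose population frequency falls in a
given quartile, to ask whether frequent codes form a more stable community
"core" than rare ones. Experiments report mean overlap and its standard
error over trials; the real-vs-null comparison uses a one-sided Welch
t-test.

All experiments consume one master seed; the rng of trial t is seeded with
``[seed, t]`` (a documented counter scheme), so individual trials are
reproducible in isolation.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import t as t_dist

from .cohort import CohortLabel
from .louvain import Partition, louvain
from .network import CooccurrenceGraph, build_graph
from .records import EncounterRecord

__all__ = [
    "OverlapResult",
    "dice",
    "match_partitions",
    "partition_overlap",
    "quantile_subset",
    "random_null",
    "shuffle_experiment",
    "shuffle_profile",
    "split_profile",
    "split_sample_experiment",
    "welch_one_sided",
    "write_results_csv",
]

logger = logging.getLogger(__name__)

QUANTILE_FILTERS = ("all", "Q0", "Q1", "Q2", "Q3")


@dataclass(frozen=True)
class OverlapResult:
    """Mean matched Dice-Sørensen overlap +/- SEM for one experiment."""

    experiment: str
    mean_overlap: float
    sem: float
    n_trials: int
    quantile_filter: str = "all"
    per_trial_scores: tuple[float, ...] = field(default_factory=tuple)


def _summarize(
    experiment: str, scores: Sequence[float], quantile_filter: str = "all"
) -> OverlapResult:
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{experiment}: no trials produced a score")
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return OverlapResult(
        experiment=experiment,
        mean_overlap=float(arr.mean()),
        sem=sem,
        n_trials=int(arr.size),
        quantile_filter=quantile_filter,
        per_trial_scores=tuple(float(x) for x in arr),
    )


def dice(set_a: Iterable, set_b: Iterable) -> float:
    """Dice-Sørensen coefficient 2|A∩B|/(|A|+|B|); two empty sets score 1."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 1.0
    return 2 * len(a & b) / (len(a) + len(b))


def _community_sets(p: Partition | Sequence[set]) -> list[set]:
    if isinstance(p, Partition):
        return p.communities()
    return [set(c) for c in p]


def match_partitions(
    p: Partition | Sequence[set], r: Partition | Sequence[set]
) -> list[tuple[int | None, int | None, float]]:
    """Optimal one-to-one community pairing maximizing total Dice.

    Returns (community id in P, community id in R, Dice) triples; the
    smaller side is padded with empty communities (id ``None``, Dice 0
    against anything non-empty).
    """
    sets_p, sets_r = _community_sets(p), _community_sets(r)
    kp, kr = len(sets_p), len(sets_r)
    k = max(kp, kr)
    if k == 0:
        return []
    d = np.zeros((k, k))
    for i in range(kp):
        for j in range(kr):
            d[i, j] = dice(sets_p[i], sets_r[j])
    rows, cols = linear_sum_assignment(-d)
    out = []
    for i, j in zip(rows, cols):
        pid = int(i) if i < kp else None
        rid = int(j) if j < kr else None
        score = d[i, j] if (pid is not None and rid is not None) else 0.0
        out.append((pid, rid, float(score)))
    return out


def partition_overlap(
    p: Partition | Sequence[set],
    r: Partition | Sequence[set],
    code_subset: Iterable | None = None,
) -> float:
    """Mean matched Dice over community pairs (padded pairs included).

    With ``code_subset``, every community is intersected with the subset
    first; communities emptied by the restriction are dropped before
    matching. Raises if the restriction empties every community on either
    side.
    """
    sets_p, sets_r = _community_sets(p), _community_sets(r)
    if code_subset is not None:
        subset = set(code_subset)
        sets_p = [c & subset for c in sets_p]
        sets_r = [c & subset for c in sets_r]
        sets_p = [c for c in sets_p if c]
        sets_r = [c for c in sets_r if c]
        if not sets_p or not sets_r:
            raise ValueError("code_subset empties every community on one side")
    pairs = match_partitions(sets_p, sets_r)
    return float(np.mean([score for _, _, score in pairs]))


def quantile_subset(
    code_frequencies: Mapping[str, int], which: str
) -> set[str]:
    """Codes whose frequency falls in the stated quartile.

    Quartile boundaries are linear-interpolation percentiles of the
    frequency values; intervals are half-open below the top quartile:
    Q0 = [min, p25), Q1 = [p25, p50), Q2 = [p50, p75), Q3 = [p75, max].
    """
    if which not in ("Q0", "Q1", "Q2", "Q3"):
        raise ValueError(f"which must be Q0..Q3, got {which!r}")
    if not code_frequencies:
        raise ValueError("empty frequency map")
    values = np.array(list(code_frequencies.values()), dtype=float)
    p25, p50, p75 = np.percentile(values, [25, 50, 75], method="linear")
    lo_hi = {
        "Q0": (values.min(), p25, False),
        "Q1": (p25, p50, False),
        "Q2": (p50, p75, False),
        "Q3": (p75, values.max(), True),
    }
    lo, hi, closed = lo_hi[which]
    return {
        c
        for c, f in code_frequencies.items()
        if f >= lo and (f <= hi if closed else f < hi)
    }


# ---------------------------------------------------------------------------
# experiments


def _score_consecutive(
    partitions: Sequence[Partition], code_subset: Iterable | None
) -> list[float]:
    return [
        partition_overlap(partitions[i], partitions[i + 1], code_subset)
        for i in range(len(partitions) - 1)
    ]


def shuffle_experiment(
    graph: CooccurrenceGraph,
    n_runs: int,
    seed: int,
    code_subset: Iterable | None = None,
    quantile_filter: str = "all",
) -> OverlapResult:
    """Order-sensitivity of Louvain: n_runs with shuffled edge orders,
    matched overlap scored between consecutive runs (n_runs - 1 scores)."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    partitions = [
        louvain(graph, edge_order=_trial_shuffle(graph, seed, t))
        for t in range(n_runs)
    ]
    return _summarize(
        "shuffle", _score_consecutive(partitions, code_subset), quantile_filter
    )


def _trial_shuffle(graph: CooccurrenceGraph, seed: int, trial: int) -> list:
    rng = np.random.default_rng([seed, trial])
    keys = sorted(graph.edges)
    return [keys[i] for i in rng.permutation(len(keys))]


def shuffle_profile(
    graph: CooccurrenceGraph, n_runs: int, seed: int
) -> dict[str, OverlapResult]:
    """Shuffle experiment scored for all quantile filters from one set of
    runs (code frequencies = per-node unique patient counts)."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    partitions = [
        louvain(graph, edge_order=_trial_shuffle(graph, seed, t))
        for t in range(n_runs)
    ]
    freqs = {c: node.n_patients for c, node in graph.nodes.items()}
    out = {}
    for qf in QUANTILE_FILTERS:
        subset = None if qf == "all" else quantile_subset(freqs, qf)
        out[qf] = _summarize("shuffle", _score_consecutive(partitions, subset), qf)
    return out


def _split_partition_pairs(
    records: Sequence[EncounterRecord],
    cohort: Sequence[CohortLabel],
    n_trials: int,
    seed: int,
    cohort_tag: str = "IBD",
    **build_kwargs,
) -> tuple[list[tuple[Partition, Partition]], dict[str, int]]:
    """Disjoint-half experiment core: per trial, random equal halves of the
    case patients, one graph + Louvain (alphabetical edge order) per half."""
    case_labels = {"IBD": ("CD", "UC", "IBDU"), "CD": ("CD",), "UC": ("UC",)}[
        cohort_tag
    ]
    cases = [c for c in cohort if c.label in case_labels]
    if len(cases) < 2:
        raise ValueError("need at least 2 case patients to split")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    by_label = {c.patient_id: c for c in cases}
    pids = sorted(by_label)
    recs_by_pid: dict[str, list[EncounterRecord]] = {}
    for rec in records:
        if rec.patient_id in by_label:
            recs_by_pid.setdefault(rec.patient_id, []).append(rec)

    full_graph = build_graph(records, cohort, cohort_tag, **build_kwargs)
    freqs = {c: node.n_patients for c, node in full_graph.nodes.items()}

    pairs: list[tuple[Partition, Partition]] = []
    for t in range(n_trials):
        rng = np.random.default_rng([seed, t])
        perm = rng.permutation(len(pids))
        half = len(pids) // 2
        halves = (
            [pids[i] for i in perm[:half]],
            [pids[i] for i in perm[half : 2 * half]],
        )
        parts = []
        for side in halves:
            side_recs = [r for p in side for r in recs_by_pid.get(p, [])]
            side_cohort = [by_label[p] for p in side]
            g = build_graph(side_recs, side_cohort, cohort_tag, **build_kwargs)
            if not g.edges:
                parts = None
                break
            parts.append(louvain(g, edge_order=None))  # fixed alphabetical order
        if parts is None:
            logger.warning("split trial %d skipped: edgeless half-graph", t)
            continue
        pairs.append((parts[0], parts[1]))
    return pairs, freqs


def split_sample_experiment(
    records: Sequence[EncounterRecord],
    cohort: Sequence[CohortLabel],
    n_trials: int,
    seed: int,
    cohort_tag: str = "IBD",
    code_subset: Iterable | None = None,
    quantile_filter: str = "all",
    **build_kwargs,
) -> OverlapResult:
    """Patient-sampling sensitivity: matched overlap between partitions of
    two equal, mutually exclusive random halves of the case patients."""
    pairs, _ = _split_partition_pairs(
        records, cohort, n_trials, seed, cohort_tag, **build_kwargs
    )
    scores = [partition_overlap(p, r, code_subset) for p, r in pairs]
    return _summarize("split-sample", scores, quantile_filter)


def split_profile(
    records: Sequence[EncounterRecord],
    cohort: Sequence[CohortLabel],
    n_trials: int,
    seed: int,
    cohort_tag: str = "IBD",
    **build_kwargs,
) -> dict[str, OverlapResult]:
    """Split-sample experiment scored for all quantile filters from one set
    of trials (code frequencies from the full-cohort graph)."""
    pairs, freqs = _split_partition_pairs(
        records, cohort, n_trials, seed, cohort_tag, **build_kwargs
    )
    out = {}
    for qf in QUANTILE_FILTERS:
        subset = None if qf == "all" else quantile_subset(freqs, qf)
        scores = [partition_overlap(p, r, subset) for p, r in pairs]
        out[qf] = _summarize("split-sample", scores, qf)
    return out


def random_null(
    n_codes: int, n_communities: int, n_trials: int, seed: int
) -> OverlapResult:
    """Chance level of matched overlap: per trial, two independent uniform
    random assignments of n_codes codes to n_communities communities."""
    if n_communities < 1:
        raise ValueError("n_communities must be >= 1")
    if n_codes < n_communities:
        raise ValueError("need n_codes >= n_communities")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    codes = np.arange(n_codes)
    scores = []
    for t in range(n_trials):
        rng = np.random.default_rng([seed, t])
        a = rng.integers(0, n_communities, n_codes)
        b = rng.integers(0, n_communities, n_codes)
        sets_a = [set(codes[a == i]) for i in range(n_communities)]
        sets_b = [set(codes[b == i]) for i in range(n_communities)]
        sets_a = [s for s in sets_a if s]
        sets_b = [s for s in sets_b if s]
        scores.append(partition_overlap(sets_a, sets_b))
    return _summarize("random-null", scores)


def welch_one_sided(
    sample_real: Sequence[float], sample_null: Sequence[float]
) -> float:
    """One-sided Welch t-test p-value for H1: mean(real) > mean(null).

    Handles the degenerate zero-variance cases exactly (both samples
    constant: p = 0.5 / 0 / 1 by the sign of the mean difference).
    """
    x = np.asarray(sample_real, dtype=float)
    y = np.asarray(sample_null, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    dm = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        return 0.5 if dm == 0 else (0.0 if dm > 0 else 1.0)
    se = np.sqrt(vx / x.size + vy / y.size)
    t_stat = dm / se
    df = se**4 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return float(t_dist.sf(t_stat, df))


# ---------------------------------------------------------------------------
# result serialization


def write_results_csv(results: Sequence[OverlapResult], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["experiment", "quantile_filter", "mean_overlap", "sem", "n_trials"])
        for r in results:
            writer.writerow(
                [r.experiment, r.quantile_filter, f"{r.mean_overlap:.6f}", f"{r.sem:.6f}", r.n_trials]
            )


def write_results_json(results: Sequence[OverlapResult], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "experiment": r.experiment,
                    "quantile_filter": r.quantile_filter,
                    "mean_overlap": r.mean_overlap,
                    "sem": r.sem,
                    "n_trials": r.n_trials,
                }
                for r in results
            ],
            indent=2,
        )
    )


def plot_overlap_bars(
    profile: Mapping[str, OverlapResult],
    null_result: OverlapResult,
    path: str | Path,
    title: str = "Community overlap by ICD frequency quantile",
) -> None:
    """Bar chart of quantile-restricted overlap with the null as reference."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [q for q in QUANTILE_FILTERS if q in profile]
    means = [profile[q].mean_overlap for q in labels]
    sems = [profile[q].sem for q in labels]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(labels, means, yerr=sems, capsize=3, color="steelblue")
    ax.bar(
        ["random"], [null_result.mean_overlap], yerr=[null_result.sem],
        capsize=3, color="lightgray",
    )
    ax.set_ylabel("mean matched Dice-Sørensen overlap")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
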