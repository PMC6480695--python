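"""Cohort merging, correlation filtering and exhaustive majority-vote search.

The merged transcriptomic cohorts give one binary call per (patient, marker),
each call coming from that marker's cohort-specific Youden cutoff. Markers
correlated above |r| > 0.5 at p < 0.01 are pruned by removing a minimum
vertex cover of the correlation graph (exact search, feasible for panels of
up to ~20 markers; ties between equal-size covers are broken by removing the
markers with the lowest priority, by default the mean individual AUC).

Every subset of >= 2 retained markers is then scored by majority voting —
a patient is predicted responder when at least half the subset's calls vote
responder — giving 2^n - n - 1 combinations, e.g. 131,054 for n = 17.
A dichotomous predictor has a one-point ROC, so its AUC is
(sensitivity + specificity) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateLabelsError,
    IdentifierCollisionError,
    MissingVoteError,
    SchemaError,
    UndefinedCorrelationError,
)

__all__ = [
    "CorrelationReport",
    "CombinationRecord",
    "CombinationEnumeration",
    "FrequencyReport",
    "merge_cohorts",
    "pearson_filter",
    "enumerate_combinations",
    "majority_vote",
    "evaluate_combination",
    "search_combinations",
    "frequency_report",
]


def merge_cohorts(
    tables: Mapping[str, pd.DataFrame],
    labels: Mapping[str, pd.Series],
    cohorts: Sequence[str] | None = None,
    restrict_to_shared: bool = False,
) -> pd.DataFrame:
    """Stack per-cohort patient x marker tables into one labelled frame.

    Values may be binary calls or continuous scores; each cohort brings its
    own rows. The result carries ``label`` and ``cohort`` columns. Marker
    columns must agree across cohorts unless ``restrict_to_shared`` allows
    falling back to the intersection.
    """
    names = list(cohorts) if cohorts is not None else list(tables)
    if not names:
        raise SchemaError("no cohorts to merge")
    shared = set(tables[names[0]].columns)
    union = set(shared)
    for name in names[1:]:
        shared &= set(tables[name].columns)
        union |= set(tables[name].columns)
    if shared != union and not restrict_to_shared:
        raise SchemaError(
            "cohorts disagree on marker columns; pass restrict_to_shared=True "
            f"to use the {len(shared)} shared markers"
        )
    if not shared:
        raise SchemaError("cohorts share no marker columns")
    columns = [c for c in tables[names[0]].columns if c in shared]

    pieces = []
    for name in names:
        piece = tables[name][columns].copy()
        piece["label"] = labels[name].reindex(piece.index)
        piece["cohort"] = name
        pieces.append(piece)
    merged = pd.concat(pieces)
    dup = merged.index[merged.index.duplicated()]
    if len(dup):
        raise IdentifierCollisionError(
            f"patient ids appear in more than one cohort: {sorted(set(dup))}"
        )
    return merged


@dataclass
class CorrelationReport:
    """Pairwise Pearson structure and the minimal exclusion that breaks it."""

    markers: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    edges: list[tuple[str, str]]
    excluded: list[str]
    retained: list[str]
    r_cut: float
    alpha: float


def _min_vertex_cover(
    nodes: Sequence[str], edges: Sequence[tuple[str, str]], priority: Mapping[str, float]
) -> list[str]:
    """Exact minimum vertex cover; ties broken by removing low-priority nodes.

    Among covers of minimal size, the one whose removed nodes have the lowest
    total priority wins; any residual tie falls back to the candidate order,
    which follows the node ordering given by the caller.
    """
    if not edges:
        return []
    involved = [n for n in nodes if any(n in e for e in edges)]
    for size in range(1, len(involved) + 1):
        best: tuple[float, tuple[str, ...]] | None = None
        for cand in combinations(involved, size):
            cover = set(cand)
            if all(a in cover or b in cover for a, b in edges):
                cost = sum(priority.get(n, 0.0) for n in cand)
                if best is None or cost < best[0]:
                    best = (cost, cand)
        if best is not None:
            return list(best[1])
    return list(involved)  # unreachable: all involved nodes always cover


def pearson_filter(
    scores: pd.DataFrame,
    r_cut: float = 0.5,
    alpha: float = 0.01,
    priority: Mapping[str, float] | None = None,
) -> CorrelationReport:
    """Prune the marker set so no retained pair is strongly correlated.

    Correlations are Pearson coefficients over pairwise-complete continuous
    scores; a pair is an edge when |r| > ``r_cut`` *and* its two-sided
    p-value < ``alpha``. The excluded set is a minimum vertex cover of the
    edge graph.
    """
    markers = list(scores.columns)
    if len(markers) < 2:
        raise SchemaError("need at least 2 markers to correlate")
    r = pd.DataFrame(np.eye(len(markers)), index=markers, columns=markers)
    p = pd.DataFrame(np.zeros((len(markers), len(markers))), index=markers, columns=markers)
    edges: list[tuple[str, str]] = []
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            pair = scores[[a, b]].dropna()
            if len(pair) < 3:
                raise UndefinedCorrelationError(
                    f"fewer than 3 complete observations for ({a}, {b})"
                )
            for col in (a, b):
                if pair[col].nunique() < 2:
                    raise UndefinedCorrelationError(f"marker {col!r} is constant")
            res = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
            if abs(res.statistic) > r_cut and res.pvalue < alpha:
                edges.append((a, b))
    prio = dict(priority) if priority is not None else {m: 0.0 for m in markers}
    excluded = _min_vertex_cover(markers, edges, prio)
    retained = [m for m in markers if m not in excluded]
    return CorrelationReport(
        markers=markers, r=r, p=p, edges=edges,
        excluded=excluded, retained=retained, r_cut=r_cut, alpha=alpha,
    )


@dataclass
class CombinationEnumeration:
    """Count and deterministic iterator over marker subsets of size >= 2."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2 markers, got {self.n}")

    @property
    def count(self) -> int:
        # sum_{j=2}^{n} C(n, j) telescopes to 2^n - n - 1
        return 2**self.n - self.n - 1

    def subsets(self) -> Iterator[tuple[int, ...]]:
        """Index subsets in lexicographic order within increasing size."""
        for size in range(2, self.n + 1):
            yield from combinations(range(self.n), size)


def enumerate_combinations(n: int) -> CombinationEnumeration:
    """All marker subsets of size 2..n; their count is 2^n - n - 1."""
    return CombinationEnumeration(n)


def majority_vote(calls: np.ndarray | pd.DataFrame, tie_to_responder: bool = True) -> np.ndarray:
    """Consensus prediction: responder when at least half the calls agree.

    ``calls`` is patients x subset with 1 = responder vote. With
    ``tie_to_responder`` (the default, reading "at least half" literally),
    an exact tie predicts responder; the flag flips ties the other way.
    """
    arr = calls.to_numpy() if isinstance(calls, pd.DataFrame) else np.asarray(calls)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("calls must be patients x subset with subset size >= 2")
    if np.isnan(arr.astype(float)).any():
        raise MissingVoteError("missing marker call in subset")
    votes = arr.sum(axis=1)
    half = arr.shape[1] / 2.0
    return (votes >= half).astype(int) if tie_to_responder else (votes > half).astype(int)


@dataclass
class CombinationRecord:
    """Majority-vote performance of one marker subset on the merged cohort."""

    subset: tuple[str, ...]
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    auc: float  # one-point ROC: (sensitivity + specificity) / 2

    @property
    def size(self) -> int:
        return len(self.subset)


def _confusion(pred: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((pred == 1) & y).sum())
    fp = int(((pred == 1) & ~y).sum())
    tn = int(((pred == 0) & ~y).sum())
    fn = int(((pred == 0) & y).sum())
    return tp, fp, tn, fn


def evaluate_combination(
    subset: Sequence[str],
    calls: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    tie_to_responder: bool = True,
) -> CombinationRecord:
    """Confusion matrix, sensitivity, specificity and AUC for one subset."""
    from .performance import _as_bool_labels

    y = _as_bool_labels(labels)
    if y.all() or not y.any():
        raise DegenerateLabelsError("both classes required to evaluate a combination")
    pred = majority_vote(calls[list(subset)], tie_to_responder=tie_to_responder)
    tp, fp, tn, fn = _confusion(pred, y)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return CombinationRecord(
        subset=tuple(subset), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, auc=(sens + spec) / 2.0,
    )


def search_combinations(
    calls: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    tie_to_responder: bool = True,
) -> pd.DataFrame:
    """Exhaustively score every subset of >= 2 markers by majority voting.

    Vectorized over all subsets of each size (the 17-marker search is
    131,054 evaluations). Rows are sorted by AUC descending, then subset
    size ascending, then lexicographic subset index for stable output.
    Returns columns subset (tuple of names), size, tp, fp, tn, fn,
    sensitivity, specificity, auc.
    """
    from .performance import _as_bool_labels

    y = _as_bool_labels(labels)
    if y.all() or not y.any():
        raise DegenerateLabelsError("both classes required for the combination search")
    if calls.isna().any().any():
        raise MissingVoteError("calls table contains missing votes")
    markers = list(calls.columns)
    n = len(markers)
    mat = calls.to_numpy(dtype=np.int8)
    pos, neg = y, ~y
    n_pos, n_neg = int(pos.sum()), int(neg.sum())

    frames = []
    for size in range(2, n + 1):
        combos = np.array(list(combinations(range(n), size)), dtype=int)
        member = np.zeros((n, len(combos)), dtype=np.int16)
        for k in range(size):
            member[combos[:, k], np.arange(len(combos))] = 1
        votes = mat @ member  # patients x subsets
        if tie_to_responder:
            pred = votes * 2 >= size
        else:
            pred = votes * 2 > size
        tp = pred[pos].sum(axis=0)
        fp = pred[neg].sum(axis=0)
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos
        spec = tn / n_neg
        frames.append(
            pd.DataFrame(
                {
                    "subset": [tuple(markers[i] for i in row) for row in combos],
                    "size": size,
                    "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                    "sensitivity": sens, "specificity": spec,
                    "auc": (sens + spec) / 2.0,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(
        ["auc", "size"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out


@dataclass
class FrequencyReport:
    """How often each marker appears among the acceptable combinations."""

    auc_floor: float
    n_records: int
    n_acceptable: int
    acceptable_fraction: float
    frequency: dict[str, float] = field(default_factory=dict)


def frequency_report(
    records: pd.DataFrame | Iterable[CombinationRecord], auc_floor: float = 0.65
) -> FrequencyReport:
    """Fraction of combinations at AUC >= floor and per-marker containment."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        recs = list(records)
        frame = pd.DataFrame({"subset": [r.subset for r in recs], "auc": [r.auc for r in recs]})
    if len(frame) == 0:
        raise SchemaError("no combination records given")
    good = frame.loc[frame["auc"] >= auc_floor, "subset"]
    if len(good) == 0:
        warnings.warn(f"no combination reaches AUC >= {auc_floor}", stacklevel=2)
        return FrequencyReport(auc_floor, len(frame), 0, 0.0, {})
    counts: dict[str, int] = {}
    for subset in good:
        for name in subset:
            counts[name] = counts.get(name, 0) + 1
    freq = {name: counts[name] / len(good) for name in sorted(counts, key=counts.get, reverse=True)}
    return FrequencyReport(
        auc_floor=auc_floor,
        n_records=len(frame),
        n_acceptable=len(good),
        acceptable_fraction=len(good) / len(frame),
        frequency=freq,
    )
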