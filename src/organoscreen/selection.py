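"""Accumulative phenotypic feature selection.

For every (treatment, dose) group a pairwise comparison against the buffer
controls is run: repeated class-wise bootstrap sampling (30 rows per class,
with replacement) feeds a random-forest classifier whose impurity-based
importances rank the features; the top k (default 10) per repetition are
recorded.  Membership counts are accumulated over all (pair × repetition)
draws into a per-feature selection frequency, and the features at or above
a frequency cutoff (default 5 %) form the selected set.

The cutoff acts as a recurrence filter: a feature that dominates a single
pair's comparisons reaches a frequency of only ~1/n_pairs, so with a panel
of many (treatment, dose) pairs the selected set keeps the features that
discriminate treatments from buffer consistently across the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "RandomForestConfig",
    "PairwiseComparison",
    "SelectionResult",
    "rf_top_k",
    "accumulate_frequencies",
    "select_features",
    "run_accumulative_selection",
]


@dataclass(frozen=True)
class RandomForestConfig:
    """Pinned forest settings (reproducibility requires fixing them)."""

    n_estimators: int = 25
    max_features: str | float = 0.05
    max_depth: int | None = None


@dataclass
class PairwiseComparison:
    """Per-repetition top-k feature sets for one (treatment, dose) pair."""

    treatment: str
    dose: float
    top_k_sets: list[list[str]]
    k: int

    def __post_init__(self) -> None:
        for s in self.top_k_sets:
            if len(set(s)) != self.k:
                raise ValueError("each top-k set must contain exactly k distinct features")


@dataclass
class SelectionResult:
    """Accumulated selection frequencies and the cutoff-passing feature set."""

    frequency: pd.Series  # feature -> proportion of draws containing it
    cutoff: float
    selected: list[str] = field(init=False)
    n_repetitions: int = 0
    n_bootstrap: int = 0
    k: int = 10
    n_pairs: int = 0

    def __post_init__(self) -> None:
        passing = self.frequency[self.frequency >= self.cutoff]
        self.selected = list(passing.sort_values(ascending=False).index)


def rf_top_k(
    treatment_rows: pd.DataFrame,
    buffer_rows: pd.DataFrame,
    k: int = 10,
    n_bootstrap: int = 30,
    n_repetitions: int = 500,
    seed: int = 0,
    forest: RandomForestConfig | None = None,
) -> list[list[str]]:
    """Per-repetition top-k features separating treatment from buffer.

    Each repetition draws ``n_bootstrap`` rows per class with replacement
    (class-wise bootstrap), fits a random forest on the two-class problem,
    ranks features by impurity-based importance and records the top k.
    Importance ties are broken by the table's column order.  Fully seeded.
    """
    forest = forest or RandomForestConfig()
    if len(treatment_rows) == 0 or len(buffer_rows) == 0:
        raise ValueError("both classes need at least one row for a pairwise comparison")
    columns = list(treatment_rows.columns)
    if list(buffer_rows.columns) != columns:
        raise ValueError("treatment and buffer tables must share columns")
    tx = np.asarray(treatment_rows, dtype=float)
    bx = np.asarray(buffer_rows, dtype=float)
    if np.isnan(tx).any() or np.isnan(bx).any():
        raise ValueError("selection requires complete (non-missing) feature values")
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n_bootstrap), np.zeros(n_bootstrap)])
    out: list[list[str]] = []
    col_arr = np.array(columns)
    for _ in range(n_repetitions):
        ti = rng.integers(0, len(tx), size=n_bootstrap)
        bi = rng.integers(0, len(bx), size=n_bootstrap)
        x = np.vstack([tx[ti], bx[bi]])
        clf = RandomForestClassifier(
            n_estimators=forest.n_estimators,
            max_features=forest.max_features,
            max_depth=forest.max_depth,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        clf.fit(x, y)
        imp = clf.feature_importances_
        # stable sort on descending importance => ties broken by column order
        order = np.argsort(-imp, kind="stable")[:k]
        out.append(col_arr[order].tolist())
    return out


def accumulate_frequencies(
    comparisons: Sequence[PairwiseComparison],
    feature_names: Sequence[str],
    cutoff: float = 0.05,
) -> SelectionResult:
    """Accumulate top-k membership over all (pair × repetition) draws.

    frequency(f) = #draws whose top-k contains f / total draws; the sum of
    frequencies over features equals k exactly.
    """
    if not comparisons:
        raise ValueError("need at least one pairwise comparison")
    k = comparisons[0].k
    counts: dict[str, int] = {}
    total = 0
    for comp in comparisons:
        if comp.k != k:
            raise ValueError("all comparisons must use the same k")
        for top in comp.top_k_sets:
            total += 1
            for f in top:
                counts[f] = counts.get(f, 0) + 1
    freq = pd.Series(0.0, index=list(feature_names))
    for f, c in counts.items():
        freq[f] = c / total
    return SelectionResult(
        frequency=freq,
        cutoff=cutoff,
        n_repetitions=len(comparisons[0].top_k_sets),
        k=k,
        n_pairs=len(comparisons),
    )


def select_features(result: SelectionResult, cutoff: float | None = None) -> list[str]:
    """Features whose selection frequency reaches the cutoff, in descending
    frequency order."""
    cutoff = result.cutoff if cutoff is None else cutoff
    passing = result.frequency[result.frequency >= cutoff]
    if cutoff == 0:
        passing = result.frequency[result.frequency > 0]
    return list(passing.sort_values(ascending=False).index)


def run_accumulative_selection(
    normalized: pd.DataFrame,
    plate_map: pd.DataFrame,
    k: int = 10,
    n_bootstrap: int = 30,
    n_repetitions: int = 500,
    cutoff: float = 0.05,
    seed: int = 0,
    forest: RandomForestConfig | None = None,
) -> tuple[SelectionResult, list[PairwiseComparison]]:
    """Run the full accumulative selection over every (treatment, dose) pair.

    ``normalized`` is the buffer-z-scored wells × features table; the plate
    map supplies roles and groups.  Pairs are processed in sorted
    (treatment, dose) order with per-pair child seeds, so the result is a
    pure function of (data, seed).
    """
    pm = plate_map.set_index("well")
    buffer_wells = [w for w in pm.index[pm["role"] == "buffer"] if w in normalized.index]
    if not buffer_wells:
        raise ValueError("plate has no buffer wells")
    buffer_rows = normalized.loc[buffer_wells]
    treat = pm[pm["role"] == "treatment"]
    pairs = sorted({(str(t), float(d)) for t, d in zip(treat["treatment"], treat["dose"])})
    seeds = np.random.SeedSequence(seed).spawn(len(pairs))
    comparisons: list[PairwiseComparison] = []
    for (treatment, dose), ss in zip(pairs, seeds):
        wells = treat.index[(treat["treatment"] == treatment) & (treat["dose"] == dose)]
        wells = [w for w in wells if w in normalized.index]
        if not wells:
            raise ValueError(f"pair ({treatment}, {dose}) has no feature rows")
        tops = rf_top_k(
            normalized.loc[wells], buffer_rows,
            k=k, n_bootstrap=n_bootstrap, n_repetitions=n_repetitions,
            seed=int(ss.generate_state(1)[0] % (2**31 - 1)), forest=forest,
        )
        comparisons.append(PairwiseComparison(treatment, dose, tops, k))
    result = accumulate_frequencies(comparisons, normalized.columns, cutoff)
    result.n_bootstrap = n_bootstrap
    return result, comparisons
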