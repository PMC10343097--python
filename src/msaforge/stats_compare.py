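"""Statistical comparison of alignment strategies.

Per benchmark group, each strategy yields one Developer-Score sample
over the group's problem instances.  A Shapiro–Wilk screen motivates the
non-parametric choice; paired one-sided Wilcoxon signed-rank tests then
compare the four heuristic classes (P, C, I, CI) of each variation under
six alternative hypotheses (C>P, I>P, C>I, CI>P, CI>I, CI>C), producing
a 20-variation × 6-hypothesis p-value table.  A complementary view
counts, per class, how often it attains the best score over all
strategies — alone (unique best) or jointly (tied best).

The Wilcoxon implementation computes the exact conditional distribution
of the positive-rank sum by convolution whenever the effective sample
size is at most 25 (exact even under tied ranks, which rules out the
common library shortcut), and falls back to the normal approximation
with tie and continuity corrections above that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CLASSES = ("P", "C", "I", "CI")
HYPOTHESES = ("C>P", "I>P", "C>I", "CI>P", "CI>I", "CI>C")

EXACT_CUTOFF = 25


@dataclass
class SampleSet:
    """One strategy's score vector over a benchmark group's instances."""

    benchmark: str
    band: str
    strategy: str
    instances: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.instances):
            raise ValueError("values/instances length mismatch")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("scores must lie in [0, 1]")


def shapiro_normality(values) -> float:
    """Shapiro–Wilk p-value; errors on constant or tiny samples."""
    x = np.asarray(values, dtype=float)
    if not (3 <= len(x) <= 5000):
        raise ValueError("Shapiro-Wilk needs 3..5000 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no defined normality p-value")
    return float(sps.shapiro(x).pvalue)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """P(W+ ≥ w_plus) over the 2^n equiprobable sign assignments.

    Works on doubled ranks so tied (half-integer) average ranks stay on
    an integer lattice; the distribution is built by convolution.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    threshold = int(np.rint(2 * w_plus))
    p = counts[threshold:].sum() / counts.sum()
    return float(min(p, 1.0))


def wilcoxon_one_sided(
    a,
    b,
    zero_method: str = "wilcox",
    method: str = "auto",
) -> float:
    """One-sided paired Wilcoxon signed-rank p-value for "a > b".

    Zero differences are dropped ("wilcox", the default) or kept for
    ranking then removed from the statistic ("pratt").  All-zero
    differences return p = 1 by convention.  ``method`` is "auto"
    (exact up to effective n = 25, else normal approximation), "exact",
    or "approx".
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    d = a - b
    if zero_method == "wilcox":
        d = d[d != 0]
        if len(d) == 0:
            return 1.0
        ranks = sps.rankdata(np.abs(d))
        keep = np.ones(len(d), dtype=bool)
    elif zero_method == "pratt":
        if np.all(d == 0):
            return 1.0
        ranks = sps.rankdata(np.abs(d))
        keep = d != 0
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")

    w_plus = float(ranks[(d > 0) & keep].sum())
    n_eff = int(keep.sum())
    use_exact = method == "exact" or (
        method == "auto" and zero_method == "wilcox" and n_eff <= EXACT_CUTOFF
    )
    if use_exact:
        return _exact_signed_rank_p(ranks[keep], w_plus)

    # normal approximation with tie and continuity corrections
    used = ranks[keep]
    n = n_eff
    mean = used.sum() / 2.0
    var = np.square(used).sum() / 4.0
    if zero_method == "pratt":
        # zeros already excluded from ``used``; mean/var above are the
        # Pratt-adjusted moments since rank magnitudes include zeros
        pass
    if var == 0:
        return 1.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(sps.norm.sf(z))


def _pivot(store: pd.DataFrame, benchmark: str, band: str) -> pd.DataFrame:
    sub = store[(store["benchmark"] == benchmark) & (store["band"] == band)]
    if sub.empty:
        raise ValueError(f"no scores for benchmark {benchmark!r} band {band!r}")
    return sub


def build_comparison_table(
    store: pd.DataFrame,
    benchmark: str,
    band: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """20-variation × 6-hypothesis one-sided Wilcoxon p-value table.

    ``store`` holds one row per (instance, strategy) with columns
    ``benchmark, band, instance, variation, cls, ds``.  The returned
    frame carries the p-values plus boolean ``<hyp> sig`` columns
    marking p < alpha.
    """
    sub = _pivot(store, benchmark, band)
    variations = sorted(sub["variation"].unique())
    missing: list[str] = []
    table: dict[str, list[float]] = {h: [] for h in HYPOTHESES}
    for var in variations:
        block = sub[sub["variation"] == var]
        series: dict[str, pd.Series] = {}
        for cls in CLASSES:
            rows = block[block["cls"] == cls].set_index("instance")["ds"]
            if rows.empty:
                missing.append(f"{var}+{cls}")
                continue
            series[cls] = rows.sort_index()
        if missing:
            continue
        idx = series["P"].index
        for cls in CLASSES:
            if not series[cls].index.equals(idx):
                raise ValueError(f"instance sets differ within variation {var}")
        for hyp in HYPOTHESES:
            hi, lo = hyp.split(">")
            table[hyp].append(
                wilcoxon_one_sided(series[hi].values, series[lo].values)
            )
    if missing:
        raise ValueError(f"missing strategy results: {', '.join(missing)}")
    out = pd.DataFrame(table, index=pd.Index(variations, name="variation"))
    for hyp in HYPOTHESES:
        out[f"{hyp} sig"] = out[hyp] < alpha
    return out


def best_class_frequencies(
    store: pd.DataFrame, benchmark: str, band: str
) -> pd.DataFrame:
    """Per-class tied-best and unique-best percentages over band instances.

    For each instance the best score over all strategies is found; a
    class is *tied best* when any of its variants attains it and
    *unique best* when no other class does.
    """
    sub = _pivot(store, benchmark, band)
    instances = sorted(sub["instance"].unique())
    tied = {c: 0 for c in CLASSES}
    unique = {c: 0 for c in CLASSES}
    for inst in instances:
        block = sub[sub["instance"] == inst]
        best = block["ds"].max()
        winners = set(block.loc[block["ds"] == best, "cls"])
        for c in winners:
            tied[c] += 1
            if len(winners) == 1:
                unique[c] += 1
    n = len(instances)
    return pd.DataFrame(
        {
            "tied_best_pct": [100.0 * tied[c] / n for c in CLASSES],
            "unique_best_pct": [100.0 * unique[c] / n for c in CLASSES],
        },
        index=pd.Index(CLASSES, name="cls"),
    )
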