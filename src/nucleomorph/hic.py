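"""Condition-level summaries of chromatin loop calls and Hi-C read classes.

Consumes loop calls (BEDPE) and read-pair tallies produced by an upstream
Hi-C pipeline; it does not align reads or call loops.  The quantities of
interest when chromatin compaction is perturbed (e.g. condensin loss):

* loops unique to one condition versus another, counted per chromosome;
* the size (genomic span) distribution of those unique loops — loss of
  condensin-mediated sublooping shifts mass from ~<=90 kb subloops to
  larger undivided loops;
* the split of read pairs into short-range cis (< 20 kb), long-range cis
  (> 20 kb) and interchromosomal (trans) classes.

Loop span is the distance between anchor midpoints (``midpoint2 -
midpoint1``); the outer span (``end2 - start1``) is available as an
alternative.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LoopCall",
    "PairClassCounts",
    "parse_loops",
    "loops_to_frame",
    "unique_loops",
    "match_loops",
    "loop_size_stats",
    "classify_pairs",
    "compare_conditions",
    "mann_whitney_exact",
]

CIS_SHORT_MAX_BP = 20_000  # short-range cis: distance < 20 kb


@dataclass(frozen=True)
class LoopCall:
    """One chromatin loop: a pair of genomic anchor intervals."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int

    def __post_init__(self) -> None:
        if not (self.start1 < self.end1 and self.start2 < self.end2):
            raise ValueError(
                f"anchor start must precede end: {self.chrom1}:{self.start1}-{self.end1} "
                f"/ {self.chrom2}:{self.start2}-{self.end2}"
            )
        if min(self.start1, self.start2) < 0:
            raise ValueError("negative genomic coordinates")
        if self.intra and self.midpoint1 > self.midpoint2:
            # normalize anchor order so midpoint1 <= midpoint2
            s1, e1 = self.start1, self.end1
            object.__setattr__(self, "start1", self.start2)
            object.__setattr__(self, "end1", self.end2)
            object.__setattr__(self, "start2", s1)
            object.__setattr__(self, "end2", e1)

    @property
    def intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def midpoint1(self) -> float:
        return 0.5 * (self.start1 + self.end1)

    @property
    def midpoint2(self) -> float:
        return 0.5 * (self.start2 + self.end2)

    @property
    def span(self) -> float | None:
        """Midpoint distance for intra-chromosomal loops; None for trans."""
        if not self.intra:
            return None
        return abs(self.midpoint2 - self.midpoint1)

    @property
    def outer_span(self) -> float | None:
        if not self.intra:
            return None
        return float(max(self.end1, self.end2) - min(self.start1, self.start2))


@dataclass(frozen=True)
class PairClassCounts:
    n_cis_short: int
    n_cis_long: int
    n_trans: int

    @property
    def total(self) -> int:
        return self.n_cis_short + self.n_cis_long + self.n_trans

    @property
    def percentages(self) -> tuple[float, float, float]:
        if self.total == 0:
            raise ValueError("no read pairs to classify")
        t = self.total
        return (
            100.0 * self.n_cis_short / t,
            100.0 * self.n_cis_long / t,
            100.0 * self.n_trans / t,
        )


def _fix_anchor_order(df: pd.DataFrame) -> pd.DataFrame:
    mid1 = (df["start1"] + df["end1"]) / 2.0
    mid2 = (df["start2"] + df["end2"]) / 2.0
    swap = (df["chrom1"] == df["chrom2"]) & (mid1 > mid2)
    if swap.any():
        df = df.copy()
        for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
            df.loc[swap, [a, b]] = df.loc[swap, [b, a]].to_numpy()
    return df


def parse_loops(path) -> pd.DataFrame:
    """Read a BEDPE-like loop file into a validated DataFrame.

    At least six tab-separated columns; lines starting with ``#`` and a
    header row of column names are tolerated.  Extra columns are dropped.
    Inter-chromosomal entries are retained but carry ``span = NaN`` and
    are excluded from size statistics.  Malformed rows raise with their
    line number.
    """
    rows = []
    seen_data = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 6 tab-separated columns, got {len(parts)}"
                )
            if not seen_data and not parts[1].lstrip("-").isdigit():
                continue  # header row of column names
            seen_data = True
            try:
                start1, end1 = int(parts[1]), int(parts[2])
                start2, end2 = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 <= start1 or end2 <= start2:
                raise ValueError(f"{path}:{lineno}: anchor end <= start")
            if start1 < 0 or start2 < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate")
            rows.append(
                {
                    "chrom1": parts[0],
                    "start1": start1,
                    "end1": end1,
                    "chrom2": parts[3],
                    "start2": start2,
                    "end2": end2,
                }
            )
    if not rows:
        warnings.warn(f"no loops parsed from {path}", stacklevel=2)
        return pd.DataFrame(
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2", "span"]
        )
    df = _fix_anchor_order(pd.DataFrame(rows))
    return _with_span(df)


def _with_span(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    intra = df["chrom1"] == df["chrom2"]
    mid1 = (df["start1"] + df["end1"]) / 2.0
    mid2 = (df["start2"] + df["end2"]) / 2.0
    df["span"] = np.where(intra, np.abs(mid2 - mid1), np.nan)
    return df


def loops_to_frame(loops) -> pd.DataFrame:
    """Accept a DataFrame or a list of LoopCall; return a span-annotated frame."""
    if isinstance(loops, pd.DataFrame):
        df = loops.copy()
        if "span" not in df.columns:
            df = _with_span(_fix_anchor_order(df))
        return df
    return _with_span(
        _fix_anchor_order(
            pd.DataFrame(
                [
                    {
                        "chrom1": l.chrom1,
                        "start1": l.start1,
                        "end1": l.end1,
                        "chrom2": l.chrom2,
                        "start2": l.start2,
                        "end2": l.end2,
                    }
                    for l in loops
                ]
            )
        )
    )


def match_loops(a, b, anchor_tol_bp: float = 0.0) -> list[tuple[int, int]]:
    """One-to-one matching of loops between two call sets.

    Loop ``a`` matches loop ``b`` iff they share the chromosome pair and
    both anchor midpoints agree within ``anchor_tol_bp``.  Matching is
    greedy nearest-midpoint with ties broken by genomic order, each loop
    matched at most once; the pairing is symmetric in A and B.
    Returns (index_in_a, index_in_b) pairs.
    """
    da, db = loops_to_frame(a), loops_to_frame(b)
    if len(da) == 0 or len(db) == 0:
        return []

    def mids(df):
        return (
            ((df["start1"] + df["end1"]) / 2.0).to_numpy(),
            ((df["start2"] + df["end2"]) / 2.0).to_numpy(),
        )

    m1a, m2a = mids(da)
    m1b, m2b = mids(db)
    key_a = list(zip(da["chrom1"], da["chrom2"]))
    key_b = list(zip(db["chrom1"], db["chrom2"]))

    candidates = []
    for i in range(len(da)):
        for j in range(len(db)):
            if key_a[i] != key_b[j]:
                continue
            d1 = abs(m1a[i] - m1b[j])
            d2 = abs(m2a[i] - m2b[j])
            if d1 <= anchor_tol_bp and d2 <= anchor_tol_bp:
                candidates.append((d1 + d2, m1a[i], m2a[i], i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def unique_loops(a, b, anchor_tol_bp: float = 0.0) -> pd.DataFrame:
    """Loops of A with no match in B (at the given anchor tolerance)."""
    da = loops_to_frame(a)
    matched = {i for i, _ in match_loops(da, b, anchor_tol_bp)}
    return da.loc[[i for i in range(len(da)) if i not in matched]].reset_index(
        drop=True
    )


def loop_size_stats(loops, span_definition: str = "midpoint") -> dict:
    """n, mean/median span (bp) and per-chromosome counts for intra loops.

    An empty set reports ``n = 0`` with the span statistics missing
    (None), never zero.
    """
    df = loops_to_frame(loops)
    intra = df[df["chrom1"] == df["chrom2"]].copy()
    if span_definition == "midpoint":
        spans = intra["span"]
    elif span_definition == "outer":
        spans = intra[["end1", "end2"]].max(axis=1) - intra[["start1", "start2"]].min(
            axis=1
        )
    else:
        raise ValueError(f"unknown span definition {span_definition!r}")
    n = len(intra)
    return {
        "n": n,
        "mean_span": float(spans.mean()) if n else None,
        "median_span": float(spans.median()) if n else None,
        "per_chromosome": intra["chrom1"].value_counts().to_dict(),
    }


def classify_pairs(
    records: pd.DataFrame | None = None,
    counts: tuple[int, int, int] | None = None,
    cis_short_max_bp: int = CIS_SHORT_MAX_BP,
) -> PairClassCounts:
    """Split read pairs into cis-short, cis-long and trans classes.

    Either per-pair records (chrom1, pos1, chrom2, pos2) or pre-tallied
    (cis_short, cis_long, trans) counts.  Cis pairs with distance below
    ``cis_short_max_bp`` (20 kb) are short-range; equal-or-greater are
    long-range; different chromosomes are trans.
    """
    if (records is None) == (counts is None):
        raise ValueError("provide exactly one of records or counts")
    if counts is not None:
        return PairClassCounts(*map(int, counts))
    req = {"chrom1", "pos1", "chrom2", "pos2"}
    if not req.issubset(records.columns):
        raise ValueError(f"pair records need columns {sorted(req)}")
    if (records[["pos1", "pos2"]] < 0).any().any():
        raise ValueError("negative positions in pair records")
    cis = records["chrom1"] == records["chrom2"]
    dist = (records["pos2"] - records["pos1"]).abs()
    short = cis & (dist < cis_short_max_bp)
    return PairClassCounts(
        n_cis_short=int(short.sum()),
        n_cis_long=int((cis & ~short).sum()),
        n_trans=int((~cis).sum()),
    )


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U by enumeration of all splits.

    Brute-force null distribution over C(n+m, n) group assignments of the
    pooled sample; intended for small samples (n+m <= ~20) and as an
    oracle for the large-sample approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)
    idx = range(n + m)
    count_extreme = 0
    mu = n * m / 2.0
    for combo in combinations(idx, n):
        u = float(ranks[list(combo)].sum() - n * (n + 1) / 2)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count_extreme += 1
    return u_obs, count_extreme / comb(n + m, n)


def compare_conditions(
    loops_a,
    loops_b,
    anchor_tol_bp: float = 0.0,
    label_a: str = "A",
    label_b: str = "B",
    exact_max_n: int = 20,
) -> dict:
    """Head-to-head report for two loop-call sets.

    Computes the unique-loop sets (both directions), their size
    statistics, the fold change in unique-loop count (A over B), and a
    two-sided Mann-Whitney U on the two unique-span samples — exact
    enumeration when both samples are small, normal approximation with
    tie correction otherwise.  Empty unique sets report missing (None)
    fold change and test results.
    """
    ua = unique_loops(loops_a, loops_b, anchor_tol_bp)
    ub = unique_loops(loops_b, loops_a, anchor_tol_bp)
    sa = loop_size_stats(ua)
    sb = loop_size_stats(ub)
    spans_a = ua.loc[ua["chrom1"] == ua["chrom2"], "span"].to_numpy()
    spans_b = ub.loc[ub["chrom1"] == ub["chrom2"], "span"].to_numpy()

    fold = (len(ua) / len(ub)) if len(ua) and len(ub) else None
    mean_shift = (
        (sb["mean_span"] - sa["mean_span"])
        if sa["mean_span"] is not None and sb["mean_span"] is not None
        else None
    )
    if len(spans_a) >= 1 and len(spans_b) >= 1:
        if len(spans_a) + len(spans_b) <= exact_max_n:
            u, p = mann_whitney_exact(spans_a, spans_b)
        else:
            res = stats.mannwhitneyu(
                spans_a, spans_b, alternative="two-sided", method="asymptotic"
            )
            u, p = float(res.statistic), float(res.pvalue)
    else:
        u, p = None, None
    return {
        "label_a": label_a,
        "label_b": label_b,
        "anchor_tol_bp": anchor_tol_bp,
        "n_unique_a": len(ua),
        "n_unique_b": len(ub),
        "fold_change_unique": fold,
        "stats_a": sa,
        "stats_b": sb,
        "mean_span_shift": mean_shift,
        "mannwhitney_u": u,
        "mannwhitney_p": p,
        "unique_a": ua,
        "unique_b": ub,
    }
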