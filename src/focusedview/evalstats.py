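"""Statistical evaluation: Dice overlap, ordinal visibility-score
summaries, paired Wilcoxon, Mann-Whitney, Yates-corrected chi-square, and
Cohen's weighted kappa.

These are the statistics used to evaluate the focused-view pipeline:
per-class Dice between predicted and reference segmentations, and the
reader-study machinery — per-structure median (IQR, range) summaries of
1-5 visibility scores, paired comparison of focused vs unmodified
reading conditions (Wilcoxon signed rank), group comparisons of patient
characteristics (Mann-Whitney, Yates chi-square), and inter-reader
agreement (weighted kappa).

Implementation notes: the Wilcoxon signed-rank test drops zero
differences (a Pratt variant is available), uses midranks of the
absolute differences, and computes the exact two-sided p by dynamic
programming over the 2^n sign assignments when n <= 25 (ties allowed —
doubled midranks are integers), otherwise a tie-corrected normal
approximation.  The chi-square statistic is the closed form
``N (|ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d))`` with the continuity
term floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import LabelMap, ValidationError

EXACT_N_MAX = 25  # exact enumeration threshold for the signed-rank test


# --------------------------------------------------------------------------
# Dice
# --------------------------------------------------------------------------
def dice_coefficient(
    pred: Union[LabelMap, np.ndarray],
    truth: Union[LabelMap, np.ndarray],
    class_id: int,
) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)`` for one foreground class.

    Defined as 1.0 when the class is absent from both maps.
    """
    if class_id not in (1, 2):
        raise ValidationError(f"class_id must be 1 or 2, got {class_id}")
    a = pred.labels if isinstance(pred, LabelMap) else np.asarray(pred)
    b = truth.labels if isinstance(truth, LabelMap) else np.asarray(truth)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    am = a == class_id
    bm = b == class_id
    denom = int(am.sum()) + int(bm.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / denom


# --------------------------------------------------------------------------
# Wilcoxon signed rank
# --------------------------------------------------------------------------
def _signed_rank_exact_sf_cdf(ranks2: np.ndarray, w2: int):
    """Exact null distribution of 2*W+ over sign assignments, via the
    generating polynomial prod_i (1 + x^{r_i}) / 2^n."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    cdf = float(dist[: w2 + 1].sum())
    sf = float(dist[w2:].sum())
    return cdf, sf


def wilcoxon_signed_rank(
    a: Sequence[float],
    b: Sequence[float],
    zero_method: str = "drop",
    method: str = "auto",
) -> Tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Returns ``(W+, p)`` where ``W+`` is the positive-rank sum.  Zero
    differences are dropped by default (``zero_method='pratt'`` ranks
    them and removes their rank contribution instead).  ``method`` is
    ``'exact'`` (sign-assignment enumeration, ties allowed),
    ``'approx'`` (tie-corrected normal approximation) or ``'auto'``
    (exact for n <= 25).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError("need two equal-length 1-D samples with n >= 1")
    d = a - b
    if zero_method == "drop":
        d = d[d != 0]
        if d.size == 0:
            warnings.warn("all paired differences are zero; p = 1")
            return 0.0, 1.0
        ranks = sps.rankdata(np.abs(d))
    elif zero_method == "pratt":
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 0.0, 1.0
        ranks_all = sps.rankdata(np.abs(d))
        nz = d != 0
        ranks = ranks_all[nz]  # zeros keep their (low) ranks but are never signed
        d = d[nz]
    else:
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    if method == "auto":
        method = "exact" if n <= EXACT_N_MAX else "approx"
    if method == "exact":
        ranks2 = np.rint(2 * ranks).astype(int)
        w2 = int(np.rint(2 * w_plus))
        # Pratt zeros shift every rank but contribute no signed mass
        cdf, sf = _signed_rank_exact_sf_cdf(ranks2, w2)
        p = min(1.0, 2.0 * min(cdf, sf))
    elif method == "approx":
        mu = ranks.sum() / 2.0
        var = float((ranks**2).sum()) / 4.0  # midrank form; exact under ties
        if var == 0:
            return w_plus, 1.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * sps.norm.sf(abs(z)))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return w_plus, min(1.0, p)


# --------------------------------------------------------------------------
# Mann-Whitney
# --------------------------------------------------------------------------
def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "auto",
) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U from midranks.

    Exact for small samples without ties, otherwise a tie-corrected
    normal approximation (no continuity correction).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if method == "auto":
        method = "exact" if (not ties and max(a.size, b.size) <= 20) else "asymptotic"
    if np.unique(np.concatenate([a, b])).size == 1:
        # both samples a single shared value: no evidence either way
        return a.size * b.size / 2.0, 1.0
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method=method,
        use_continuity=False,
    )
    p = float(res.pvalue)
    return float(res.statistic), min(1.0, p) if np.isfinite(p) else 1.0


# --------------------------------------------------------------------------
# chi-square with Yates correction
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class Contingency2x2:
    """A 2x2 contingency table: rows = groups, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in cells):
            raise ValidationError(f"cells must be non-negative integers: {cells}")
        if sum(cells) == 0:
            raise ValidationError("table total must be > 0")


def chi_square_yates(
    table: Union[Contingency2x2, Sequence[Sequence[int]]],
) -> Tuple[float, float]:
    """Yates-continuity-corrected chi-square test on a 2x2 table.

    ``chi2 = N (max(|ad - bc| - N/2, 0))^2 / ((a+b)(c+d)(a+c)(b+d))``,
    with the two-sided p from the chi-square(1) survival function.
    """
    if not isinstance(table, Contingency2x2):
        arr = np.asarray(table)
        if arr.shape != (2, 2):
            raise ValidationError(f"expected a 2x2 table, got shape {arr.shape}")
        table = Contingency2x2(*(int(v) for v in arr.ravel()))
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    marg = (a + b) * (c + d) * (a + c) * (b + d)
    if marg == 0:
        raise ValidationError("a marginal total is zero; test undefined")
    chi2 = n * max(abs(a * d - b * c) - n / 2.0, 0.0) ** 2 / marg
    p = 1.0 if chi2 == 0 else float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


# --------------------------------------------------------------------------
# weighted kappa
# --------------------------------------------------------------------------
def weighted_kappa(
    ratings_a: Sequence[int],
    ratings_b: Sequence[int],
    categories: Sequence[int] = (1, 2, 3, 4, 5),
    weighting: str = "linear",
) -> float:
    """Cohen's weighted kappa for two raters over ordinal categories.

    ``kappa = 1 - sum(w * O) / sum(w * E)`` with disagreement weights
    ``|i - j| / (k - 1)`` (linear) or its square (quadratic), observed
    proportions O and chance-expected proportions E from the marginal
    products.  Raises when both raters use a single identical category
    (agreement by chance is then total and kappa is undefined).
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    cats = np.asarray(sorted(categories))
    k = cats.size
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValidationError("need two equal-length 1-D rating vectors, n >= 1")
    if not (np.isin(a, cats).all() and np.isin(b, cats).all()):
        raise ValidationError(f"ratings outside category set {list(cats)}")
    if weighting not in ("linear", "quadratic"):
        raise ValidationError(f"weighting must be linear|quadratic, got {weighting!r}")
    ia = np.searchsorted(cats, a)
    ib = np.searchsorted(cats, b)
    obs = np.zeros((k, k))
    np.add.at(obs, (ia, ib), 1.0)
    obs /= a.size
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    diff = np.abs(np.arange(k)[:, None] - np.arange(k)[None, :]) / (k - 1)
    w = diff if weighting == "linear" else diff**2
    denom = float((w * exp).sum())
    if denom == 0:
        raise ValidationError(
            "kappa undefined: both raters used a single identical category"
        )
    return float(1.0 - (w * obs).sum() / denom)


# --------------------------------------------------------------------------
# score summaries
# --------------------------------------------------------------------------
REQUIRED_SCORE_COLUMNS = ("case", "structure", "condition", "reader", "score")


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the visibility-score table invariants (1-5 integral scores,
    unique (case, structure, condition, reader) keys)."""
    missing = [c for c in REQUIRED_SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"score table missing columns {missing}")
    s = table["score"]
    if not ((s >= 1) & (s <= 5) & (s == s.astype(int))).all():
        raise ValidationError("scores must be integers in [1, 5]")
    key = ["case", "structure", "condition", "reader"]
    if table.duplicated(subset=key).any():
        raise ValidationError("duplicate (case, structure, condition, reader) rows")
    return table


def summarize_scores(
    table: pd.DataFrame,
    grouping: Sequence[str] = ("structure", "condition"),
) -> pd.DataFrame:
    """Per-group median, IQR and range of visibility scores.

    Quantiles use inclusive linear interpolation, so an even-sized group
    like [2, 2, 3, 3] gets the half-integer median 2.5.  Output includes
    a formatted ``"m (IQR: a-b, range: c-d)"`` column.
    """
    validate_score_table(table)
    rows = []
    for keys, grp in table.groupby(list(grouping)):
        if grp.empty:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"empty group {keys}; omitted")
            continue
        s = grp["score"].to_numpy(dtype=float)
        med = float(np.percentile(s, 50, method="linear"))
        q1 = float(np.percentile(s, 25, method="linear"))
        q3 = float(np.percentile(s, 75, method="linear"))
        lo, hi = float(s.min()), float(s.max())
        keys = keys if isinstance(keys, tuple) else (keys,)
        rows.append(
            dict(zip(grouping, keys))
            | {
                "n": len(s),
                "median": med,
                "q1": q1,
                "q3": q3,
                "min": lo,
                "max": hi,
                "formatted": f"{_fmt(med)} (IQR: {_fmt(q1)}–{_fmt(q3)}, "
                f"range: {_fmt(lo)}–{_fmt(hi)})",
            }
        )
    return pd.DataFrame(rows)


def _fmt(x: float) -> str:
    return f"{x:g}"


def compare_conditions(
    table: pd.DataFrame,
    reader: Union[str, int, None] = None,
) -> pd.DataFrame:
    """Per-structure paired Wilcoxon of focused vs unmodified scores."""
    validate_score_table(table)
    if reader is not None:
        table = table[table["reader"] == reader]
    rows = []
    for structure, grp in table.groupby("structure"):
        piv = grp.pivot_table(
            index="case", columns="condition", values="score", aggfunc="first"
        ).dropna()
        if not {"focused", "unmodified"} <= set(piv.columns):
            warnings.warn(f"structure {structure}: missing a condition; omitted")
            continue
        w, p = wilcoxon_signed_rank(piv["focused"], piv["unmodified"])
        rows.append(
            {"structure": structure, "n": len(piv), "w_plus": w, "p_value": p}
        )
    return pd.DataFrame(rows)
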