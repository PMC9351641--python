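"""Word-report scoring, unimodality testing and bootstrap correlations.

Behavioral performance is the percentage of words correctly reported per
sentence, regardless of word order; per-subject condition means feed the
group statistics.  The distribution of the audio-visual benefit score
(word report in low-clarity AV minus matched-intelligibility high-clarity
AO) is tested for unimodality with Hartigan's dip statistic, and its
association with lip-reading ability (visual-only word report) is
quantified by a Pearson correlation with a percentile bootstrap CI.
"""

from __future__ import annotations

import re
import string
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrialReport",
    "normalize_words",
    "score_word_report",
    "score_transcripts",
    "dip_statistic",
    "hartigans_dip",
    "correlate_bootstrap",
]

CONDITIONS = ("AO_high", "AO_low", "AV_high", "AV_low", "VO")

_PUNCT = re.compile(r"[^\w\s']", flags=re.UNICODE)


def normalize_words(text: str | list[str]) -> list[str]:
    """Lowercase, strip punctuation, split on whitespace.

    Contractions keep their internal apostrophe and count as one token
    ("don't" stays "don't"); no stemming is applied.
    """
    if isinstance(text, str):
        tokens = _PUNCT.sub(" ", text.lower()).split()
    else:
        tokens = [t for w in text for t in _PUNCT.sub(" ", str(w).lower()).split()]
    return [t.strip("'") for t in tokens if t.strip("'")]


@dataclass
class TrialReport:
    """One sentence's target transcript and the listener's response."""

    target: list[str]
    response: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.target = normalize_words(self.target)
        self.response = normalize_words(self.response)
        if not self.target:
            raise ValueError("target sentence must contain at least one word")
        if self.condition and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")


def score_word_report(report: TrialReport) -> float:
    """Percent of target words present in the response, order-free.

    Matching is on word multisets: each target token can be credited at
    most once, and a repeated target word needs a repeated response word.
    """
    target = Counter(report.target)
    response = Counter(report.response)
    matched = sum((target & response).values())
    return 100.0 * matched / sum(target.values())


def score_transcripts(path: str | Path) -> pd.DataFrame:
    """Score a transcript table and summarise by condition.

    The file is delimited text with columns
    ``sentence_id, condition, target_text, response_text``.  Returns a
    tidy frame with one row per sentence plus an ``accuracy`` column;
    ``df.groupby("condition")["accuracy"].mean()`` gives condition means.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"sentence_id", "condition", "target_text", "response_text"}
    if not required.issubset(df.columns):
        raise ValueError(f"transcript table needs columns {sorted(required)}")
    df = df.copy()
    df["response_text"] = df["response_text"].fillna("")
    df["accuracy"] = [
        score_word_report(TrialReport(str(t), str(r), str(c)))
        for t, r, c in zip(df["target_text"], df["response_text"], df["condition"])
    ]
    return df


# -- Hartigan's dip statistic -------------------------------------------------

def dip_statistic(values: np.ndarray) -> float:
    """Hartigan's dip: sup-distance from the empirical CDF to the nearest
    unimodal CDF.

    Implementation follows the classical iterative scheme: repeatedly fit
    the greatest convex minorant and least concave majorant of the
    empirical CDF over a shrinking candidate modal interval, tracking the
    largest deviation.  Distances are carried in counts and converted to
    the [0, 0.25] dip scale at the end.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 4:
        raise ValueError("dip statistic needs at least 4 observations")
    if x[0] == x[-1]:
        return 0.0

    # mn[j]: leftmost index such that the empirical CDF restricted to
    # [mn[j], j] lies on/above its chord (convex-minorant predecessors);
    # mj[k]: the concave-majorant successors, symmetrically.
    mn = np.zeros(n, dtype=int)
    for j in range(1, n):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 0 or (x[j] - x[mnj]) * (mnj - mnmnj) < (x[mnj] - x[mnmnj]) * (j - mnj):
                break
            mn[j] = mnmnj
    mj = np.zeros(n, dtype=int)
    mj[n - 1] = n - 1
    for k in range(n - 2, -1, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n - 1 or (x[k] - x[mjk]) * (mjk - mjmjk) < (x[mjk] - x[mjmjk]) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 0, n - 1
    D = 1.0  # counts scale; enforces the dip's 1/(2n) lower bound
    while True:
        # GCM touch points from high down to low; LCM from low up to high.
        gcm = [high]
        while gcm[-1] > low:
            gcm.append(int(mn[gcm[-1]]))
        l_gcm = len(gcm)
        lcm = [low]
        while lcm[-1] < high:
            lcm.append(int(mj[lcm[-1]]))
        l_lcm = len(lcm)

        # Largest distance between the two fitted curves inside [low, high].
        d = 0.0
        ix, iv = l_gcm - 2, 1
        ig, ih = l_gcm - 1, l_lcm - 1
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix, lcmiv = gcm[ix], lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (x[lcmiv] - x[gcmi1]) * \
                        (gcmix - gcmi1) / (x[gcmix] - x[gcmi1])
                    iv += 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (x[gcmix] - x[lcmiv1]) * (lcmiv - lcmiv1) / \
                        (x[lcmiv] - x[lcmiv1]) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d, ig, ih = dx, ix + 1, iv
                ix = max(ix, 0)
                iv = min(iv, l_lcm - 1)
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0
        if d < D:
            break

        # Largest deviation of the CDF from each fitted curve outside the
        # prospective modal interval.
        dip_l = 0.0
        for j in range(ig, l_gcm - 1):
            jb, je = gcm[j + 1], gcm[j]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (jj - jb + 1) - (x[jj] - x[jb]) * C
                    dip_l = max(dip_l, t)
        dip_u = 0.0
        for j in range(ih, l_lcm - 1):
            jb, je = lcm[j], lcm[j + 1]
            if je - jb > 1 and x[je] != x[jb]:
                C = (je - jb) / (x[je] - x[jb])
                for jj in range(jb, je + 1):
                    t = (je - jj + 1) - (x[je] - x[jj]) * C
                    dip_u = max(dip_u, t)

        D = max(D, dip_l, dip_u)
        if low == gcm[ig] and high == lcm[ih]:
            break
        low, high = gcm[ig], lcm[ih]

    return D / (2.0 * n)


@lru_cache(maxsize=16)
def _null_dips(n: int, n_mc: int, seed: int) -> tuple[float, ...]:
    """Monte-Carlo dip distribution for uniform samples of size n."""
    rng = np.random.default_rng(seed)
    return tuple(dip_statistic(rng.uniform(size=n)) for _ in range(n_mc))


def hartigans_dip(
    values: np.ndarray,
    n_mc: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Dip statistic and its Monte-Carlo p-value.

    The null of unimodality is calibrated against ``n_mc`` uniform samples
    of the same size (the conventional least-favourable unimodal null);
    ``p = (#null >= observed + 1) / (n_mc + 1)``.  A small p-value is
    evidence for a non-unimodal (at least bimodal) distribution.
    """
    d = dip_statistic(values)
    null = np.asarray(_null_dips(int(np.asarray(values).size), n_mc, seed))
    p = (np.sum(null >= d) + 1.0) / (n_mc + 1.0)
    return d, float(p)


def correlate_bootstrap(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    tail: str = "two",
    ci: float = 95.0,
):
    """Pearson correlation with a percentile bootstrap confidence interval.

    Subjects are resampled with replacement ``n_boot`` times; resamples
    with zero variance in either variable (all identical subjects) are
    skipped.  The parametric p-value uses the t transform of r; ``tail``
    selects one- or two-tailed.

    Returns ``(r, p, (ci_lo, ci_hi))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("need paired 1-D samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance sample; correlation undefined")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if tail == "two":
        p = float(res.pvalue)
    else:
        p = float(res.pvalue / 2) if r > 0 else float(1 - res.pvalue / 2)

    rng = np.random.default_rng(seed)
    n = x.size
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xs, ys = x[idx], y[idx]
        if np.std(xs) == 0 or np.std(ys) == 0:
            continue
        boots.append(stats.pearsonr(xs, ys).statistic)
    boots = np.asarray(boots)
    half = (100.0 - ci) / 2.0
    lo, hi = np.percentile(boots, [half, 100.0 - half])
    return r, p, (float(lo), float(hi))
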