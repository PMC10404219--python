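"""Behavioral indices for the lateralized change-detection task.

A session is 120 delayed match-to-sample trials: six 20-trial blocks,
two blocks per memory load (4, 5 or 6 items), each block split 10/10
between left- and right-hemifield trials with 5 match / 5 mismatch per
hemifield.  From the per-(load, hemifield) response counts the module
derives

* the capacity estimate K = load * (accuracy - miss rate) (a Cowan-style
  hit-minus-false-alarm variant is available),
* the sensitivity d' = Z(hit rate) - Z(false-alarm rate) with an
  extreme-rate correction, and its load-weighted average
  mean_load(load * d'_load),
* the lateralization index LI = (M_R - M_L) / (M_R + M_L) for either
  measure, positive when the right hemifield is favoured,
* a median split into low/high-LI groups (at-median goes high), and
* Benjamini-Hochberg FDR adjustment for post-hoc p-values.

A generative signal-detection simulator produces synthetic sessions so
every index is testable without participant data: "same/different"
responses follow the equal-variance Gaussian model with per-hemifield
sensitivity, a common criterion and a lapse rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError

LOADS = (4, 5, 6)
HEMIFIELDS = ("left", "right")


@dataclass(frozen=True)
class SessionDesign:
    """Trial-count structure of one session."""

    blocks: int = 6
    trials_per_block: int = 20
    loads: tuple[int, ...] = LOADS

    def __post_init__(self) -> None:
        if self.blocks % len(self.loads) != 0:
            raise ValidationError("blocks must divide evenly over loads")
        if self.trials_per_block % 4 != 0:
            raise ValidationError(
                "trials per block must split into hemifield x truth quarters"
            )

    @property
    def total_trials(self) -> int:
        return self.blocks * self.trials_per_block

    @property
    def trials_per_load(self) -> int:
        return self.total_trials // len(self.loads)


DEFAULT_DESIGN = SessionDesign()


# ----------------------------------------------------------------- indices
def k_value(load: float, accuracy: float, miss_rate: float) -> float:
    """Working-memory capacity K = load * (accuracy - miss rate).

    Not clipped: poor performance may give a negative K.
    """
    if not (0 <= accuracy <= 1 and 0 <= miss_rate <= 1):
        raise ValidationError("rates must lie in [0, 1]")
    return load * (accuracy - miss_rate)


def corrected_rate(count: int, n: int, method: str = "half") -> float:
    """Proportion with extreme-rate correction: 0 -> 1/(2N), 1 -> 1-1/(2N)
    (``method='half'``), or the log-linear (count+0.5)/(N+1) rule."""
    if n <= 0:
        raise ValidationError("need a positive trial count")
    if method == "loglinear":
        return (count + 0.5) / (n + 1)
    p = count / n
    if p <= 0:
        return 1.0 / (2 * n)
    if p >= 1:
        return 1.0 - 1.0 / (2 * n)
    return p


def dprime(
    hit_rate: float,
    fa_rate: float,
    n_match: int | None = None,
    n_mismatch: int | None = None,
    correction: str = "half",
) -> float:
    """Sensitivity d' = Z(hit rate) - Z(false-alarm rate).

    When trial counts are given, rates of exactly 0 or 1 are first pulled
    off the boundary (1/(2N) rule by default) so d' stays finite.
    """
    h, f = float(hit_rate), float(fa_rate)
    if not (0 <= h <= 1 and 0 <= f <= 1):
        raise ValidationError("rates must lie in [0, 1]")
    if n_match is not None and h in (0.0, 1.0):
        h = corrected_rate(round(h * n_match), n_match, correction)
    if n_mismatch is not None and f in (0.0, 1.0):
        f = corrected_rate(round(f * n_mismatch), n_mismatch, correction)
    return float(norm.ppf(h) - norm.ppf(f))


def weighted_dprime(per_load_dprimes, loads=LOADS) -> float:
    """Load-weighted average: mean over loads of load * d'(load)."""
    d = np.asarray(per_load_dprimes, dtype=float)
    w = np.asarray(loads, dtype=float)
    if d.shape != w.shape:
        raise ValidationError("d' list must align with loads")
    return float(np.mean(w * d))


def lateralization_index(m_right: float, m_left: float) -> float:
    """LI = (M_R - M_L) / (M_R + M_L); NaN (flagged, not raised) when the
    denominator vanishes."""
    denom = m_right + m_left
    if denom == 0:
        return float("nan")
    return (m_right - m_left) / denom


def median_split(per_subject_li) -> pd.Series:
    """Label subjects 'low' (strictly below the median) or 'high' (at or
    above the median LI)."""
    li = pd.Series(per_subject_li, dtype=float)
    if len(li) < 2:
        raise ValidationError("median split needs at least two subjects")
    med = li.median()
    return pd.Series(np.where(li < med, "low", "high"), index=li.index)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("need a 1-D non-empty p-value array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ------------------------------------------------------------------ scoring
def sdt_counts(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-(load, hemifield) response counts.

    A *hit* is a correct 'same' response on a match trial; a *false
    alarm* is a 'same' response on a mismatch trial; omissions ('none')
    count as errors and are tallied separately.
    """
    required = {"load", "hemifield", "truth", "response"}
    if not required <= set(trials.columns):
        raise ValidationError(f"trial table needs columns {sorted(required)}")
    rows = []
    for (load, hemi), g in trials.groupby(["load", "hemifield"], sort=True):
        match = g[g["truth"] == "match"]
        mismatch = g[g["truth"] == "mismatch"]
        rows.append(
            {
                "load": load,
                "hemifield": hemi,
                "n_match": len(match),
                "n_mismatch": len(mismatch),
                "hits": int((match["response"] == "same").sum()),
                "misses": int((match["response"] != "same").sum()),
                "false_alarms": int((mismatch["response"] == "same").sum()),
                "correct_rejections": int(
                    (mismatch["response"] == "different").sum()
                ),
                "omissions": int((g["response"] == "none").sum()),
            }
        )
    return pd.DataFrame(rows)


def indices_from_trials(
    trials: pd.DataFrame,
    k_convention: str = "printed",
    miss_convention: str = "all_trials",
    correction: str = "half",
) -> dict:
    """Compute per-hemifield K, weighted d' and both LIs for one session.

    ``k_convention='printed'`` uses K = load * (accuracy - miss rate)
    with accuracy = (hits + correct rejections) / trials and miss rate =
    misses / trials of that load-hemifield cell (``miss_convention=
    'match_trials'`` divides misses by match trials instead);
    ``k_convention='cowan'`` uses K = load * (hit rate - false-alarm
    rate).  Conventions are recorded in the output.
    """
    counts = sdt_counts(trials)
    out: dict = {
        "k_convention": k_convention,
        "miss_convention": miss_convention,
        "per_hemifield": {},
    }
    for hemi in sorted(counts["hemifield"].unique()):
        sub = counts[counts["hemifield"] == hemi].sort_values("load")
        ks, ds, loads = [], [], []
        for _, row in sub.iterrows():
            n_all = row["n_match"] + row["n_mismatch"]
            hr = row["hits"] / row["n_match"]
            fr = row["false_alarms"] / row["n_mismatch"]
            if k_convention == "cowan":
                k = row["load"] * (hr - fr)
            else:
                accuracy = (row["hits"] + row["correct_rejections"]) / n_all
                denom = row["n_match"] if miss_convention == "match_trials" else n_all
                k = k_value(row["load"], accuracy, row["misses"] / denom)
            ks.append(k)
            ds.append(
                dprime(hr, fr, row["n_match"], row["n_mismatch"], correction)
            )
            loads.append(row["load"])
        out["per_hemifield"][hemi] = {
            "k_per_load": dict(zip(loads, ks)),
            "k_mean": float(np.mean(ks)),
            "dprime_per_load": dict(zip(loads, ds)),
            "weighted_dprime": weighted_dprime(ds, loads),
        }
    if set(out["per_hemifield"]) >= {"left", "right"}:
        left = out["per_hemifield"]["left"]
        right = out["per_hemifield"]["right"]
        out["li_k"] = lateralization_index(right["k_mean"], left["k_mean"])
        out["li_dprime"] = lateralization_index(
            right["weighted_dprime"], left["weighted_dprime"]
        )
    return out


# ---------------------------------------------------------------- simulator
def simulate_session(
    design: SessionDesign = DEFAULT_DESIGN,
    dprime_left: float = 1.5,
    dprime_right: float = 1.5,
    criterion: float = 0.0,
    lapse_rate: float = 0.02,
    seed: int | np.random.Generator = 0,
    subject: str = "s01",
    condition: str = "sim",
) -> pd.DataFrame:
    """Generate one session of synthetic trials from the equal-variance
    Gaussian signal-detection model.

    P(respond 'same' | match) = Phi(d'/2 - c) and P('same' | mismatch) =
    Phi(-d'/2 - c); with probability ``lapse_rate`` the response is a
    coin flip.  Deterministic for a fixed seed; trial counts match the
    design exactly.
    """
    if dprime_left < 0 or dprime_right < 0:
        raise ValidationError("d' must be non-negative")
    if not 0 <= lapse_rate <= 0.2:
        raise ValidationError("lapse rate must lie in [0, 0.2]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dp = {"left": dprime_left, "right": dprime_right}
    quarter = design.trials_per_block // 4
    block_loads = np.repeat(design.loads, design.blocks // len(design.loads))
    rows = []
    for block, load in enumerate(block_loads, start=1):
        for hemi in HEMIFIELDS:
            for truth in ("match", "mismatch"):
                mu = dp[hemi] / 2 if truth == "match" else -dp[hemi] / 2
                p_same = norm.cdf(mu - criterion)
                for _ in range(quarter):
                    if rng.random() < lapse_rate:
                        resp = "same" if rng.random() < 0.5 else "different"
                    else:
                        resp = "same" if rng.random() < p_same else "different"
                    rows.append(
                        (subject, condition, block, load, hemi, truth, resp)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "condition", "block", "load", "hemifield", "truth",
            "response",
        ],
    )
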