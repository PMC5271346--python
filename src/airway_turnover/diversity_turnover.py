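"""Within-subject community turnover statistics.

Two complementary measures of how much a subject's airway community
changes across serial samples:

* **Multi-sample Shannon beta diversity**, the abundance-weighted
  Kullback-Leibler divergence of each sample's composition from the
  subject's pooled composition,

      H_beta = sum_j w_j sum_k q_jk ln(q_jk / qbar_k),

  with sample weights w_j = (sample depth)/(subject total), within-sample
  proportions q_jk and pooled proportions qbar_k.  This is exactly the
  mutual information between the (sample, taxon) joint distribution and
  its marginals.  Exponentiating gives a Hill number — the *effective
  number of communities* among the subject's samples — which runs from 1
  (all samples compositionally identical) to the number of samples
  (fully disjoint).

* **Morisita-Horn similarity** for each within-subject pair of samples,
  in [0, 1]; lower values indicate greater turnover.  MH is computed on
  within-sample proportions and is therefore invariant to sequencing
  depth.

The Hill number depends on how many samples a subject contributed, so a
normalisation (hill - 1)/(j - 1) rescales it to [0, 1] for comparison
across subjects with different sample counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core_data import SubjectSeries

__all__ = [
    "TurnoverResult",
    "shannon_beta_hill",
    "normalize_hill",
    "morisita_horn",
    "pairwise_turnover",
    "turnover_tables",
]


@dataclass
class TurnoverResult:
    """Per-subject turnover summary plus all within-subject pairwise MH values."""

    subject_id: str
    group: str
    n_samples: int
    shannon_beta_nats: float
    hill: float
    hill_normalized: float
    #: (day_a, day_b, interval_days, morisita_horn) for each sample pair
    pairwise: list[tuple[int, int, int, float]]


def shannon_beta_hill(series: SubjectSeries) -> tuple[float, float]:
    """Multi-sample Shannon beta diversity (nats) and its Hill number.

    Requires at least two samples (turnover is undefined for one) and a
    positive total in every sample.  Conventions: 0 * ln 0 = 0.
    """
    counts = np.asarray(series.counts, dtype=float)
    if counts.shape[0] < 2:
        raise ValueError(
            f"subject {series.subject_id}: turnover undefined for a single sample"
        )
    depths = counts.sum(axis=1)
    if (depths == 0).any():
        raise ValueError(f"subject {series.subject_id}: sample with zero total count")
    total = depths.sum()
    w = depths / total  # sample weights c_ij+/c_i++
    q = counts / depths[:, None]  # within-sample proportions
    qbar = counts.sum(axis=0) / total  # pooled subject composition
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = q * np.log(q / qbar[None, :])
    terms[~np.isfinite(terms)] = 0.0  # 0 ln 0 := 0
    h_beta = float((w[:, None] * terms).sum())
    h_beta = max(h_beta, 0.0)  # clip tiny negative rounding
    return h_beta, float(np.exp(h_beta))


def normalize_hill(hill: float, j_i: int) -> float:
    """Rescale a Hill number to [0, 1]: (hill - 1) / (j - 1).

    Undefined for single-sample subjects (j < 2), which is an error here;
    callers report such subjects as missing, never as zero.
    """
    if j_i < 2:
        raise ValueError("normalization undefined for fewer than 2 samples")
    if hill < 1 - 1e-9:
        raise ValueError(f"Hill number {hill} < 1 is impossible")
    return (max(hill, 1.0) - 1.0) / (j_i - 1.0)


def morisita_horn(x, y) -> float:
    """Morisita-Horn similarity between two samples, on proportions.

    MH = 2 sum_k p_k q_k / (sum p_k^2 + sum q_k^2), in [0, 1]: 1 when the
    compositions are proportional, 0 when taxon supports are disjoint.
    Counts are accepted; the statistic is invariant to depth rescaling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"count vectors differ in length: {x.shape} vs {y.shape}")
    sx, sy = x.sum(), y.sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("both samples must have positive totals")
    p, q = x / sx, y / sy
    denom = (p * p).sum() + (q * q).sum()
    return float(2.0 * (p * q).sum() / denom)


def pairwise_turnover(series: SubjectSeries) -> TurnoverResult:
    """All within-subject pairwise MH values plus the Hill-number summary."""
    h_beta, hill = shannon_beta_hill(series)
    pairs = []
    for a, b in combinations(range(series.n_samples), 2):
        mh = morisita_horn(series.counts[a], series.counts[b])
        da, db = int(series.days[a]), int(series.days[b])
        pairs.append((da, db, abs(db - da), mh))
    return TurnoverResult(
        subject_id=series.subject_id,
        group=series.group,
        n_samples=series.n_samples,
        shannon_beta_nats=h_beta,
        hill=hill,
        hill_normalized=normalize_hill(hill, series.n_samples),
        pairwise=pairs,
    )


def turnover_tables(
    series_list: list[SubjectSeries],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch turnover over a cohort.

    Returns a per-subject table (Hill summaries) and a long-format table of
    pairwise Morisita-Horn values with collection intervals.
    """
    subj_rows, pair_rows = [], []
    for s in series_list:
        res = pairwise_turnover(s)
        subj_rows.append(
            {
                "subject_id": res.subject_id,
                "group": res.group,
                "n_samples": res.n_samples,
                "shannon_beta_nats": res.shannon_beta_nats,
                "hill": res.hill,
                "hill_normalized": res.hill_normalized,
            }
        )
        for da, db, interval, mh in res.pairwise:
            pair_rows.append(
                {
                    "subject_id": res.subject_id,
                    "group": res.group,
                    "day_a": da,
                    "day_b": db,
                    "interval_days": interval,
                    "morisita_horn": mh,
                }
            )
    return pd.DataFrame(subj_rows), pd.DataFrame(pair_rows)
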