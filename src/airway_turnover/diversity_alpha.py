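"""Per-sample alpha diversity, evenness and rarefied Good's coverage.

Shannon index H = -sum p_k log(p_k), Pielou evenness H / log(S) for S
observed taxa, and Good's coverage 1 - singletons/depth computed as the
median over repeated without-replacement subsamples at a fixed
rarefaction depth.  The default log base is 2 (the convention of common
amplicon diversity software); natural log is available since the
turnover statistics work in nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd

from .core_data import TaxonCountTable

__all__ = [
    "AlphaResult",
    "shannon_alpha",
    "evenness",
    "goods_coverage_rarefied",
    "alpha_table",
]


@dataclass
class AlphaResult:
    sample_id: str
    shannon: float
    evenness: float | None  # None when < 2 observed taxa (undefined, not 0)
    goods_coverage: float | None  # None when not rarefiable at the depth
    rarefaction_depth: int | None


def shannon_alpha(counts, base: float = 2.0) -> float:
    """Shannon diversity -sum p_k log_base p_k over taxa with p_k > 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / log(base))


def evenness(counts, base: float = 2.0) -> float:
    """Pielou evenness: Shannon / log(observed richness); in [0, 1].

    Small values flag dominance by one or a few organisms.  Undefined for
    fewer than two observed taxa (raises rather than returning 0).
    """
    counts = np.asarray(counts, dtype=float)
    s_obs = int((counts > 0).sum())
    if s_obs < 2:
        raise ValueError("evenness undefined for fewer than 2 observed taxa")
    return shannon_alpha(counts, base=base) / (log(s_obs) / log(base))


def goods_coverage_rarefied(
    counts, depth: int, n_draws: int = 100, seed: int | np.random.Generator = 0
) -> float:
    """Median Good's coverage over repeated rarefactions to ``depth``.

    Each draw subsamples ``depth`` sequences without replacement
    (multivariate hypergeometric) and scores 1 - singletons/depth, the
    fraction of the subsample belonging to taxa seen more than once.
    Samples shallower than ``depth`` are not rarefiable and raise.
    """
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample total {total} below rarefaction depth {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = counts[counts > 0]
    coverages = np.empty(n_draws)
    for i in range(n_draws):
        sub = rng.multivariate_hypergeometric(pos, depth)
        coverages[i] = 1.0 - (sub == 1).sum() / depth
    return float(np.median(coverages))


def alpha_table(
    table: TaxonCountTable,
    base: float = 2.0,
    rarefaction_depth: int | None = None,
    n_draws: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample alpha diversity summary for a whole count table.

    Samples shallower than the rarefaction depth get a missing coverage
    (excluded from rarefaction, never imputed); single-taxon samples get a
    missing evenness.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid, row in zip(table.sample_ids, table.counts):
        s_obs = int((row > 0).sum())
        even = evenness(row, base=base) if s_obs >= 2 else np.nan
        cov = np.nan
        if rarefaction_depth is not None and row.sum() >= rarefaction_depth:
            cov = goods_coverage_rarefied(row, rarefaction_depth, n_draws=n_draws, seed=rng)
        rows.append(
            {
                "sample_id": sid,
                "shannon": shannon_alpha(row, base=base),
                "evenness": even,
                "goods_coverage": cov,
                "rarefaction_depth": rarefaction_depth,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
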