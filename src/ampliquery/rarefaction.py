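"""Rarefaction: random subsampling of a count table to a fixed depth.

All enrichment analysis runs on a rarefied table so that per-sample
sequencing depth cannot masquerade as a biological signal. Each sample's
reads are subsampled uniformly *without replacement* (multivariate
hypergeometric over its feature counts) down to the target depth;
samples with fewer total reads than the depth are dropped.

Randomness is reproducible and order-independent: every sample draws
from its own stream derived from ``(seed, sample_id)``, so reordering
the table's samples does not change any sample's subsample.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np

from ampliquery.core_tables import FeatureTable

__all__ = ["rarefy", "zero_total_features", "sample_rng"]

logger = logging.getLogger(__name__)

#: Default subsampling depth (reads per sample).
DEFAULT_DEPTH = 5000


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Independent random stream for one sample under a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(sample_id.encode()),))
    )


def rarefy(table: FeatureTable, depth: int = DEFAULT_DEPTH, seed: int = 0) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Parameters
    ----------
    table : FeatureTable
    depth : int
        Target reads per sample (default 5000). Samples whose total is
        below ``depth`` are dropped from the output.
    seed : int
        Global seed; each sample's draw uses a stream derived from
        ``(seed, sample_id)``, so identical inputs give bit-identical
        outputs regardless of sample order.

    Returns
    -------
    FeatureTable
        Retained samples each summing to ``depth``; every cell is <=
        its input value. Features left with an all-zero column are kept
        (and logged), not removed — use :func:`zero_total_features` to
        list them.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.info(
            "rarefy: dropping %d/%d samples below depth %d",
            len(dropped), table.n_samples, depth,
        )
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    out = np.zeros((len(kept_ids), table.n_features), dtype=np.int64)
    for i, sid in enumerate(kept_ids):
        row = table.counts[table.sample_index(sid)]
        if row.sum() == depth:
            out[i] = row
            continue
        rng = sample_rng(seed, sid)
        out[i] = rng.multivariate_hypergeometric(row, depth)
    result = FeatureTable(kept_ids, table.feature_ids, out, table.feature_taxonomy)
    empties = zero_total_features(result)
    if empties:
        logger.info("rarefy: %d features have zero total after subsampling", len(empties))
    return result


def zero_total_features(table: FeatureTable) -> list[str]:
    """Feature ids whose column is all zero (e.g. lost to subsampling)."""
    totals = table.feature_totals()
    return [f for f, t in zip(table.feature_ids, totals) if t == 0]
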