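"""Per-sequence metadata-category enrichment statistics.

For a sequence *s* and a categorical metadata value *v*, two tests ask
whether *s* is over-represented among the samples carrying *v*, on a
table rarefied to constant depth:

* **binomial (presence/absence)** — with *N* total samples, *O(s)*
  samples where *s* is present, *T(v)* samples with value *v*, and
  *K_v(s)* samples with value *v* where *s* is present, the null holds
  that presence is equally likely in every sample, ``P_null = O(s)/N``.
  The enrichment P-value is the binomial CDF of ``T(v) - K_v(s)``
  failures in ``T(v)`` trials at failure probability ``1 - P_null`` —
  algebraically the upper-tail probability ``P(X >= K_v(s))`` for
  ``X ~ Binomial(T(v), P_null)``.

* **ranksum (frequency-aware)** — a two-group Kruskal-Wallis test of the
  relative frequencies of *s* in samples with value *v* against all
  other samples, with midranks and tie correction; enrichment is
  reported only when the mean rank of the *v* group exceeds the rest
  (positive direction).

:func:`enumerate_enrichment` applies both tests to every distinct value
of the requested fields and controls the false discovery rate by
Benjamini-Hochberg within each (field, test) family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ampliquery.core_tables import MISSING, FeatureTable, SampleMetadata

__all__ = [
    "PrevalenceSummary",
    "FrequencyPair",
    "EnrichmentResult",
    "prevalence_summary",
    "frequency_pair",
    "binomial_enrichment",
    "ranksum_enrichment",
    "enumerate_enrichment",
    "enriched_subset",
]


@dataclass(frozen=True)
class PrevalenceSummary:
    """Presence/absence bookkeeping for one (sequence, metadata value) pair.

    Attributes
    ----------
    N : int
        Total number of samples.
    O_s : int
        Samples where the sequence is present (count > 0).
    T_v : int
        Samples carrying the metadata value.
    K_vs : int
        Samples carrying the value where the sequence is present.
    """

    N: int
    O_s: int
    T_v: int
    K_vs: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.K_vs <= min(self.O_s, self.T_v)
            and self.T_v <= self.N
            and self.O_s <= self.N
        )
        if not ok:
            raise ValueError(f"inconsistent prevalence summary {self}")

    @property
    def p_null(self) -> float:
        """Null presence probability O(s)/N."""
        return self.O_s / self.N if self.N else 0.0


@dataclass(frozen=True)
class FrequencyPair:
    """Relative frequencies of a sequence inside and outside a category."""

    in_group: tuple[float, ...]
    out_group: tuple[float, ...]

    def __post_init__(self) -> None:
        for v in (*self.in_group, *self.out_group):
            if not (0.0 <= v <= 1.0):
                raise ValueError("relative frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one test of one (field, value) pair for one sequence."""

    field: str
    value: str
    test: str  # "binomial" or "ranksum"
    statistic: float  # K_v(s) for binomial, H for ranksum
    p_value: float
    q_value: float | None
    direction: float | None  # mean-rank difference; ranksum only
    summary: PrevalenceSummary


def _presence(table: FeatureTable, feature: str) -> np.ndarray:
    return table.feature_vector(feature) > 0


def prevalence_summary(
    table: FeatureTable,
    md: SampleMetadata,
    field: str,
    value: str,
    feature: str,
) -> PrevalenceSummary:
    """Count N, O(s), T(v), K_v(s) for one (sequence, value) pair.

    ``N`` and ``O(s)`` are computed over *all* of the table's samples;
    ``T(v)`` and ``K_v(s)`` over the samples whose (non-missing) field
    value equals ``value``. The table and metadata must cover the same
    samples; presence means count > 0 on the (rarefied) table.
    """
    present = _presence(table, feature)
    vals = md.values(field, table.sample_ids)
    in_v = np.array([v is not MISSING and v == value for v in vals])
    return PrevalenceSummary(
        N=table.n_samples,
        O_s=int(present.sum()),
        T_v=int(in_v.sum()),
        K_vs=int((present & in_v).sum()),
    )


def frequency_pair(
    table: FeatureTable,
    md: SampleMetadata,
    field: str,
    value: str,
    feature: str,
) -> FrequencyPair:
    """Split a feature's relative frequencies by category membership.

    Frequencies are count / sample total on the rarefied table (a
    constant denominator when every sample sums to the depth). The
    out-group is every sample not carrying ``value``, including samples
    missing the field, so the two vectors have lengths T(v) and
    N - T(v).
    """
    counts = table.feature_vector(feature).astype(float)
    totals = table.sample_totals().astype(float)
    freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    vals = md.values(field, table.sample_ids)
    in_v = np.array([v is not MISSING and v == value for v in vals])
    return FrequencyPair(
        in_group=tuple(freqs[in_v].tolist()),
        out_group=tuple(freqs[~in_v].tolist()),
    )


def binomial_enrichment(ps: PrevalenceSummary) -> float:
    """Presence/absence enrichment P-value.

    ``binomial_cdf(T(v) - K_v(s), T(v), 1 - P_null)`` with
    ``P_null = O(s)/N``; equals the upper tail P(X >= K) for
    X ~ Binomial(T, P_null). Degenerate nulls (sequence present in
    every sample, or K = 0) give P = 1. The result lies in (0, 1].
    """
    p = float(stats.binom.cdf(ps.T_v - ps.K_vs, ps.T_v, 1.0 - ps.p_null))
    return min(1.0, max(p, math.ulp(0.0)))


def ranksum_enrichment(fp: FrequencyPair) -> tuple[float, float, float]:
    """Two-group Kruskal-Wallis test on a frequency pair.

    Returns
    -------
    (H, p_value, direction)
        ``H`` is computed on midranks over the pooled frequencies and
        divided by the tie correction ``1 - sum(t^3 - t)/(n^3 - n)``;
        ``p_value`` is the chi-square upper tail at 1 degree of freedom;
        ``direction`` is mean rank(in-group) - mean rank(out-group), so
        positive values mean enrichment inside the category. When every
        pooled observation is tied, H = 0 and p = 1.
    """
    a = np.asarray(fp.in_group, dtype=float)
    b = np.asarray(fp.out_group, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_in = ranks[: a.size].mean()
    mean_out = ranks[a.size :].mean()
    direction = float(mean_in - mean_out)
    grand = (n + 1) / 2.0
    h = (
        12.0
        / (n * (n + 1))
        * (a.size * (mean_in - grand) ** 2 + b.size * (mean_out - grand) ** 2)
    )
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    denom = 1.0 - tie_term / (n**3 - n) if n > 1 else 1.0
    if denom <= 0.0:  # all observations identical
        return 0.0, 1.0, direction
    h /= denom
    p = float(stats.chi2.sf(h, df=1)) if h > 0 else 1.0
    return float(h), min(1.0, max(p, math.ulp(0.0))), direction


def _bh_qvalues(pvals: Sequence[float]) -> np.ndarray:
    if len(pvals) == 0:
        return np.array([])
    return stats.false_discovery_control(np.asarray(pvals), method="bh")


def enumerate_enrichment(
    table: FeatureTable,
    md: SampleMetadata,
    feature: str,
    fields: Sequence[str],
    alpha: float = 0.1,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """Test one sequence against every distinct value of each field.

    For each field and each distinct non-missing value, both a binomial
    and a ranksum result are produced. Q-values are computed by the
    chosen correction (``"bh"`` Benjamini-Hochberg, or ``"none"``)
    within each (field, test) family. Use :func:`enriched_subset` to
    extract results significant at ``alpha`` (ranksum additionally
    requires positive direction).
    """
    if correction not in {"bh", "none"}:
        raise ValueError(f"unknown correction {correction!r}")
    results: list[EnrichmentResult] = []
    for field in fields:
        vals = md.values(field, table.sample_ids)
        observed = sum(v is not MISSING for v in vals)
        present = _presence(table, feature)
        o_observed = int(
            sum(p for p, v in zip(present, vals) if v is not MISSING)
        )
        field_results: list[EnrichmentResult] = []
        sum_t = sum_k = 0
        for value in md.distinct_values(field):
            ps = prevalence_summary(table, md, field, value, feature)
            sum_t += ps.T_v
            sum_k += ps.K_vs
            p_bin = binomial_enrichment(ps)
            field_results.append(
                EnrichmentResult(
                    field=field,
                    value=value,
                    test="binomial",
                    statistic=float(ps.K_vs),
                    p_value=p_bin,
                    q_value=None,
                    direction=None,
                    summary=ps,
                )
            )
            fp = frequency_pair(table, md, field, value, feature)
            if fp.out_group:
                h, p_rs, direction = ranksum_enrichment(fp)
            else:  # value covers every sample: no complement to rank against
                h, p_rs, direction = 0.0, 1.0, 0.0
            field_results.append(
                EnrichmentResult(
                    field=field,
                    value=value,
                    test="ranksum",
                    statistic=h,
                    p_value=p_rs,
                    q_value=None,
                    direction=direction,
                    summary=ps,
                )
            )
        # partition bookkeeping: values tile the observed samples exactly
        assert sum_t == observed, (field, sum_t, observed)
        assert sum_k == o_observed, (field, sum_k, o_observed)
        for test in ("binomial", "ranksum"):
            fam = [r for r in field_results if r.test == test]
            ps_ = [r.p_value for r in fam]
            qs = _bh_qvalues(ps_) if correction == "bh" else np.asarray(ps_)
            for r, q in zip(fam, qs):
                results.append(
                    EnrichmentResult(
                        field=r.field,
                        value=r.value,
                        test=r.test,
                        statistic=r.statistic,
                        p_value=r.p_value,
                        q_value=float(q),
                        direction=r.direction,
                        summary=r.summary,
                    )
                )
    return results


def enriched_subset(
    results: Sequence[EnrichmentResult], alpha: float = 0.1
) -> list[EnrichmentResult]:
    """Results significant at ``alpha``; ranksum needs positive direction."""
    out = []
    for r in results:
        q = r.q_value if r.q_value is not None else r.p_value
        if q <= alpha and (r.test != "ranksum" or (r.direction or 0) > 0):
            out.append(r)
    return out
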