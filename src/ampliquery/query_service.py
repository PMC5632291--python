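"""Sequence-in, report-out query layer over a rarefied survey snapshot.

A submitted 16S fragment is matched (by exact 5' prefix) against the
feature sequences of an sOTU table; the report returns the feature's
taxonomy, its prevalence (samples present / total samples), per-field
"pie" breakdowns of all samples versus the samples containing the
sequence, and the metadata categories the sequence is significantly
enriched in.

:class:`QueryService` loads a table once, rarefies it once with a
configured seed, and answers every query from that snapshot, so
repeated queries are mutually consistent. A thin REST application
(stdlib ``http.server``) and the CLI both emit the same canonical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Mapping, Sequence

from ampliquery.core_tables import MISSING, FeatureTable, SampleMetadata
from ampliquery.enrichment import (
    EnrichmentResult,
    PrevalenceSummary,
    enriched_subset,
    enumerate_enrichment,
)
from ampliquery.rarefaction import DEFAULT_DEPTH, rarefy

__all__ = [
    "QueryReport",
    "QueryService",
    "match_query",
    "query_report",
    "make_http_server",
]

_ALPHABET = frozenset("ACGTN")


def match_query(seq: str, table: FeatureTable) -> str | None:
    """Match a query sequence against a table whose feature ids are sequences.

    The query is uppercased, validated over ``{A,C,G,T,N}``, trimmed to
    the table's (uniform) feature length L, and compared for exact
    string equality. Returns the matching feature id, or ``None`` when
    nothing matches or the query is shorter than L.
    """
    q = seq.strip().upper()
    if not q or not set(q) <= _ALPHABET:
        bad = sorted(set(q) - _ALPHABET) if q else []
        raise ValueError(f"query contains characters outside ACGTN: {bad}")
    lengths = {len(f) for f in table.feature_ids}
    if len(lengths) != 1:
        raise ValueError("table features are not uniform-length sequences")
    length = lengths.pop()
    if len(q) < length:
        return None
    q = q[:length]
    return q if q in set(table.feature_ids) else None


@dataclass
class QueryReport:
    """Everything the server returns for one submitted sequence."""

    query_seq: str
    matched_feature: str | None
    taxonomy: str
    n_total: int
    n_present: int
    per_field_pies: dict[str, dict[str, dict[str, int]]]
    enriched: list[EnrichmentResult]

    def to_dict(self) -> dict:
        return {
            "query_seq": self.query_seq,
            "matched_feature": self.matched_feature,
            "taxonomy": self.taxonomy,
            "n_total": self.n_total,
            "n_present": self.n_present,
            "per_field_pies": self.per_field_pies,
            "enriched": [
                {
                    "field": r.field,
                    "value": r.value,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "direction": r.direction,
                    "N": r.summary.N,
                    "O": r.summary.O_s,
                    "T": r.summary.T_v,
                    "K": r.summary.K_vs,
                }
                for r in self.enriched
            ],
        }

    def to_json(self) -> str:
        """Canonical JSON (sorted keys, compact separators)."""
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, doc: Mapping) -> "QueryReport":
        enriched = [
            EnrichmentResult(
                field=e["field"],
                value=e["value"],
                test=e["test"],
                statistic=e["statistic"],
                p_value=e["p_value"],
                q_value=e["q_value"],
                direction=e["direction"],
                summary=PrevalenceSummary(
                    N=e["N"], O_s=e["O"], T_v=e["T"], K_vs=e["K"]
                ),
            )
            for e in doc["enriched"]
        ]
        return cls(
            query_seq=doc["query_seq"],
            matched_feature=doc["matched_feature"],
            taxonomy=doc["taxonomy"],
            n_total=doc["n_total"],
            n_present=doc["n_present"],
            per_field_pies={
                f: {k: dict(v) for k, v in pies.items()}
                for f, pies in doc["per_field_pies"].items()
            },
            enriched=enriched,
        )

    @classmethod
    def from_json(cls, text: str) -> "QueryReport":
        return cls.from_dict(json.loads(text))


def _pies(
    table: FeatureTable,
    md: SampleMetadata,
    fields: Sequence[str],
    feature: str | None,
) -> dict[str, dict[str, dict[str, int]]]:
    present = (
        table.feature_vector(feature) > 0
        if feature is not None
        else [False] * table.n_samples
    )
    pies: dict[str, dict[str, dict[str, int]]] = {}
    for field in fields:
        vals = md.values(field, table.sample_ids)
        all_counts: dict[str, int] = {}
        present_counts: dict[str, int] = {}
        for v, p in zip(vals, present):
            if v is MISSING:
                continue
            all_counts[v] = all_counts.get(v, 0) + 1
            if p:
                present_counts[v] = present_counts.get(v, 0) + 1
        pies[field] = {"all": all_counts, "present": present_counts}
    return pies


def query_report(
    seq: str,
    table: FeatureTable,
    md: SampleMetadata,
    fields: Sequence[str] | None = None,
    alpha: float = 0.1,
) -> QueryReport:
    """Full report for one query against an already-rarefied table.

    Composes :func:`match_query`, the per-field prevalence pies, and
    :func:`ampliquery.enrichment.enumerate_enrichment`. An unmatched
    query yields ``matched_feature=None``, zero prevalence, and an
    empty enrichment list.
    """
    fields = list(fields) if fields is not None else md.field_names
    feature = match_query(seq, table)
    if feature is None:
        return QueryReport(
            query_seq=seq,
            matched_feature=None,
            taxonomy="Unclassified",
            n_total=table.n_samples,
            n_present=0,
            per_field_pies=_pies(table, md, fields, None),
            enriched=[],
        )
    taxonomy = "Unclassified"
    if table.feature_taxonomy and feature in table.feature_taxonomy:
        taxonomy = table.feature_taxonomy[feature].to_string() or "Unclassified"
    results = enumerate_enrichment(table, md, feature, fields, alpha=alpha)
    return QueryReport(
        query_seq=seq,
        matched_feature=feature,
        taxonomy=taxonomy,
        n_total=table.n_samples,
        n_present=int((table.feature_vector(feature) > 0).sum()),
        per_field_pies=_pies(table, md, fields, feature),
        enriched=enriched_subset(results, alpha=alpha),
    )


class QueryService:
    """A loaded, rarefied survey snapshot answering sequence queries.

    The table is rarefied exactly once at construction with the given
    depth and seed; metadata is aligned to the retained samples. All
    queries are answered from this snapshot.
    """

    def __init__(
        self,
        table: FeatureTable,
        metadata: SampleMetadata,
        fields: Sequence[str] | None = None,
        depth: int = DEFAULT_DEPTH,
        seed: int = 0,
        alpha: float = 0.1,
        rarefied: bool = False,
    ) -> None:
        missing = set(table.sample_ids) - set(metadata.sample_ids)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        self.depth = depth
        self.seed = seed
        self.alpha = alpha
        self.table = table if rarefied else rarefy(table, depth=depth, seed=seed)
        self.metadata = metadata
        self.fields = list(fields) if fields is not None else metadata.field_names

    def info(self) -> dict:
        return {
            "n_samples": self.table.n_samples,
            "n_features": self.table.n_features,
            "fields": self.fields,
            "depth": self.depth,
            "seed": self.seed,
        }

    def report(
        self,
        seq: str,
        fields: Sequence[str] | None = None,
        alpha: float | None = None,
    ) -> QueryReport:
        return query_report(
            seq,
            self.table,
            self.metadata,
            fields=fields if fields is not None else self.fields,
            alpha=alpha if alpha is not None else self.alpha,
        )

    def report_many(
        self, seqs: Sequence[str], fields=None, alpha=None
    ) -> list[QueryReport]:
        """Reports for several queries, returned in input order."""
        return [self.report(s, fields=fields, alpha=alpha) for s in seqs]


def make_http_server(service: QueryService, host: str = "127.0.0.1", port: int = 5000):
    """REST application over a :class:`QueryService`.

    Endpoints:

    * ``GET /v1/info`` — snapshot summary
      ``{n_samples, n_features, fields, depth, seed}``.
    * ``POST /v1/enrichment`` — body
      ``{"sequence": str, "fields": [str]?, "alpha": float?}``; returns
      the :class:`QueryReport` JSON. Alphabet errors give HTTP 400; an
      unmatched sequence is a normal 200 report with
      ``matched_feature`` null.

    Returns an unstarted :class:`http.server.ThreadingHTTPServer`; call
    ``serve_forever()`` (or run it in a thread) and ``shutdown()``.
    """

    class Handler(BaseHTTPRequestHandler):
        def log_message(self, fmt, *args):  # quiet by default
            pass

        def _send(self, code: int, payload: str) -> None:
            body = payload.encode()
            self.send_response(code)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(body)))
            self.end_headers()
            self.wfile.write(body)

        def do_GET(self) -> None:
            if self.path.rstrip("/") == "/v1/info":
                self._send(
                    200,
                    json.dumps(service.info(), sort_keys=True, separators=(",", ":")),
                )
            else:
                self._send(404, json.dumps({"error": "not found"}))

        def do_POST(self) -> None:
            if self.path.rstrip("/") != "/v1/enrichment":
                self._send(404, json.dumps({"error": "not found"}))
                return
            try:
                length = int(self.headers.get("Content-Length", "0"))
                doc = json.loads(self.rfile.read(length) or b"{}")
                seq = doc["sequence"]
            except (json.JSONDecodeError, KeyError) as exc:
                self._send(400, json.dumps({"error": f"bad request: {exc}"}))
                return
            try:
                report = service.report(
                    seq, fields=doc.get("fields"), alpha=doc.get("alpha")
                )
            except ValueError as exc:
                self._send(400, json.dumps({"error": str(exc)}))
                return
            self._send(200, report.to_json())

    return ThreadingHTTPServer((host, port), Handler)
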