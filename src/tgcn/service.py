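"""Minimal HTTP facade over the construction engine.

A single stateless endpoint, ``POST /tgcn``, accepts

.. code-block:: json

    {"genes": ["EWSR1", "YAP1"], "tissues": null, "threshold": 0.05}

and responds with the temporal network in the JSON sidecar schema.  The
expression matrix, sample annotations and reference table are configured
at startup and loaded once; each request only resolves its gene list and
rebuilds the network.  Built on the standard library's ``http.server`` —
no web-framework dependency, no state between requests.

Request validation mirrors the CLI's RunConfig invariants (nonempty gene
list, threshold strictly inside (0, 1)); violations return a 422 with a
``detail`` field, engine failures a 500.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

from .builder import DEFAULT_ALPHA, build_temporal_network
from .errors import TGCNError
from .expression import ExpressionDataset, load_expression
from .genes import ReferenceGeneTable, load_reference_table, resolve_genes
from .network_io import to_json_dict

__all__ = ["ServiceState", "create_server", "handle_request"]


@dataclass
class ServiceState:
    """Dataset and reference table shared by all requests."""

    dataset: ExpressionDataset
    reference: ReferenceGeneTable
    workers: int | None = None

    @classmethod
    def from_paths(
        cls,
        expression_path: str | Path,
        annotations_path: str | Path,
        reference_path: str | Path,
        workers: int | None = None,
    ) -> "ServiceState":
        return cls(
            dataset=load_expression(expression_path, annotations_path),
            reference=load_reference_table(reference_path),
            workers=workers,
        )


def _validate(payload: object) -> tuple[list[str], list[str] | None, float]:
    if not isinstance(payload, dict):
        raise ValueError("request body must be a JSON object")
    genes = payload.get("genes")
    if (
        not isinstance(genes, list)
        or not genes
        or not all(isinstance(g, str) and g.strip() for g in genes)
    ):
        raise ValueError("'genes' must be a nonempty list of nonempty strings")
    tissues = payload.get("tissues")
    if tissues is not None and (
        not isinstance(tissues, list)
        or not all(isinstance(t, str) and t.strip() for t in tissues)
    ):
        raise ValueError("'tissues' must be null or a list of nonempty strings")
    threshold = payload.get("threshold", DEFAULT_ALPHA)
    if not isinstance(threshold, (int, float)) or not 0.0 < float(threshold) < 1.0:
        raise ValueError("'threshold' must be a number strictly between 0 and 1")
    return genes, tissues, float(threshold)


def handle_request(payload: object, state: ServiceState) -> tuple[int, dict]:
    """Process one request body; returns (status code, response body).

    Pure function of payload and state — the transport layer below and any
    test can call it directly.
    """
    try:
        genes, tissues, threshold = _validate(payload)
    except ValueError as exc:
        return 422, {"detail": str(exc)}
    try:
        records = resolve_genes(genes, state.reference, strict=True)
        tn, _ = build_temporal_network(
            records,
            state.dataset,
            tissues=tissues,
            alpha=threshold,
            workers=state.workers,
        )
    except TGCNError as exc:
        return 500, {"detail": str(exc)}
    return 200, to_json_dict(tn)


def create_server(
    state: ServiceState, host: str = "127.0.0.1", port: int = 8000
) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server; call ``serve_forever()``."""

    class Handler(BaseHTTPRequestHandler):
        def do_POST(self) -> None:  # noqa: N802 - http.server API
            if self.path.rstrip("/") != "/tgcn":
                self._reply(404, {"detail": "unknown endpoint; POST /tgcn"})
                return
            length = int(self.headers.get("Content-Length", 0))
            try:
                payload = json.loads(self.rfile.read(length) or b"null")
            except json.JSONDecodeError:
                self._reply(422, {"detail": "request body is not valid JSON"})
                return
            status, body = handle_request(payload, state)
            self._reply(status, body)

        def _reply(self, status: int, body: dict) -> None:
            data = json.dumps(body).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def log_message(self, *args) -> None:  # silence per-request stderr noise
            pass

    return ThreadingHTTPServer((host, port), Handler)
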