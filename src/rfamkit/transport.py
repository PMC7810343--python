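"""Remote Rfam interactions behind a pluggable backend.

Every remote operation — family data retrieval, sequence-search job
submission and polling, keyword search, accession/ID lookup — is expressed
as an :class:`EndpointRequest` and served by a backend: either live HTTP
against the Rfam REST service (stdlib ``urllib``) or a deterministic on-disk
replay store. Replay mode performs zero network operations; an unrecorded
request raises :class:`ReplayMissError`, never a silent network call.

Payloads (SVG, covariance models, NHX trees, images) are opaque bytes at
this layer; parsing belongs to :mod:`rfamkit.formats`.
"""

from __future__ import annotations

import hashlib
import json
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

from .errors import (
    FamilyNotFoundError,
    FragmentTooLongError,
    JobExpiredError,
    ReplayMissError,
    ServiceUnavailableError,
    ValidationError,
)
from .model import SEARCH_WINDOW_LIMIT, SequenceFragment

ENDPOINT_KINDS = frozenset(
    {
        "summary",
        "secondary_structure",
        "structure_image",
        "seed_alignment",
        "seed_tree",
        "seed_tree_image",
        "covariance_model",
        "regions",
        "pdb_mapping",
        "text_search",
        "search_submit",
        "search_poll",
        "id_lookup",
    }
)

DEFAULT_BASE_URL = "https://rfam.org"


@dataclass(frozen=True)
class EndpointRequest:
    """One canonicalizable request against the Rfam service."""

    kind: str
    accession_or_id: str = ""
    params: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ENDPOINT_KINDS:
            raise ValidationError(f"unknown endpoint kind {self.kind!r}")

    def canonical_key(self) -> str:
        """Stable digest of the request used as the replay-store key.

        Canonical form: endpoint kind + accession/id + params sorted by key,
        with any ``sequence`` parameter replaced by the SHA-256 digest of its
        uppercased value so the key is stable across clients and compact for
        long queries.
        """
        params = dict(self.params)
        if "sequence" in params:
            params["sequence"] = hashlib.sha256(
                params["sequence"].upper().encode()
            ).hexdigest()
        blob = json.dumps(
            {"kind": self.kind, "target": self.accession_or_id, "params": params},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:24]

    def describe(self) -> str:
        return f"{self.kind}({self.accession_or_id or self.params})"


@dataclass(frozen=True)
class TransportResponse:
    status: int
    content_kind: str  # json | stockholm | nhx | cm | svg | image | text
    body: bytes


@dataclass(frozen=True)
class JobHandle:
    """Opaque handle to an asynchronous server-side search job."""

    job_identifier: str
    submitted_fragment: SequenceFragment

    def __post_init__(self) -> None:
        if not self.job_identifier:
            raise ValidationError("job identifier must be non-empty")


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class ReplayStore:
    """On-disk store of recorded responses, one JSON envelope + raw body per entry.

    Layout: ``<dir>/<key>.json`` holds ``{"request": ..., "status": ...,
    "content_kind": ..., "body_file": "<key>.body"}``; the body file holds the
    verbatim payload bytes. Lookups are deterministic and identical requests
    return byte-identical responses.
    """

    def __init__(self, directory: str | Path) -> None:
        self.directory = Path(directory)

    def record(self, request: EndpointRequest, response: TransportResponse) -> str:
        self.directory.mkdir(parents=True, exist_ok=True)
        key = request.canonical_key()
        body_name = f"{key}.body"
        envelope = {
            "request": {
                "kind": request.kind,
                "accession_or_id": request.accession_or_id,
                "params": dict(request.params),
            },
            "status": response.status,
            "content_kind": response.content_kind,
            "body_file": body_name,
        }
        (self.directory / f"{key}.json").write_text(
            json.dumps(envelope, indent=1, sort_keys=True)
        )
        (self.directory / body_name).write_bytes(response.body)
        return key

    def lookup(self, request: EndpointRequest) -> TransportResponse:
        key = request.canonical_key()
        envelope_path = self.directory / f"{key}.json"
        if not envelope_path.exists():
            raise ReplayMissError(key, request.describe())
        envelope = json.loads(envelope_path.read_text())
        body = (self.directory / envelope["body_file"]).read_bytes()
        return TransportResponse(
            status=envelope["status"],
            content_kind=envelope["content_kind"],
            body=body,
        )


class ReplayBackend:
    """Backend serving only recorded responses; performs no network I/O."""

    is_replay = True

    def __init__(self, directory: str | Path) -> None:
        self.store = ReplayStore(directory)

    def request(self, request: EndpointRequest) -> TransportResponse:
        return self.store.lookup(request)


_LIVE_PATHS = {
    "summary": "/family/{target}?content-type=application/json",
    "secondary_structure": "/family/{target}/structure?content-type=application/json",
    "structure_image": "/family/{target}/image/{plot_type}",
    "seed_alignment": "/family/{target}/alignment?format={format}&download=1",
    "seed_tree": "/family/{target}/tree/?content-type=text/plain",
    "seed_tree_image": "/family/{target}/tree/label/{label}/image",
    "covariance_model": "/family/{target}/cm",
    "regions": "/family/{target}/regions?content-type=application/json",
    "pdb_mapping": "/family/{target}/structures?content-type=application/json",
    "text_search": "/search?q={query}&content-type=application/json",
    "id_lookup": "/family/{target}?content-type=application/json",
}


class HttpBackend:
    """Live HTTP backend against the public Rfam REST service.

    Uses stdlib urllib; enforces a minimum spacing between sequence-search
    submissions (default 1 s) to stay polite to the public service.
    """

    is_replay = False

    def __init__(
        self,
        base_url: str = DEFAULT_BASE_URL,
        timeout: float = 30.0,
        min_submit_spacing: float = 1.0,
        clock: Callable[[], float] = time.monotonic,
        sleep: Callable[[float], None] = time.sleep,
    ) -> None:
        self.base_url = base_url.rstrip("/")
        self.timeout = timeout
        self.min_submit_spacing = min_submit_spacing
        self._clock = clock
        self._sleep = sleep
        self._last_submit: Optional[float] = None

    def _url(self, request: EndpointRequest) -> tuple[str, Optional[bytes]]:
        params = {k: str(v) for k, v in request.params.items()}
        if request.kind == "search_submit":
            return f"{self.base_url}/search/sequence", urllib.parse.urlencode(
                {"q": params["sequence"]}
            ).encode()
        if request.kind == "search_poll":
            return (
                f"{self.base_url}/search/sequence/{params['job_id']}"
                "?content-type=application/json",
                None,
            )
        path = _LIVE_PATHS[request.kind].format(
            target=urllib.parse.quote(request.accession_or_id),
            query=urllib.parse.quote(params.get("query", "")),
            plot_type=params.get("plot_type", "norm"),
            format=params.get("format", "stockholm"),
            label=params.get("label", "species"),
        )
        return self.base_url + path, None

    def request(self, request: EndpointRequest) -> TransportResponse:
        if request.kind == "search_submit":
            self._throttle()
        url, data = self._url(request)
        req = urllib.request.Request(
            url, data=data, headers={"Accept": "application/json, */*"}
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                body = resp.read()
                status = resp.status
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise FamilyNotFoundError(request.accession_or_id) from exc
            raise ServiceUnavailableError(f"HTTP {exc.code} for {url}") from exc
        except urllib.error.URLError as exc:
            raise ServiceUnavailableError(f"cannot reach {url}: {exc.reason}") from exc
        kind = "json" if b"json" in (req.get_header("Accept") or "").encode() else "text"
        return TransportResponse(status=status, content_kind=kind, body=body)

    def _throttle(self) -> None:
        now = self._clock()
        if self._last_submit is not None:
            wait = self.min_submit_spacing - (now - self._last_submit)
            if wait > 0:
                self._sleep(wait)
        self._last_submit = self._clock()


# ---------------------------------------------------------------------------
# Transport facade: retries, job orchestration, payload-level helpers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RetryPolicy:
    """Exponential backoff for transient failures and job polling.

    Poll delays start at ``poll_initial`` seconds and grow by
    ``poll_multiplier`` up to ``poll_cap``; the schedule is monotonically
    non-decreasing. ``max_retries`` bounds re-attempts of a failed fetch.
    """

    max_retries: int = 3
    backoff_initial: float = 1.0
    backoff_multiplier: float = 2.0
    poll_initial: float = 5.0
    poll_multiplier: float = 1.5
    poll_cap: float = 60.0
    poll_timeout: float = 600.0

    def backoff_delays(self) -> list[float]:
        return [
            self.backoff_initial * self.backoff_multiplier**i
            for i in range(self.max_retries)
        ]

    def poll_delays(self):
        delay = self.poll_initial
        while True:
            yield delay
            delay = min(delay * self.poll_multiplier, self.poll_cap)


#: Retry policy with no waiting, used for replay backends where delays are
#: pointless because responses are local and deterministic.
NO_WAIT = RetryPolicy(
    max_retries=0,
    backoff_initial=0.0,
    poll_initial=0.0,
    poll_multiplier=1.0,
    poll_cap=0.0,
    poll_timeout=0.0,
)


class Transport:
    """Retrying, job-aware facade over a backend."""

    def __init__(
        self,
        backend,
        policy: Optional[RetryPolicy] = None,
        sleep: Callable[[float], None] = time.sleep,
    ) -> None:
        self.backend = backend
        if policy is None:
            policy = NO_WAIT if getattr(backend, "is_replay", False) else RetryPolicy()
        self.policy = policy
        self._sleep = sleep
        self._poll_counts: dict[str, int] = {}

    @classmethod
    def for_replay(cls, directory: str | Path) -> "Transport":
        return cls(ReplayBackend(directory), policy=NO_WAIT)

    # -- low-level -----------------------------------------------------

    def fetch(self, request: EndpointRequest) -> TransportResponse:
        """Fetch with retries on transient failures.

        Not-found and replay-miss errors are final and never retried; backoff
        delays are monotonically non-decreasing and the retry count never
        exceeds the policy cap.
        """
        delays = self.policy.backoff_delays()
        attempt = 0
        while True:
            try:
                response = self.backend.request(request)
            except (FamilyNotFoundError, ReplayMissError):
                raise
            except ServiceUnavailableError:
                if attempt >= self.policy.max_retries:
                    raise
                if delays[attempt] > 0:
                    self._sleep(delays[attempt])
                attempt += 1
                continue
            if response.status == 404:
                raise FamilyNotFoundError(request.accession_or_id or request.describe())
            if response.status >= 400:
                raise ServiceUnavailableError(
                    f"status {response.status} for {request.describe()}"
                )
            return response

    def fetch_json(self, request: EndpointRequest) -> dict | list:
        return json.loads(self.fetch(request).body.decode())

    # -- sequence search -----------------------------------------------

    def submit_search(self, fragment: SequenceFragment) -> JobHandle:
        """Submit one fragment for searching; never blocks on completion."""
        if len(fragment) > SEARCH_WINDOW_LIMIT:
            raise FragmentTooLongError(len(fragment), SEARCH_WINDOW_LIMIT)
        request = EndpointRequest(
            kind="search_submit", params={"sequence": fragment.residues}
        )
        payload = json.loads(self.fetch(request).body.decode())
        job_id = payload.get("job_id") or payload.get("resultURL", "")
        if not job_id:
            raise ServiceUnavailableError("search submission returned no job id")
        return JobHandle(job_identifier=str(job_id), submitted_fragment=fragment)

    def poll_search(self, handle: JobHandle) -> tuple[str, Optional[dict]]:
        """One poll of a search job: ``("pending", None)`` or ``("done", payload)``.

        A recorded poll entry may hold a single response object or a
        ``{"responses": [...]}`` sequence emulating the pending -> done
        transition; successive polls consume the sequence and the final
        element repeats, so a completed result never mutates.
        """
        request = EndpointRequest(
            kind="search_poll", params={"job_id": handle.job_identifier}
        )
        try:
            payload = json.loads(self.fetch(request).body.decode())
        except ReplayMissError:
            raise JobExpiredError(handle.job_identifier) from None
        except FamilyNotFoundError:
            raise JobExpiredError(handle.job_identifier) from None
        if isinstance(payload, dict) and "responses" in payload:
            seq = payload["responses"]
            i = self._poll_counts.get(handle.job_identifier, 0)
            self._poll_counts[handle.job_identifier] = i + 1
            payload = seq[min(i, len(seq) - 1)]
        status = payload.get("status", "done" if "hits" in payload else "pending")
        if status in ("pending", "PEND", "RUN", "queued"):
            return "pending", None
        if status in ("done", "COMPLETE", "complete"):
            return "done", payload
        raise ServiceUnavailableError(f"unexpected job status {status!r}")

    def run_search(self, fragment: SequenceFragment) -> dict:
        """Submit a fragment and poll to completion under the retry policy."""
        handle = self.submit_search(fragment)
        waited = 0.0
        polls = 0
        for delay in self.policy.poll_delays():
            state, payload = self.poll_search(handle)
            polls += 1
            if state == "done":
                assert payload is not None
                return payload
            if self.policy.poll_timeout > 0 and waited >= self.policy.poll_timeout:
                raise ServiceUnavailableError(
                    f"search job {handle.job_identifier} timed out after {waited:.0f} s"
                )
            if delay <= 0 and polls > 1000:
                # replay stores resolve in a bounded number of recorded polls
                raise ServiceUnavailableError(
                    f"recorded job {handle.job_identifier} never completed"
                )
            if delay > 0:
                self._sleep(delay)
                waited += delay
        raise AssertionError("unreachable")  # pragma: no cover

    # -- lookups -------------------------------------------------------

    def lookup_id(self, accession_or_id: str) -> tuple[str, str]:
        """Resolve a family accession or ID to the (accession, id) pair.

        The pairing is bijective: looking up either member returns the same
        pair.
        """
        request = EndpointRequest(kind="id_lookup", accession_or_id=accession_or_id)
        payload = self.fetch_json(request)
        return str(payload["accession"]), str(payload["id"])

    def text_search(self, query: str) -> list[str]:
        """Keyword search returning de-duplicated accessions in stable order."""
        if not query:
            raise ValidationError("text-search query must be non-empty")
        request = EndpointRequest(kind="text_search", params={"query": query})
        payload = self.fetch_json(request)
        rows = payload["accessions"] if isinstance(payload, dict) else payload
        seen: dict[str, None] = {}
        for acc in rows:
            seen.setdefault(str(acc))
        return list(seen)
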