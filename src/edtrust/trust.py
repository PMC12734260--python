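"""Nurse-side task selection: the CA trust policy and the FIFO comparator.

Under the CA ("Create Assemblies") trust mechanism the service *provider*
decides: doctors broadcast task requests to every nurse, each nurse keeps a
local store of pending requests, maintains per-difficulty-level trust weights
updated from her own success/failure feedback, and self-assesses: once the
weight at some level falls strictly below a threshold (after a warm-up number
of attempts) she classifies herself unreliable and restricts the difficulty
she accepts.  FIFO simply takes the oldest pending request, always.

The weight update is exponential smoothing toward the binary outcome,
``w <- w + alpha * (outcome - w)``, which keeps weights in [0, 1] and gives the
closed-form trajectory ``w_n = 1 - (1 - w_0)(1 - alpha)^n`` under all-success.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterable, Mapping, Optional

from .behavior import LEVELS, MAX_LEVEL, validate_level

if TYPE_CHECKING:  # pragma: no cover
    from .engine import TaskRequest


class StoreConsistencyError(RuntimeError):
    """A request store references an id unknown to the request registry."""


@dataclass
class TrustState:
    """Per-level trust weights, attempt counts, and self-assessment outcome."""

    weights: dict[int, float] = field(default_factory=lambda: {lvl: 0.8 for lvl in LEVELS})
    attempts: dict[int, int] = field(default_factory=lambda: {lvl: 0 for lvl in LEVELS})
    reliable: bool = True
    restricted_max_level: Optional[int] = None

    def accepts_level(self, level: int) -> bool:
        """Whether the nurse currently accepts requests at ``level``.

        A reliable nurse accepts everything.  An unreliable one accepts only
        levels up to her restriction; a restriction of ``None`` (Training
        scenario: the trainee keeps working while mentored) means no cap.
        """
        lvl = validate_level(level)
        if self.reliable or self.restricted_max_level is None:
            return True
        return lvl <= self.restricted_max_level


def record_outcome(
    state: TrustState, level: int, success: bool, learning_rate: float
) -> TrustState:
    """Update the trust weight at ``level`` from one task outcome (in place)."""
    lvl = validate_level(level)
    if not 0.0 < learning_rate <= 1.0:
        raise ValueError("learning_rate must lie in (0, 1]")
    outcome = 1.0 if success else 0.0
    state.weights[lvl] += learning_rate * (outcome - state.weights[lvl])
    # smoothing of values in [0,1] stays in [0,1]; clip only against float dust
    state.weights[lvl] = min(1.0, max(0.0, state.weights[lvl]))
    state.attempts[lvl] += 1
    return state


def self_assess(
    state: TrustState,
    threshold: float,
    min_attempts: int,
    cap: Optional[int] = None,
) -> TrustState:
    """Re-classify the nurse from her current weights (idempotent, in place).

    A level counts as *failing* when it has at least ``min_attempts`` attempts
    and its weight is strictly below ``threshold`` ("falls below" is strict).
    If any level fails the nurse becomes unreliable and her restriction is the
    highest level of the contiguous run of still-acceptable levels starting at
    1 (a capability ladder: failing the easiest tasks disqualifies everything
    above them; untested levels count as acceptable), bounded above by ``cap``
    when one is configured.  ``cap=None`` leaves her unrestricted (the Training
    scenario's mentored trainee keeps working).  A restriction of 0 means no
    task is within her skill level and the nurse idles in the waiting room.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    failing = [
        lvl
        for lvl in LEVELS
        if state.attempts[lvl] >= min_attempts and state.weights[lvl] < threshold
    ]
    if not failing:
        return state
    state.reliable = False
    if cap is None:
        state.restricted_max_level = None
        return state
    prefix = 0
    for lvl in LEVELS:
        if state.attempts[lvl] >= min_attempts and state.weights[lvl] < threshold:
            break
        prefix = lvl
    state.restricted_max_level = min(cap, prefix)
    return state


class RequestStore:
    """A nurse's local, issue-ordered store of pending request ids."""

    def __init__(self, ids: Iterable[int] = ()):
        self._ids: dict[int, None] = {}  # insertion-ordered set
        for rid in ids:
            self.add(rid)

    def add(self, request_id: int) -> None:
        if request_id in self._ids:
            raise ValueError(f"request {request_id} already stored")
        self._ids[request_id] = None

    def discard(self, request_id: int) -> None:
        self._ids.pop(request_id, None)

    def __contains__(self, request_id: int) -> bool:
        return request_id in self._ids

    def __len__(self) -> int:
        return len(self._ids)

    def ids(self) -> list[int]:
        return list(self._ids)


def _ordered_pending(
    store: RequestStore, requests: Mapping[int, "TaskRequest"]
) -> list["TaskRequest"]:
    out = []
    for rid in store.ids():
        try:
            req = requests[rid]
        except KeyError as exc:
            raise StoreConsistencyError(f"request {rid} missing from registry") from exc
        out.append(req)
    # oldest first; ties on issue time break toward the lower request id
    out.sort(key=lambda r: (r.issue_time_s, r.request_id))
    return out


def select_request_ca(
    state: TrustState,
    store: RequestStore,
    requests: Mapping[int, "TaskRequest"],
) -> Optional["TaskRequest"]:
    """Oldest pending request whose requested level the nurse accepts, else None."""
    for req in _ordered_pending(store, requests):
        if state.accepts_level(req.requested_level):
            return req
    return None


def select_request_fifo(
    store: RequestStore, requests: Mapping[int, "TaskRequest"]
) -> Optional["TaskRequest"]:
    """Oldest pending request irrespective of level; None on an empty store."""
    pending = _ordered_pending(store, requests)
    return pending[0] if pending else None


def weight_trajectory(w0: float, learning_rate: float, outcomes: Iterable[bool]) -> list[float]:
    """Iterated weight values after each outcome (convenience for analysis)."""
    state = TrustState(weights={lvl: w0 for lvl in LEVELS})
    traj = []
    for outcome in outcomes:
        record_outcome(state, 1, outcome, learning_rate)
        traj.append(state.weights[1])
    return traj
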