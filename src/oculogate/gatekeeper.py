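"""Decision fusion: combine the identity and screening outcomes into the
four-way access decision and emit an auditable record.

Truth table (identity accepted?, depressive pattern flagged?):

* accepted, not flagged  -> GRANT
* accepted, flagged      -> DENY_TEMP_SCREEN (further investigation)
* rejected, not flagged  -> DENY_IDENTITY
* rejected, flagged      -> DENY_BOTH (data handled separately)

Screening runs only after successful identification; when identity fails the
screening result may be absent and is recorded as not-run.  Screening alone
never grants access.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone

from .irisid import MatchResult

__all__ = ["AccessDecision", "decide", "append_audit", "read_audit"]

OUTCOMES = ("GRANT", "DENY_TEMP_SCREEN", "DENY_IDENTITY", "DENY_BOTH")


@dataclass
class AccessDecision:
    outcome: str
    reasons: list[str] = field(default_factory=list)
    timestamp: str = ""
    probe_ref: str | None = None
    session_ref: str | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()


def decide(match: MatchResult | None, screening_flagged: bool | None,
           probe_ref: str | None = None,
           session_ref: str | None = None) -> AccessDecision:
    """Fuse identification and screening into an access decision.

    ``screening_flagged`` may be None only when identification failed (the
    screening module is skipped in that case and the skip is recorded).
    A missing identity result is an error: screening alone never grants.
    """
    if match is None:
        raise ValueError("identity result is required; screening alone never grants")
    if match.accepted:
        if screening_flagged is None:
            raise ValueError("screening result required after successful "
                             "identification")
        if screening_flagged:
            return AccessDecision(
                "DENY_TEMP_SCREEN",
                reasons=["identity accepted",
                         "depressive pattern flagged: temporary denial, "
                         "further investigation"],
                probe_ref=probe_ref, session_ref=session_ref)
        return AccessDecision("GRANT", reasons=["identity accepted",
                                                "no depressive pattern"],
                              probe_ref=probe_ref, session_ref=session_ref)
    if screening_flagged is None:
        return AccessDecision("DENY_IDENTITY",
                              reasons=["identity rejected", "screening not run"],
                              probe_ref=probe_ref, session_ref=session_ref)
    if screening_flagged:
        return AccessDecision(
            "DENY_BOTH",
            reasons=["identity rejected",
                     "depressive pattern flagged: handle data separately"],
            probe_ref=probe_ref, session_ref=session_ref)
    return AccessDecision("DENY_IDENTITY",
                          reasons=["identity rejected"],
                          probe_ref=probe_ref, session_ref=session_ref)


def append_audit(decision: AccessDecision, path) -> None:
    """Append one decision to a JSON-lines audit log (append-only)."""
    with open(path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(asdict(decision)) + "\n")


def read_audit(path) -> list[AccessDecision]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(AccessDecision(**json.loads(line)))
    return out
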