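"""Typed errors with a fixed message catalogue.

Every analyst-facing failure carries a code and a constant message drawn from
:data:`CATALOGUE`.  Messages never interpolate data values, sizes or
thresholds — a confirming error must not itself become a disclosure channel.
Exact sizes live only in the custodian-side audit metadata.
"""

from __future__ import annotations

__all__ = ["CATALOGUE", "FedShieldError", "error_message"]

CATALOGUE: dict[str, str] = {
    "AUTH_FAILED": "authentication failed",
    "SESSION_INVALID": "session is not valid for this site",
    "VIEW_DENIED": "no data view grants access to the requested dataset",
    "VARIABLE_DENIED": "a requested variable is outside the permitted data view",
    "PARSE_REJECTED": "the request was rejected by the command parser",
    "SEMANTIC_ERROR": "a request argument is not semantically valid",
    "UNKNOWN_SYMBOL": "a referenced server-side object does not exist",
    "NOT_IMPLEMENTED": "the requested function is registered but not executable",
    "SUBSET_TOO_SMALL": "the requested subset does not meet the minimum size threshold",
    "SUMMARY_TOO_SMALL": "the variable does not meet the minimum size threshold for summaries",
    "TABLE_SUPPRESSED": "the requested table was suppressed by disclosure checks",
    "LEVELS_BLOCKED": "the level set was blocked by disclosure checks",
    "POOL_BLOCKED": "pooling was blocked because a site-level result was suppressed",
    "POOL_MISMATCH": "site results are not structurally compatible for pooling",
    "GLM_DIM_BLOCKED": "the model dimension filter blocked the regression request",
    "SINGULAR_INFORMATION": "the pooled information matrix is singular",
    "OBFUSCATION_BLOCKED": "the obfuscation request was blocked by disclosure checks",
    "ACCESS_DENIED": "access denied",
    "CONFIG_ERROR": "the site or connection configuration is invalid",
    "INTERNAL_ERROR": "the request could not be completed",
}


def error_message(code: str) -> str:
    return CATALOGUE.get(code, CATALOGUE["INTERNAL_ERROR"])


class FedShieldError(Exception):
    """A typed failure whose message text comes from the fixed catalogue."""

    def __init__(self, code: str):
        if code not in CATALOGUE:
            code = "INTERNAL_ERROR"
        self.code = code
        super().__init__(CATALOGUE[code])
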