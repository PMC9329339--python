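"""Issue objects shared by the parser and the validator."""

from __future__ import annotations

from dataclasses import dataclass

SEVERITIES = ("error", "warning", "advice")

# Rule catalog applied by validate_record.
VALIDATION_CODES = (
    "REQUIRED_MISSING",
    "COND_FUNDERS",
    "COND_PERSONAL_ID",
    "NO_CREATOR",
    "VOCAB_VIOLATION",
    "VOCAB_CASE",
    "COLOR_FORMAT",
    "STEP_NONPOSITIVE",
    "AGE_NEGATIVE",
    "TAXON_SYNTAX",
    "ID_SYNTAX",
    "SPDX_HINT",
    "SUGGESTED_VALUE_MISS",
    "CARDINALITY",
    "CHANNEL_MISMATCH",
)

# Issues the parser (JSON or tabular) can attach; never raised, always reported.
PARSE_CODES = (
    "UNKNOWN_FIELD",
    "MULTIPLICITY",
    "UNPARSEABLE",
)

ALL_CODES = VALIDATION_CODES + PARSE_CODES


@dataclass(frozen=True)
class ValidationIssue:
    """One problem found in a metadata record.

    ``path`` locates the offending value (``Dataset.Title``,
    ``Contributors[0].nameIdentifier``, ``Image.Channels[2].displayColor``);
    ``code`` is drawn from the fixed rule catalog; ``severity`` is one of
    error / warning / advice.  Only error-severity issues make a record
    invalid.
    """

    path: str
    code: str
    severity: str
    message: str

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown rule code {self.code!r}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")
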