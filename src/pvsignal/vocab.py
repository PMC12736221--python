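"""Controlled vocabularies for ICSR fields, with tolerant normalization.

The canonical spellings follow the public EudraVigilance line-listing
dialect (adrreports.eu).  Parsing is tolerant of case, surrounding
whitespace, repeated internal whitespace and hyphen/en-dash variants;
anything that does not normalize to a canonical value is an error, never
a guess.
"""

from __future__ import annotations

from .exceptions import ValidationError

AGE_GROUPS = (
    "Not Specified",
    "0–1 Month",
    "2 Months–2 Years",
    "3–11 Years",
    "12–17 Years",
    "18–64 Years",
    "65–85 Years",
    "More than 85 Years",
)

SEXES = ("Female", "Male", "Not Specified")

REPORTER_GROUPS = (
    "Healthcare Professional",
    "Non-Healthcare Professional",
    "Not Specified",
)

REGIONS = ("EEA", "Non-EEA")

SERIOUSNESS = ("Serious", "Non-Serious", "Not Specified")

OUTCOMES = (
    "Recovered/Resolved",
    "Recovering/Resolving",
    "Recovered/Resolved with Sequelae",
    "Not Recovered/Not Resolved",
    "Fatal",
    "Unknown",
    "Not Specified",
)

#: Sentinel system organ class for preferred terms absent from the mapping.
UNMAPPED_SOC = "Unmapped"

FIELD_VOCABULARIES = {
    "age_group": AGE_GROUPS,
    "sex": SEXES,
    "reporter_group": REPORTER_GROUPS,
    "region": REGIONS,
    "seriousness": SERIOUSNESS,
    "outcome": OUTCOMES,
}


def normalization_key(value) -> str:
    """Collapse a raw string to the key used for vocabulary lookup."""
    s = str(value).strip().casefold()
    s = s.replace("–", "-").replace("—", "-")
    return " ".join(s.split())


_LOOKUPS = {
    field: {normalization_key(v): v for v in values}
    for field, values in FIELD_VOCABULARIES.items()
}
# Common portal synonyms.
_LOOKUPS["region"]["european economic area"] = "EEA"
_LOOKUPS["region"]["eea"] = "EEA"
_LOOKUPS["region"]["non-european economic area"] = "Non-EEA"
_LOOKUPS["region"]["non eea"] = "Non-EEA"


def normalize(field: str, value, *, row: int | None = None) -> str:
    """Map a raw field value onto its canonical vocabulary spelling.

    Raises :class:`ValidationError` (mentioning the row number when
    known) if the value is not recognised after normalization.
    """
    try:
        return _LOOKUPS[field][normalization_key(value)]
    except KeyError:
        where = f" (row {row})" if row is not None else ""
        raise ValidationError(
            f"unknown {field} value {value!r}{where}; "
            f"expected one of {FIELD_VOCABULARIES[field]}"
        ) from None


def normalize_country(value, *, row: int | None = None) -> str:
    """Normalize an ISO 3166-1 alpha-2 country code ('XX' = unknown)."""
    code = str(value).strip().upper()
    if len(code) == 2 and code.isalpha():
        return code
    where = f" (row {row})" if row is not None else ""
    raise ValidationError(
        f"country must be a two-letter ISO 3166-1 code or 'XX', got {value!r}{where}"
    )


def normalize_year(value, *, row: int | None = None) -> int:
    try:
        return int(str(value).strip())
    except (TypeError, ValueError):
        where = f" (row {row})" if row is not None else ""
        raise ValidationError(f"year must be an integer, got {value!r}{where}") from None
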