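"""Registry of standard-defined metadata keys and dimension tags.

The registry is data, not code: the key table lives in
``data/standard_keys.tsv`` (name, value type, units, privacy flag, one-line
doc) and the dimension-tag vocabulary in ``data/dim_tags.txt``.  Both can be
extended without touching the implementation.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

VALUE_TYPES = frozenset(
    {"number", "string", "number-array", "string-array", "object", "bool"}
)

#: Tags always accepted in addition to the bundled vocabulary.
USER_DIM_TAGS = ("DIM_USER_0", "DIM_USER_1", "DIM_USER_2")

MANDATORY_KEYS = ("SpectrometerFrequency", "ResonantNucleus")

PRIVATE_PREFIX = "private_"


@dataclass(frozen=True)
class KeyDefinition:
    """One standard-defined metadata key."""

    name: str
    value_type: str
    units: str | None
    private: bool
    doc: str


def _read_data_text(filename: str) -> str:
    return resources.files("niftimrs.data").joinpath(filename).read_text("utf-8")


@lru_cache(maxsize=1)
def standard_key_registry() -> dict[str, KeyDefinition]:
    """Parse the bundled key table. Raises on duplicate names or bad types."""
    registry: dict[str, KeyDefinition] = {}
    for lineno, line in enumerate(_read_data_text("standard_keys.tsv").splitlines(), 1):
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise ValueError(f"standard_keys.tsv:{lineno}: expected 5 columns")
        name, value_type, units, private, doc = parts
        if value_type not in VALUE_TYPES:
            raise ValueError(f"standard_keys.tsv:{lineno}: bad type {value_type!r}")
        if name in registry:
            raise ValueError(f"standard_keys.tsv:{lineno}: duplicate key {name!r}")
        registry[name] = KeyDefinition(
            name=name,
            value_type=value_type,
            units=None if units == "-" else units,
            private=private.lower() == "true",
            doc=doc,
        )
    return registry


@lru_cache(maxsize=1)
def dim_tag_vocabulary() -> tuple[str, ...]:
    """Bundled dim-tag vocabulary plus the DIM_USER tags."""
    tags = [
        line.strip()
        for line in _read_data_text("dim_tags.txt").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return tuple(tags) + USER_DIM_TAGS


def key_definition(name: str) -> KeyDefinition | None:
    """Look up a standard-defined key; ``None`` if the name is not standard."""
    return standard_key_registry().get(name)


def is_private(name: str) -> bool:
    """True iff ``name`` is privacy-sensitive.

    A key is private when its standard definition flags it so, or when it
    carries the ``private_`` self-marking prefix (applies to user keys at any
    nesting depth).
    """
    if name.startswith(PRIVATE_PREFIX):
        return True
    definition = standard_key_registry().get(name)
    return definition is not None and definition.private
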