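"""Chronic-condition catalog and ICD-10-CM category mapping.

The analysis classifies every treated condition into one of 20 chronic-condition
categories selected for relevance to primary care (the Fortin-style roster).
Conditions arrive as 3-character ICD-10-CM category codes (e.g. ``I10``); the
mapping from codes to the 20 categories is plain data — an editable TSV — and is
never hard-coded in the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

N_CONDITIONS = 20

#: Default roster, in display order. Each name is a category of treated chronic
#: disease; the roster is configurable but must always have exactly 20 entries.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "arthritis",
    "cardiovascular disease",
    "heart failure",
    "asthma/COPD",
    "musculoskeletal disorder",
    "thyroid disorder",
    "stomach problem",
    "urinary problem",
    "anxiety/depression",
    "cancer",
    "kidney disease",
    "liver disease",
    "dementia",
    "osteoporosis",
    "stroke/TIA",
    "epilepsy",
    "substance use",
)

_ICD3_RE = re.compile(r"^[A-Z][0-9A-Z]{2}$")


class CatalogError(ValueError):
    """Raised when a catalog or code map violates its invariants."""


@dataclass(frozen=True)
class ConditionCatalog:
    """Ordered roster of exactly 20 condition categories plus an ICD-10 code map.

    Parameters
    ----------
    categories:
        Exactly 20 unique condition names; their order fixes the bit layout of
        every condition vector downstream (bit ``i`` <-> ``categories[i]``).
    code_map:
        3-character ICD-10-CM category -> index into ``categories``.
    """

    categories: tuple[str, ...]
    code_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.categories) != N_CONDITIONS:
            raise CatalogError(
                f"catalog must have exactly {N_CONDITIONS} categories, "
                f"got {len(self.categories)}"
            )
        if len(set(self.categories)) != len(self.categories):
            raise CatalogError("category names must be unique")
        for code, idx in self.code_map.items():
            if not _ICD3_RE.match(code):
                raise CatalogError(f"malformed ICD-10 category code: {code!r}")
            if not 0 <= idx < N_CONDITIONS:
                raise CatalogError(f"code {code} maps to invalid index {idx}")

    def index(self, name: str) -> int:
        """Index of a category by name."""
        try:
            return self.categories.index(name)
        except ValueError:
            raise CatalogError(f"unknown condition name: {name!r}") from None

    def mask(self, names) -> int:
        """Bitmask with the bit of each named category set."""
        m = 0
        for name in names:
            m |= 1 << self.index(name)
        return m

    def names(self, itemset) -> tuple[str, ...]:
        """Category names for a tuple of indices."""
        return tuple(self.categories[i] for i in itemset)


def map_icd_to_conditions(
    codes, catalog: ConditionCatalog
) -> tuple[int, int]:
    """Map ICD-10-CM 3-character codes to a 20-bit condition vector.

    A bit is set iff at least one code maps to that category; duplicate codes
    are idempotent and codes absent from the map are ignored but tallied.

    Parameters
    ----------
    codes:
        Iterable of 3-character ICD-10-CM category strings (truncate full
        codes to 3 characters before calling).
    catalog:
        Catalog whose ``code_map`` drives the lookup.

    Returns
    -------
    (mask, n_unmapped):
        ``mask`` is the 20-bit condition vector; ``n_unmapped`` counts codes
        (with multiplicity) not present in the map.

    Raises
    ------
    CatalogError
        If a code string is malformed; the message reports its position.
    """
    mask = 0
    unmapped = 0
    for pos, code in enumerate(codes):
        if not isinstance(code, str) or not _ICD3_RE.match(code):
            raise CatalogError(f"malformed ICD-10 code at position {pos}: {code!r}")
        idx = catalog.code_map.get(code)
        if idx is None:
            unmapped += 1
        else:
            mask |= 1 << idx
    return mask, unmapped


def load_code_map(path, categories: tuple[str, ...]) -> dict[str, int]:
    """Read a (icd10_3, category_name) TSV into a code -> index map."""
    cat_index = {name: i for i, name in enumerate(categories)}
    code_map: dict[str, int] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if lineno == 0 and parts[0].lower() in {"icd10_3", "code"}:
            continue
        if len(parts) != 2:
            raise CatalogError(f"line {lineno + 1}: expected 2 tab-separated fields")
        code, name = parts[0].strip().upper(), parts[1].strip()
        if name not in cat_index:
            raise CatalogError(f"line {lineno + 1}: unknown category {name!r}")
        code_map[code] = cat_index[name]
    return code_map


@lru_cache(maxsize=1)
def default_catalog() -> ConditionCatalog:
    """The shipped catalog: default roster + best-effort ICD-10 map.

    The shipped TSV approximates the primary-care multimorbidity roster from
    3-digit ICD-10-CM categories; swap in a site-specific TSV via
    :func:`load_code_map` when a vetted mapping is available.
    """
    with resources.as_file(
        resources.files("morbmine.data").joinpath("condition_map.tsv")
    ) as p:
        code_map = load_code_map(p, DEFAULT_CATEGORIES)
    return ConditionCatalog(DEFAULT_CATEGORIES, code_map)
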