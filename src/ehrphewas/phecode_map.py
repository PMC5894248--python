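"""ICD-9-CM to phecode mapping.

Phecodes aggregate the ~18,000 ICD-9-CM billing codes into ~1,800
clinically meaningful phenotype codes.  Each map row carries the source
ICD-9 code, the target phecode, a phenotype description, an organ-system
category, and an optional *exclusion range*: the span of phecodes
representing "related diseases", used downstream to remove subjects with
related conditions from a phenotype's control group.

The phecode hierarchy is positional: ``401.22`` is a child of ``401.2``,
which is a child of ``401``.  :func:`related_phecodes` closes a phecode
over (a) itself, (b) its positional descendants, and (c) every phecode in
the map whose numeric value falls inside its exclusion range.

A 30-entry fixture map covering the phecodes used by the bundled
synthetic scenario ships with the package (``fixture_map_path``); the
full v1.2 map from phewascatalog.org loads through the same reader.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

#: Default header aliases, matched case-insensitively after stripping
#: whitespace.  phewascatalog exports vary in header spelling.
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "icd9": ("icd9", "icd9_code", "icd9cm", "icd9 code"),
    "phecode": ("phecode", "phewas code", "phewas_code", "jd_code"),
    "description": ("phewas_string", "phewas string", "phenotype", "description", "phecode_string"),
    "category": ("category", "group", "phewas category", "category_string"),
    "exclusion": (
        "excl_phecodes",
        "excl. phecodes",
        "exclusion_range",
        "exclusion phecode range",
        "phecode_exclude_range",
    ),
}

_EXCL_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*-\s*(\d+(?:\.\d+)?)\s*$")
_PHECODE_RE = re.compile(r"^\d+(?:\.\d{1,2})?$")


class PhecodeMapError(ValueError):
    """Malformed or inconsistent phecode map input."""


@dataclass(frozen=True)
class PhecodeMapEntry:
    """One ICD-9 → phecode map row."""

    icd9_code: str
    phecode: str
    description: str
    category: str
    exclusion_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.icd9_code:
            raise PhecodeMapError("empty icd9_code")
        if not _PHECODE_RE.match(self.phecode):
            raise PhecodeMapError(
                f"phecode {self.phecode!r} is not a decimal with <=2 fractional digits"
            )
        if self.exclusion_range is not None:
            lo, hi = self.exclusion_range
            if lo > hi:
                raise PhecodeMapError(
                    f"exclusion range lower bound {lo} > upper bound {hi} "
                    f"(icd9 {self.icd9_code})"
                )


class PhecodeMap:
    """Validated ICD-9 → phecode lookup with hierarchy and exclusion ranges."""

    def __init__(self, entries: Iterable[PhecodeMapEntry]):
        self.entries: list[PhecodeMapEntry] = list(entries)
        self._by_icd9: dict[str, PhecodeMapEntry] = {}
        self._by_phecode: dict[str, PhecodeMapEntry] = {}
        conflicts = []
        for e in self.entries:
            prev = self._by_icd9.get(e.icd9_code)
            if prev is not None and prev.phecode != e.phecode:
                conflicts.append((e.icd9_code, prev.phecode, e.phecode))
            self._by_icd9[e.icd9_code] = e
            # first row wins as the phecode's representative metadata
            self._by_phecode.setdefault(e.phecode, e)
        if conflicts:
            raise PhecodeMapError(
                "conflicting duplicate icd9 rows: "
                + "; ".join(f"{c[0]} -> {{{c[1]}, {c[2]}}}" for c in conflicts)
            )
        self._phecode_values = {p: float(p) for p in self._by_phecode}

    def __len__(self) -> int:
        return len(self._by_icd9)

    def __contains__(self, phecode: str) -> bool:
        return phecode in self._by_phecode

    @property
    def phecodes(self) -> list[str]:
        return list(self._by_phecode)

    @property
    def categories(self) -> set[str]:
        return {e.category for e in self._by_phecode.values()}

    def entry_for_phecode(self, phecode: str) -> PhecodeMapEntry:
        try:
            return self._by_phecode[phecode]
        except KeyError:
            raise KeyError(f"phecode {phecode!r} not in map") from None

    def entry_for_icd9(self, code: str) -> Optional[PhecodeMapEntry]:
        return self._by_icd9.get(code)

    def to_frame(self) -> pd.DataFrame:
        """Normalized tabular view (one row per ICD-9 code)."""
        rows = []
        for e in self._by_icd9.values():
            excl = (
                ""
                if e.exclusion_range is None
                else f"{_fmt(e.exclusion_range[0])}-{_fmt(e.exclusion_range[1])}"
            )
            rows.append(
                {
                    "icd9": e.icd9_code,
                    "phecode": e.phecode,
                    "phewas_string": e.description,
                    "category": e.category,
                    "excl_phecodes": excl,
                }
            )
        return pd.DataFrame(rows, columns=["icd9", "phecode", "phewas_string", "category", "excl_phecodes"])


def _fmt(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s


def parse_exclusion_range(text: str) -> Optional[tuple[float, float]]:
    """Parse ``"580-589.99"`` into ``(580.0, 589.99)``; blank → None."""
    if text is None or (isinstance(text, float) and pd.isna(text)) or str(text).strip() == "":
        return None
    m = _EXCL_RE.match(str(text))
    if not m:
        raise PhecodeMapError(f"unparseable exclusion range {text!r}")
    return float(m.group(1)), float(m.group(2))


def _resolve_columns(columns: list[str], aliases: dict[str, tuple[str, ...]]) -> dict[str, str]:
    lowered = {c.strip().lower(): c for c in columns}
    resolved = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lowered:
                resolved[canonical] = lowered[name]
                break
    return resolved


def load_phecode_map(path, aliases: Optional[dict[str, tuple[str, ...]]] = None) -> PhecodeMap:
    """Load a phecode map from a v1.2-layout CSV.

    The file must name at least the icd9, phecode, exclusion-range, and
    category columns (header matching is case-insensitive with
    configurable aliases; see :data:`COLUMN_ALIASES`).

    Raises
    ------
    PhecodeMapError
        If a required column is missing, an exclusion range is
        unparseable, or duplicate ICD-9 rows map to conflicting phecodes.
    """
    aliases = aliases or COLUMN_ALIASES
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    resolved = _resolve_columns(list(df.columns), aliases)
    for required in ("icd9", "phecode", "exclusion", "category"):
        if required not in resolved:
            raise PhecodeMapError(
                f"required column {required!r} not found in header {list(df.columns)}"
            )
    entries = []
    for _, row in df.iterrows():
        entries.append(
            PhecodeMapEntry(
                icd9_code=row[resolved["icd9"]].strip(),
                phecode=row[resolved["phecode"]].strip(),
                description=row[resolved["description"]].strip() if "description" in resolved else "",
                category=row[resolved["category"]].strip(),
                exclusion_range=parse_exclusion_range(row[resolved["exclusion"]]),
            )
        )
    pmap = PhecodeMap(entries)
    logger.info("loaded phecode map: %d rows, %d phecodes", len(pmap), len(pmap.phecodes))
    return pmap


def save_phecode_map(pmap: PhecodeMap, path) -> None:
    """Write a normalized map CSV that :func:`load_phecode_map` round-trips."""
    pmap.to_frame().to_csv(path, index=False)


def fixture_map_path():
    """Path to the bundled 30-entry fixture map."""
    return resources.files("ehrphewas.data").joinpath("phecode_map_fixture.csv")


def icd_to_phecodes(code: str, pmap: PhecodeMap) -> set[str]:
    """Map one ICD-9 code to its phecode (singleton set) or the empty set.

    Unmapped codes are not an error: a PheWAS simply ignores them.
    """
    entry = pmap.entry_for_icd9(code)
    return {entry.phecode} if entry is not None else set()


def is_descendant(child: str, parent: str) -> bool:
    """True iff ``child`` extends ``parent`` positionally (``401.22`` under ``401.2``)."""
    if child == parent or not child.startswith(parent):
        return False
    # "58" must not claim "585.1": without a decimal point in the parent,
    # the extension must start at the decimal point.
    return "." in parent or child[len(parent)] == "."


def related_phecodes(phecode: str, pmap: PhecodeMap) -> set[str]:
    """The phecode, its descendants, and every map phecode in its exclusion range.

    This is the "related diseases" set: subjects with any code mapping
    into it are ineligible as controls for ``phecode``.
    """
    entry = pmap.entry_for_phecode(phecode)  # KeyError if unknown
    related = {phecode}
    for other in pmap.phecodes:
        if is_descendant(other, phecode):
            related.add(other)
    if entry.exclusion_range is not None:
        lo, hi = entry.exclusion_range
        for other, value in pmap._phecode_values.items():
            if lo <= value <= hi:
                related.add(other)
    return related


def descendant_closure(phecode: str, pmap: PhecodeMap) -> set[str]:
    """The phecode plus its positional descendants (case-counting closure)."""
    return {phecode} | {p for p in pmap.phecodes if is_descendant(p, phecode)}
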