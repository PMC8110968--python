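"""Matrisome gene catalogue: loading, validation, and division queries.

The catalogue is the annotation that gates every gene-set-restricted
computation in the package: 281 mouse ECM genes split into basement-membrane
(BM) and interstitial divisions. Symbols are matched case-insensitively
(mouse symbols are mixed case and count tables are not always consistent),
with the catalogue's spelling kept as canonical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

BM = "BM"
INTERSTITIAL = "interstitial"
NON_MATRISOME = "non-matrisome"
DIVISIONS = (BM, INTERSTITIAL)


class CatalogueFormatError(ValueError):
    """Raised when a catalogue file is structurally malformed."""


class CatalogueValidationError(ValueError):
    """Raised when catalogue content violates an invariant."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One matrisome gene: symbol, division, optional free-text class."""

    symbol: str
    division: str
    category: str | None = None
    provenance: str = "transcribed"

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogueValidationError("gene symbol must be non-empty")
        if self.division not in DIVISIONS:
            raise CatalogueValidationError(
                f"unknown division {self.division!r} for {self.symbol!r}; "
                f"expected one of {DIVISIONS}"
            )


@dataclass
class MatrisomeCatalogue:
    """Validated collection of matrisome gene annotations."""

    entries: tuple[GeneAnnotation, ...]
    source: str = "unknown"
    _index: dict[str, GeneAnnotation] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        index: dict[str, GeneAnnotation] = {}
        for entry in self.entries:
            key = entry.symbol.casefold()
            if key in index:
                raise CatalogueValidationError(
                    f"duplicate gene symbol {entry.symbol!r} in catalogue"
                )
            index[key] = entry
        self._index = index

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GeneAnnotation]:
        return iter(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol.casefold() in self._index

    def lookup(self, symbol: str) -> GeneAnnotation | None:
        return self._index.get(symbol.casefold())

    def symbols(self, division: str | None = None) -> list[str]:
        """Canonical symbols, optionally restricted to one division."""
        if division is None:
            return [e.symbol for e in self.entries]
        if division not in DIVISIONS:
            raise ValueError(f"unknown division {division!r}")
        return [e.symbol for e in self.entries if e.division == division]


def load_catalogue(path: str | Path) -> MatrisomeCatalogue:
    """Load a catalogue TSV with columns ``symbol``, ``division``
    (``category`` and ``provenance`` optional).

    Raises :class:`CatalogueFormatError` for missing columns and
    :class:`CatalogueValidationError` for duplicate symbols or unknown
    division tokens.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        fields = reader.fieldnames or []
        missing = {"symbol", "division"} - set(fields)
        if missing:
            raise CatalogueFormatError(
                f"{path}: missing required column(s) {sorted(missing)}"
            )
        entries = []
        for row in reader:
            entries.append(
                GeneAnnotation(
                    symbol=(row["symbol"] or "").strip(),
                    division=(row["division"] or "").strip(),
                    category=(row.get("category") or "").strip() or None,
                    provenance=(row.get("provenance") or "").strip() or "transcribed",
                )
            )
    return MatrisomeCatalogue(entries=tuple(entries), source=str(path))


def write_catalogue(catalogue: MatrisomeCatalogue, path: str | Path) -> None:
    """Write the catalogue back to TSV (round-trips with :func:`load_catalogue`)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        handle.write("symbol\tdivision\tcategory\tprovenance\n")
        for e in catalogue.entries:
            handle.write(f"{e.symbol}\t{e.division}\t{e.category or ''}\t{e.provenance}\n")


def load_default_catalogue() -> MatrisomeCatalogue:
    """Load the packaged 281-gene mouse matrisome catalogue.

    The packaged list transcribes literature-standard mouse matrisome symbols;
    rows whose ``provenance`` column reads ``placeholder`` are synthetic
    padding that preserves the 67 BM / 214 interstitial division totals.
    """
    ref = resources.files("ecmatlas").joinpath("data/matrisome_mouse.tsv")
    with resources.as_file(ref) as path:
        catalogue = load_catalogue(path)
    catalogue.source = "packaged:matrisome_mouse.tsv"
    return catalogue


def classify_symbol(catalogue: MatrisomeCatalogue, symbol: str) -> str:
    """Return ``BM``, ``interstitial``, or ``non-matrisome`` for a symbol.

    Absence from the catalogue is a valid outcome, not an error.
    """
    entry = catalogue.lookup(symbol)
    return entry.division if entry is not None else NON_MATRISOME


def partition_counts(catalogue: MatrisomeCatalogue) -> Mapping[str, int]:
    """Count catalogue entries per division; counts sum to ``len(catalogue)``."""
    counts = {division: 0 for division in DIVISIONS}
    for entry in catalogue.entries:
        counts[entry.division] += 1
    return counts


def intersect_symbols(catalogue: MatrisomeCatalogue, symbols: Iterable[str],
                      division: str | None = None) -> list[str]:
    """Subset of ``symbols`` present in the catalogue (optionally one division),
    preserving the input order and spelling."""
    out = []
    for s in symbols:
        entry = catalogue.lookup(s)
        if entry is not None and (division is None or entry.division == division):
            out.append(s)
    return out
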