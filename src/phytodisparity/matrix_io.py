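"""Discrete morphological character matrices.

A :class:`CharacterMatrix` holds taxa x characters cells where every cell is
an integer state code (0-9), missing (``?``) or inapplicable (``-``).
Missing means *unknown but potentially scorable*; inapplicable means the
character cannot logically be scored for that taxon (e.g. petal colour in a
moss).  The distinction matters downstream: Gower dissimilarity drops both
from the comparable set, while presence/absence recoding treats an
inapplicable organ as absent.

Characters may belong to named, possibly overlapping categories
(``partitions``), e.g. sporophytic vs gametophytic trait sets, used for
subsetting the morphospace.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("phytodisparity")

#: Cell sentinel for an unknown state ("?").
MISSING: int = -1
#: Cell sentinel for a logically unscorable character ("-").
INAPPLICABLE: int = -2

_SYMBOL_TO_CODE = {"?": MISSING, "-": INAPPLICABLE}
_CODE_TO_SYMBOL = {MISSING: "?", INAPPLICABLE: "-"}

_POLY_RE = re.compile(r"^[\{\(\[].*[\}\)\]]$")


class MatrixParseError(ValueError):
    """Raised when a character-matrix file violates the format contract."""


def _cell_from_symbol(sym: str, taxon: str, char: str) -> tuple[int, bool]:
    """Map one cell token to an internal code.

    Returns ``(code, was_polymorphic)``.  Polymorphic/ambiguous tokens such
    as ``{01}`` collapse to MISSING (the source analyses never score them).
    """
    sym = sym.strip()
    if sym in _SYMBOL_TO_CODE:
        return _SYMBOL_TO_CODE[sym], False
    if _POLY_RE.match(sym) or len(sym) > 1:
        return MISSING, True
    if sym.isdigit():
        return int(sym), False
    raise MatrixParseError(
        f"undeclared symbol {sym!r} for taxon {taxon!r}, character {char!r}"
    )


@dataclass
class CharacterMatrix:
    """Taxa x discrete characters with missing/inapplicable codes.

    Parameters
    ----------
    taxa
        Ordered unique taxon labels (rows).
    characters
        Ordered character identifiers (columns).
    cells
        ``(len(taxa), len(characters))`` int array; entries are state codes
        ``0..9``, :data:`MISSING` or :data:`INAPPLICABLE`.
    partitions
        Named, possibly overlapping character-id sets.
    ordered_flags
        Per-character ordered flag; all analyses here treat characters as
        unordered, the flag is carried for provenance only.
    """

    taxa: list[str]
    characters: list[str]
    cells: np.ndarray
    partitions: dict[str, list[str]] = field(default_factory=dict)
    ordered_flags: list[bool] | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int16)
        if self.ordered_flags is None:
            self.ordered_flags = [False] * len(self.characters)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise MatrixParseError(f"duplicate taxon labels: {dupes}")
        if self.cells.shape != (len(self.taxa), len(self.characters)):
            raise MatrixParseError(
                f"cell block shape {self.cells.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.characters)} characters"
            )
        bad = (self.cells > 9) | (
            (self.cells < 0) & (self.cells != MISSING) & (self.cells != INAPPLICABLE)
        )
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise MatrixParseError(
                f"invalid state code {self.cells[i, j]} at taxon "
                f"{self.taxa[i]!r}, character {self.characters[j]!r}"
            )
        known = set(self.characters)
        for name, members in self.partitions.items():
            unknown = [c for c in members if c not in known]
            if unknown:
                raise MatrixParseError(
                    f"partition {name!r} references unknown characters {unknown}"
                )

    # -- basic access -----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def taxon_index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in matrix") from None

    def row(self, taxon: str) -> np.ndarray:
        return self.cells[self.taxon_index(taxon)]

    def observed_states(self, char_index: int) -> np.ndarray:
        """Sorted distinct coded states of one character across all taxa."""
        col = self.cells[:, char_index]
        return np.unique(col[col >= 0])

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            list(self.taxa),
            list(self.characters),
            self.cells.copy(),
            {k: list(v) for k, v in self.partitions.items()},
            list(self.ordered_flags),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.cells, other.cells)
            and {k: sorted(v) for k, v in self.partitions.items()}
            == {k: sorted(v) for k, v in other.partitions.items()}
            and self.ordered_flags == other.ordered_flags
        )


@dataclass
class PresenceMatrix:
    """Binary presence/absence recode of a character matrix.

    Cells are 0 (absent), 1 (present) or :data:`MISSING`; taxon order matches
    the source :class:`CharacterMatrix`.
    """

    taxa: list[str]
    characters: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int16)
        ok = (self.cells == 0) | (self.cells == 1) | (self.cells == MISSING)
        if not ok.all():
            raise ValueError("PresenceMatrix cells must be 0, 1 or MISSING")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, format: str | None = None) -> CharacterMatrix:
    """Read a character matrix from NEXUS or CSV.

    ``-`` maps to inapplicable, ``?`` to missing; polymorphic cells such as
    ``{01}`` collapse to missing with a logged warning.  The format is
    inferred from the file suffix when not given.
    """
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".nxs"} else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "nexus":
        return _read_nexus(path)
    raise ValueError(f"unknown format {format!r}")


def write_matrix(m: CharacterMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a matrix as NEXUS (with a SETS block) or CSV (+ partition sidecar)."""
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in {".nex", ".nexus", ".nxs"} else "csv"
    if format == "csv":
        _write_csv(m, path)
    elif format == "nexus":
        _write_nexus(m, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> CharacterMatrix:
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    taxa = [str(t) for t in df.index]
    characters = [str(c) for c in df.columns]
    n_poly = 0
    cells = np.empty((len(taxa), len(characters)), dtype=np.int16)
    for i, taxon in enumerate(taxa):
        for j, char in enumerate(characters):
            code, poly = _cell_from_symbol(df.iat[i, j], taxon, char)
            n_poly += poly
            cells[i, j] = code
    if n_poly:
        logger.warning("%d polymorphic/ambiguous cells collapsed to MISSING", n_poly)
    partitions: dict[str, list[str]] = {}
    sidecar = path.with_suffix(path.suffix + ".charsets.json")
    if sidecar.exists():
        partitions = json.loads(sidecar.read_text())
    return CharacterMatrix(taxa, characters, cells, partitions)


def _write_csv(m: CharacterMatrix, path: Path) -> None:
    sym = np.empty(m.cells.shape, dtype=object)
    for code, s in _CODE_TO_SYMBOL.items():
        sym[m.cells == code] = s
    coded = m.cells >= 0
    sym[coded] = m.cells[coded].astype(str)
    pd.DataFrame(sym, index=m.taxa, columns=m.characters).to_csv(path, index_label="taxon")
    sidecar = path.with_suffix(path.suffix + ".charsets.json")
    if m.partitions:
        sidecar.write_text(json.dumps(m.partitions, indent=1, sort_keys=True))
    elif sidecar.exists():
        sidecar.unlink()


def _read_nexus(path: Path) -> CharacterMatrix:
    import dendropy

    try:
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises assorted error types
        raise MatrixParseError(f"NEXUS parse failure for {path}: {exc}") from exc
    taxa = [t.label for t in dmat.taxon_namespace]
    characters: list[str] | None = None
    rows = []
    n_poly = 0
    ncols = None
    for taxon in dmat.taxon_namespace:
        seq = dmat[taxon]
        if ncols is None:
            ncols = len(seq)
        elif len(seq) != ncols:
            raise MatrixParseError(
                f"ragged matrix: taxon {taxon.label!r} has {len(seq)} cells, expected {ncols}"
            )
        row = []
        for j, state in enumerate(seq):
            sym = str(state.symbol) if state.symbol is not None else str(state)
            code, poly = _cell_from_symbol(sym, taxon.label, str(j + 1))
            n_poly += poly
            row.append(code)
        rows.append(row)
    if n_poly:
        logger.warning("%d polymorphic/ambiguous cells collapsed to MISSING", n_poly)
    characters = [f"c{j + 1}" for j in range(ncols or 0)]
    partitions = _parse_charsets(path.read_text(), characters)
    return CharacterMatrix(taxa, characters, np.array(rows, dtype=np.int16), partitions)


_CHARSET_RE = re.compile(r"charset\s+(\S+?)\s*=\s*([^;]+);", re.IGNORECASE)


def _parse_charsets(text: str, characters: Sequence[str]) -> dict[str, list[str]]:
    """Extract CHARSET lines (1-based indices and ranges) from a SETS block."""
    partitions: dict[str, list[str]] = {}
    for name, body in _CHARSET_RE.findall(text):
        ids: list[str] = []
        for token in body.split():
            if "-" in token:
                lo, hi = token.split("-")
                ids.extend(characters[int(lo) - 1 : int(hi)])
            else:
                ids.append(characters[int(token) - 1])
        partitions[name.strip("'\"")] = ids
    return partitions


def _write_nexus(m: CharacterMatrix, path: Path) -> None:
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    width = max((len(t) for t in m.taxa), default=0) + 2
    for i, taxon in enumerate(m.taxa):
        cells = "".join(
            _CODE_TO_SYMBOL.get(int(c), str(int(c))) for c in m.cells[i]
        )
        safe = f"'{taxon}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", taxon) else taxon
        lines.append(f"    {safe:<{width}}{cells}")
    lines.append("    ;")
    lines.append("END;")
    if m.partitions:
        index = {c: j + 1 for j, c in enumerate(m.characters)}
        lines.append("BEGIN SETS;")
        for name in sorted(m.partitions):
            idx = " ".join(str(index[c]) for c in m.partitions[name])
            lines.append(f"    CHARSET {name} = {idx};")
        lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def subset_characters(m: CharacterMatrix, keep: Iterable[str]) -> CharacterMatrix:
    """Restrict to a character subset, preserving column order.

    Partitions are intersected with ``keep``; empty intersections are dropped.
    """
    keep_set = set(keep)
    if not keep_set:
        raise ValueError("keep must be a nonempty character-id set")
    unknown = keep_set - set(m.characters)
    if unknown:
        raise KeyError(f"unknown character ids: {sorted(unknown)}")
    idx = [j for j, c in enumerate(m.characters) if c in keep_set]
    partitions = {}
    for name, members in m.partitions.items():
        inter = [c for c in members if c in keep_set]
        if inter:
            partitions[name] = inter
    return CharacterMatrix(
        list(m.taxa),
        [m.characters[j] for j in idx],
        m.cells[:, idx].copy(),
        partitions,
        [m.ordered_flags[j] for j in idx],
    )


def subset_partition(m: CharacterMatrix, name: str) -> CharacterMatrix:
    """Restrict to the characters of one named category."""
    if name not in m.partitions:
        raise KeyError(f"no partition named {name!r}")
    return subset_characters(m, m.partitions[name])


def recode_presence(
    m: CharacterMatrix,
    recode_table: Mapping[str, Mapping[int, int | str]] | None = None,
) -> PresenceMatrix:
    """Recode multistate characters to presence/absence.

    ``recode_table`` maps character id -> {state -> 0, 1 or "drop"}.  A
    character mapped to "drop" (any of its states) is removed entirely.
    Characters absent from the table must already be binary and pass through
    with the identity map.  Inapplicable recodes to absent (0): an organ that
    cannot exist is not present.  Missing is preserved.
    """
    recode_table = recode_table or {}
    keep_idx: list[int] = []
    columns: list[np.ndarray] = []
    for j, char in enumerate(m.characters):
        col = m.cells[:, j]
        states = set(int(s) for s in np.unique(col[col >= 0]))
        table = recode_table.get(char)
        if table is None:
            if states - {0, 1}:
                raise ValueError(
                    f"character {char!r} has states {sorted(states)} but no recode map"
                )
            table = {0: 0, 1: 1}
        if any(v == "drop" for v in table.values()):
            continue
        unmapped = states - {int(s) for s in table}
        if unmapped:
            raise ValueError(
                f"character {char!r}: states {sorted(unmapped)} unmapped in recode table"
            )
        out = np.full(col.shape, MISSING, dtype=np.int16)
        out[col == INAPPLICABLE] = 0
        for state, value in table.items():
            out[col == int(state)] = int(value)
        keep_idx.append(j)
        columns.append(out)
    cells = (
        np.column_stack(columns) if columns else np.empty((m.n_taxa, 0), dtype=np.int16)
    )
    return PresenceMatrix(list(m.taxa), [m.characters[j] for j in keep_idx], cells)


def applicable_proportion(
    m: CharacterMatrix, taxon: str, include_missing: bool = False
) -> float:
    """Fraction of a taxon's scored characters that are applicable.

    By default missing cells are excluded from the denominator so that poorly
    known taxa are not penalised twice; ``include_missing=True`` counts them
    as scored-but-inapplicable-free denominators (missing treated as scorable).
    """
    row = m.row(taxon)
    n_applicable = int((row >= 0).sum())
    if include_missing:
        denom = len(row)
    else:
        denom = int((row != MISSING).sum())
    if denom == 0:
        return 0.0
    return n_applicable / denom
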