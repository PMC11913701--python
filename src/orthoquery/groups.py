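"""Ortholog-group tables: parse the upstream flat-file format, tidy it, query it.

Graph-based orthology inference tools emit one row per putative ortholog
group, with one column per species and each cell holding that species'
member protein id(s) — several ids separated by commas, an optional
``:score`` confidence suffix per id, and a placeholder token where a species
has no member. That wide, non-standard layout is reshaped here into a tidy
long table (one row per group member) that downstream stages can join
against proteome sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

COLUMNS = ["group_id", "species_code", "protein_id", "member_score"]


class GroupFormatError(ValueError):
    """Raised on malformed group flat files or invalid tables."""


class GroupNotFoundError(KeyError):
    """Raised when a group id is looked up but absent."""


@dataclass(frozen=True)
class Dialect:
    """Flat-file dialect: separators and placeholder token are configuration."""

    column_sep: str = "\t"
    member_sep: str = ","
    score_sep: str = ":"
    placeholder: str = "*"
    group_column: str = "group_id"


#: Registry of named dialects; ``default`` matches comma-joined members with
#: optional ``:score`` suffixes and ``*`` for species without a member.
DIALECTS: dict[str, Dialect] = {
    "default": Dialect(),
    "semicolon-members": Dialect(member_sep=";"),
}


def _get_dialect(dialect: str | Dialect) -> Dialect:
    if isinstance(dialect, Dialect):
        return dialect
    try:
        return DIALECTS[dialect]
    except KeyError:
        raise GroupFormatError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")


@dataclass
class OrthologGroupTable:
    """Tidy long-format mapping of group id -> member proteins.

    ``data`` has columns group_id, species_code, protein_id, member_score
    (float or NaN); ``species_roster`` preserves the column order of the
    source file so output ordering is deterministic.
    """

    data: pd.DataFrame
    species_roster: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        for col in ("group_id", "species_code", "protein_id"):
            self.data[col] = self.data[col].astype(str)
        if "member_score" not in self.data.columns:
            self.data["member_score"] = float("nan")
        if not self.species_roster:
            self.species_roster = list(dict.fromkeys(self.data["species_code"]))
        self.validate()

    def validate(self) -> None:
        df = self.data
        dup = df.duplicated(subset=["group_id", "species_code", "protein_id"])
        if dup.any():
            rows = df.loc[dup, ["group_id", "species_code", "protein_id"]]
            raise GroupFormatError(f"duplicate group members:\n{rows.to_string(index=False)}")
        # membership must partition proteins: one group per (species, protein)
        per_protein = df.groupby(["species_code", "protein_id"])["group_id"].nunique()
        clashes = per_protein[per_protein > 1]
        if not clashes.empty:
            raise GroupFormatError(
                "proteins assigned to multiple groups: "
                + ", ".join(f"{sp}|{pid}" for sp, pid in clashes.index))
        roster = set(self.species_roster)
        missing = set(df["species_code"]) - roster
        if missing:
            raise GroupFormatError(f"species {sorted(missing)} absent from roster")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def group_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["group_id"]))

    def cross_species_groups(self) -> set[str]:
        """Group ids whose members span at least two species."""
        n_sp = self.data.groupby("group_id")["species_code"].nunique()
        return set(n_sp[n_sp >= 2].index)

    def lookup_group(self, group_id: str) -> list[tuple[str, str]]:
        """All (species_code, protein_id) members of a group, roster-then-id order."""
        sub = self.data[self.data["group_id"] == str(group_id)]
        if sub.empty:
            raise GroupNotFoundError(f"group {group_id!r} not found")
        return sorted(
            zip(sub["species_code"], sub["protein_id"]),
            key=lambda t: (self._roster_rank(t[0]), t[1]))

    def group_of(self, species_code: str, protein_id: str) -> str | None:
        sub = self.data[(self.data["species_code"] == species_code)
                        & (self.data["protein_id"] == str(protein_id))]
        return None if sub.empty else sub["group_id"].iloc[0]

    def _roster_rank(self, species: str) -> int:
        try:
            return self.species_roster.index(species)
        except ValueError:
            return len(self.species_roster)

    def sorted_data(self) -> pd.DataFrame:
        df = self.data.copy()
        df["_rank"] = df["species_code"].map(self._roster_rank)
        df = df.sort_values(["group_id", "_rank", "protein_id"],
                            key=lambda s: s if s.name != "group_id" else _natural_key(s))
        return df.drop(columns="_rank").reset_index(drop=True)


def _natural_key(series: pd.Series) -> pd.Series:
    """Sort numeric-looking group ids numerically, others lexically after."""
    def key(v: str):
        return (0, int(v), "") if v.isdigit() else (1, 0, v)
    return series.map(key)


def _split_member(token: str, dialect: Dialect) -> tuple[str, float]:
    if dialect.score_sep in token:
        pid, _, score = token.rpartition(dialect.score_sep)
        try:
            return pid.strip(), float(score)
        except ValueError:
            pass  # score suffix not numeric: treat whole token as the id
    return token.strip(), float("nan")


def parse_group_file(path: str | Path, dialect: str | Dialect = "default") -> OrthologGroupTable:
    """Parse a wide one-row-per-group flat file into an :class:`OrthologGroupTable`.

    The first line names the columns: the group-id column followed by one
    column per species. Cells fan out to one tidy row per member protein;
    placeholder cells contribute no rows.
    """
    d = _get_dialect(dialect)
    path = Path(path)
    lines = path.read_text().splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise GroupFormatError(f"{path}: empty group file")
    header = lines[0].split(d.column_sep)
    if len(header) < 2:
        raise GroupFormatError(f"{path}: header row must name a group column and >=1 species")
    species_roster = [h.strip() for h in header[1:]]
    rows: list[tuple[str, str, str, float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(d.column_sep)
        if len(cells) != len(header):
            raise GroupFormatError(
                f"{path}: line {lineno}: {len(cells)} cells, expected {len(header)}")
        gid = cells[0].strip()
        for species, cell in zip(species_roster, cells[1:]):
            cell = cell.strip()
            if cell == d.placeholder or cell == "":
                continue
            for token in cell.split(d.member_sep):
                pid, score = _split_member(token, d)
                if pid:
                    rows.append((gid, species, pid, score))
    if not rows:
        raise GroupFormatError(f"{path}: no group members parsed")
    df = pd.DataFrame(rows, columns=COLUMNS)
    return OrthologGroupTable(df, species_roster=species_roster)


def write_group_table(table: OrthologGroupTable, path: str | Path) -> Path:
    """Write the tidy long-format TSV (deterministic row order; NaN scores blank)."""
    if len(table) == 0:
        raise GroupFormatError("refusing to write an empty group table")
    path = Path(path)
    df = table.sorted_data()
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def read_group_table(path: str | Path) -> OrthologGroupTable:
    """Read back the tidy long-format TSV written by :func:`write_group_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"group_id": str, "species_code": str,
                                            "protein_id": str})
    if df.empty:
        raise GroupFormatError(f"{path}: empty table")
    return OrthologGroupTable(df)


def from_rows(rows: Iterable[tuple[str, str, str]],
              species_roster: list[str] | None = None) -> OrthologGroupTable:
    """Build a table from (group_id, species_code, protein_id) triples."""
    df = pd.DataFrame(list(rows), columns=COLUMNS[:3])
    df["member_score"] = float("nan")
    return OrthologGroupTable(df, species_roster=species_roster or [])
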