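"""Semantic-type to semantic-group mapping.

UMLS semantic types (e.g. ``gngm`` = Gene or Genome, ``dsyn`` = Disease
or Syndrome) roll up into coarse semantic groups (GENE, DISO, LIVB, ...).
The co-occurrence features are defined over groups, so the mapping is a
first-class, editable configuration table rather than hard-coded logic.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

__all__ = ["load_semgroup_table", "default_semgroup_table", "groups_for"]


def _parse(lines) -> dict[str, str]:
    table: dict[str, str] = {}
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"bad semgroup line: {raw!r}")
        table[parts[0]] = parts[1]
    return table


def load_semgroup_table(path: str | Path) -> dict[str, str]:
    """Read a ``semtype group`` table from a plain-text file."""
    return _parse(Path(path).read_text().splitlines())


def default_semgroup_table() -> dict[str, str]:
    """The packaged default table (standard UMLS semantic-group release)."""
    text = resources.files("genetriage.data").joinpath("semgroups.txt").read_text()
    return _parse(text.splitlines())


def groups_for(semtypes, table: dict[str, str]) -> frozenset[str]:
    """Semantic groups for a set of semantic types; unknown types are skipped."""
    return frozenset(table[st] for st in semtypes if st in table)
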