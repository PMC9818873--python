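"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are TSV (first column gene id, remaining columns sample
ids, log-scale values); clinical tables are CSV keyed by ``sample_id``;
gene sets use the standard GMT format (set name, description, then genes,
tab separated).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
]

#: columns a clinical table may carry beyond the required three
CLINICAL_OPTIONAL = ("age", "gender", "tnm_stage", "cohort", "response")


@dataclass
class GeneSetCollection:
    """Ordered, named gene lists (e.g. the 28 immune-cell metagene sets).

    Set names are unique, no set is empty, and genes within a set are
    unique (first occurrence wins on duplicates).
    """

    sets: "OrderedDict[str, list[str]]"
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: "OrderedDict[str, list[str]]" = OrderedDict()
        for name, genes in self.sets.items():
            if name in clean:
                raise ValueError(f"duplicate gene-set name: {name!r}")
            deduped = list(dict.fromkeys(genes))
            if not deduped:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = deduped
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are dropped keeping the first occurrence.
    Raises ``ValueError`` on lines with fewer than three fields or on a
    duplicated set name.
    """
    path = Path(path)
    sets: "OrderedDict[str, list[str]]" = OrderedDict()
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (name, description, >=1 gene)"
                )
            name, description = fields[0], fields[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = description
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Load a genes x samples TSV. Gene and sample ids must be unique."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    _validate_expression(df, source=str(path))
    return df


def _validate_expression(df: pd.DataFrame, source: str = "expression") -> None:
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise ValueError(f"{source}: need at least 2 genes and 1 sample, got {df.shape}")
    if df.index.has_duplicates:
        raise ValueError(f"{source}: duplicate gene ids")
    if df.columns.has_duplicates:
        raise ValueError(f"{source}: duplicate sample ids")
    if df.isna().any().any():
        raise ValueError(f"{source}: missing values in expression matrix")


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Load a clinical/survival CSV indexed by ``sample_id``.

    Requires ``time_months`` (positive, finite) and ``event`` (0/1);
    carries through any of the optional columns present.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table must have a 'sample_id' column")
    df = df.set_index("sample_id")
    validate_clinical(df, source=str(path))
    return df


def validate_clinical(df: pd.DataFrame, source: str = "clinical") -> None:
    for col in ("time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"{source}: missing required column {col!r}")
    if df.index.has_duplicates:
        raise ValueError(f"{source}: duplicate sample ids")
    times = df["time_months"]
    if not ((times > 0) & times.notna() & (times < float("inf"))).all():
        raise ValueError(f"{source}: times must be positive and finite")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{source}: event must be 0/1")


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index_label="sample_id")
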