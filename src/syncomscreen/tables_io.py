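"""Tabular input/output for fermentation screening data.

Three tab-separated tables describe one experiment: a genus-level abundance
table (taxa x samples, with a kingdom annotation), a compound table
(compounds x samples, with a compound-class annotation), and sample metadata
(group, fermentation day, replicate).  All three must share exactly one
sample universe; loading harmonizes sample order to the metadata order.

Relative abundances are stored internally as proportions in [0, 1]; the
conventional "0.1 %" abundance threshold is therefore 0.001 on this scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KINGDOMS = frozenset({"bacteria", "fungi"})
COMPOUND_CLASSES = frozenset(
    {
        "ester",
        "acid",
        "alcohol",
        "aldehyde",
        "phenol",
        "amino_acid",
        "organic_acid",
        "physicochemical",
    }
)

#: compound classes counted as "acid" when screening for flavor producers
ACID_CLASSES = frozenset({"acid", "organic_acid"})


class DataValidationError(ValueError):
    """Input data violate a structural contract (exit code 3 at the CLI)."""


class ConfigError(ValueError):
    """Bad configuration (exit code 2 at the CLI)."""


class NumericError(RuntimeError):
    """A numeric procedure failed (exit code 4 at the CLI)."""


@dataclass
class SampleMetadata:
    """Per-sample design information.

    ``frame`` is indexed by sample id and carries ``group`` (str),
    ``day`` (int >= 0) and ``replicate`` (int >= 1) columns.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "day", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise DataValidationError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample ids: {dup}")
        frame = self.frame.copy()
        frame["day"] = frame["day"].astype(int)
        frame["replicate"] = frame["replicate"].astype(int)
        if (frame["day"] < 0).any():
            raise DataValidationError("negative fermentation day in metadata")
        if (frame["replicate"] < 1).any():
            raise DataValidationError("replicate numbers must be >= 1")
        triples = frame[["group", "day", "replicate"]]
        if triples.duplicated().any():
            bad = triples[triples.duplicated()].iloc[0].tolist()
            raise DataValidationError(f"duplicated (group, day, replicate) triple: {bad}")
        self.frame = frame

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class AbundanceTable:
    """Taxa x samples matrix of non-negative (relative) abundances.

    ``data`` is indexed by taxon name with sample-id columns; ``kingdom``
    maps each taxon to ``bacteria`` or ``fungi``.
    """

    data: pd.DataFrame
    kingdom: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise DataValidationError(f"duplicated taxon names: {dup}")
        if not self.kingdom.index.equals(self.data.index):
            self.kingdom = self.kingdom.reindex(self.data.index)
        unknown = set(self.kingdom.dropna()) - KINGDOMS
        if unknown or self.kingdom.isna().any():
            raise DataValidationError(
                f"unknown kingdom labels: {sorted(unknown) or 'missing entries'}"
            )
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            t, s = np.argwhere(values < 0)[0]
            raise DataValidationError(
                f"negative abundance at taxon {self.data.index[t]!r}, "
                f"sample {self.data.columns[s]!r}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def is_normalized(self, tol: float = 1e-9) -> bool:
        sums = self.data.sum(axis=0).to_numpy()
        return bool(np.all(np.abs(sums - 1.0) <= tol))

    def subset_kingdom(self, kingdom: str) -> "AbundanceTable":
        if kingdom not in KINGDOMS:
            raise ConfigError(f"unknown kingdom {kingdom!r}")
        keep = self.kingdom[self.kingdom == kingdom].index
        return AbundanceTable(self.data.loc[keep].copy(), self.kingdom.loc[keep].copy())

    def subset_samples(self, samples: list[str]) -> "AbundanceTable":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise DataValidationError(f"samples not in table: {missing}")
        return AbundanceTable(self.data[samples].copy(), self.kingdom.copy())


@dataclass
class CompoundTable:
    """Compounds x samples matrix of concentrations (arbitrary units)."""

    data: pd.DataFrame
    compound_class: pd.Series

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise DataValidationError(f"duplicated compound names: {dup}")
        if not self.compound_class.index.equals(self.data.index):
            self.compound_class = self.compound_class.reindex(self.data.index)
        unknown = set(self.compound_class.dropna()) - COMPOUND_CLASSES
        if unknown or self.compound_class.isna().any():
            raise DataValidationError(
                f"unknown compound_class labels: {sorted(unknown) or 'missing entries'}"
            )

    @property
    def compounds(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)


def _read_annotated_matrix(
    path: str | Path, annotation: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Read a TSV whose first column is the row key and second the annotation."""
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"input file not found: {path}")
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if annotation not in raw.columns:
        raise DataValidationError(f"{path}: missing annotation column {annotation!r}")
    labels = raw[annotation]
    body = raw.drop(columns=[annotation])
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"{path}: non-numeric cell at row {body.index[r]!r}, "
            f"column {body.columns[c]!r}: {body.iat[r, c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise DataValidationError(
            f"{path}: missing value at row {body.index[r]!r}, column {body.columns[c]!r}"
        )
    return numeric.astype(float), labels


def read_metadata(path: str | Path) -> SampleMetadata:
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(frame)


def read_abundance(path: str | Path) -> AbundanceTable:
    data, kingdom = _read_annotated_matrix(path, "kingdom")
    return AbundanceTable(data, kingdom.rename("kingdom"))


def read_compounds(path: str | Path) -> CompoundTable:
    data, cls = _read_annotated_matrix(path, "compound_class")
    return CompoundTable(data, cls.rename("compound_class"))


def _check_sample_universe(name: str, samples: list[str], meta: SampleMetadata) -> None:
    got, want = set(samples), set(meta.samples)
    if got != want:
        only_table = sorted(got - want)
        only_meta = sorted(want - got)
        raise DataValidationError(
            f"sample sets differ between {name} table and metadata; "
            f"only in {name}: {only_table}; only in metadata: {only_meta}"
        )


def load_dataset(
    abundance_path: str | Path,
    compound_path: str | Path,
    metadata_path: str | Path,
) -> tuple[AbundanceTable, CompoundTable, SampleMetadata]:
    """Load and cross-validate the three input tables.

    Sample order of both matrices is harmonized to the metadata order.
    """
    meta = read_metadata(metadata_path)
    abund = read_abundance(abundance_path)
    comp = read_compounds(compound_path)
    _check_sample_universe("abundance", abund.samples, meta)
    _check_sample_universe("compound", comp.samples, meta)
    order = meta.samples
    abund = AbundanceTable(abund.data[order], abund.kingdom)
    comp = CompoundTable(comp.data[order], comp.compound_class)
    return abund, comp, meta


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample column to proportions summing to one.

    Idempotent and scale-invariant; zero entries stay zero.  An all-zero
    sample column has no defined composition and is a fatal error.
    """
    sums = table.data.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise DataValidationError(f"all-zero sample column(s): {list(zero.index)}")
    return AbundanceTable(table.data.div(sums, axis=1), table.kingdom.copy())


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.frame.rename_axis("sample_id").to_csv(path, sep="\t")


def write_abundance(table: AbundanceTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "kingdom", table.kingdom)
    out.rename_axis("taxon").to_csv(path, sep="\t")


def write_compounds(table: CompoundTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "compound_class", table.compound_class)
    out.rename_axis("compound").to_csv(path, sep="\t")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
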