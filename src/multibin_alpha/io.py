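"""Reading and writing clonotype count tables and sample metadata.

Inputs are post-processed clonotype count tables (immunoSEQ-style exports or
the AIRR rearrangement schema subset): tab-separated, one row per unique
V-gene / CDR3 amino-acid / J-gene combination with a read or template count.
A clonotype is identified by the exact string triple; no allele collapsing or
CDR3 normalisation is performed, since any collapsing would change richness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Clonotype",
    "Repertoire",
    "CohortTable",
    "DEFAULT_COLUMNS",
    "AIRR_COLUMNS",
    "read_repertoire_table",
    "write_repertoire_table",
    "read_cohort_table",
    "library_size",
]

#: Logical field -> default column name in package-native TSV files.
DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "v_gene": "v_gene",
    "cdr3_aa": "cdr3_aa",
    "j_gene": "j_gene",
    "count": "count",
}

#: Column map for AIRR rearrangement exports.
AIRR_COLUMNS = {
    "sample_id": "repertoire_id",
    "v_gene": "v_call",
    "cdr3_aa": "junction_aa",
    "j_gene": "j_call",
    "count": "duplicate_count",
}


@dataclass(frozen=True, slots=True)
class Clonotype:
    """A unique V gene / CDR3 amino-acid sequence / J gene combination."""

    v_gene: str
    cdr3_aa: str
    j_gene: str

    def __post_init__(self):
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")


class Repertoire:
    """One sample's clonotype -> count map.

    Counts are strictly positive integers; zero-count clonotypes are never
    stored.  The library size ``L_i`` is the sum of all counts.
    """

    __slots__ = ("sample_id", "counts", "_library_size")

    def __init__(self, sample_id: str, counts: Mapping[Clonotype, int]):
        if not counts:
            raise ValueError(f"repertoire {sample_id!r} has no clonotypes")
        clean: dict[Clonotype, int] = {}
        for ct, c in counts.items():
            ci = int(c)
            if ci != c or ci < 1:
                raise ValueError(
                    f"count for {ct} in sample {sample_id!r} must be a positive "
                    f"integer, got {c!r}"
                )
            clean[ct] = ci
        self.sample_id = str(sample_id)
        self.counts = clean
        self._library_size = sum(clean.values())

    @property
    def library_size(self) -> int:
        return self._library_size

    def abundance(self) -> np.ndarray:
        """Counts as an integer vector (one entry per clonotype)."""
        return np.fromiter(self.counts.values(), dtype=np.int64, count=len(self.counts))

    def n_clonotypes(self) -> int:
        return len(self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Repertoire)
            and self.sample_id == other.sample_id
            and self.counts == other.counts
        )

    def __repr__(self) -> str:
        return (
            f"Repertoire({self.sample_id!r}, {len(self.counts)} clonotypes, "
            f"L={self._library_size})"
        )


def library_size(rep: Repertoire) -> int:
    """Total read/template count of a sample (``L_i``)."""
    return rep.library_size


@dataclass
class CohortTable:
    """Sample metadata aligned to repertoires.

    Wraps a DataFrame indexed by unique ``sample_id`` with a ``library_size``
    column plus arbitrary phenotype/covariate columns (numeric or two-level
    categorical).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.df
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ValueError("cohort table needs a 'sample_id' column or index")
            df = df.set_index("sample_id")
        if not df.index.is_unique:
            dup = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_id values: {dup}")
        self.df = df

    @classmethod
    def from_repertoires(cls, reps, metadata: pd.DataFrame | None = None) -> "CohortTable":
        """Build a table from repertoires, optionally joining covariates."""
        ids = [r.sample_id for r in reps]
        tab = pd.DataFrame(
            {"library_size": [r.library_size for r in reps]},
            index=pd.Index(ids, name="sample_id"),
        )
        if metadata is not None:
            meta = cls(metadata).df
            tab = tab.join(meta.drop(columns=["library_size"], errors="ignore"))
        return cls(tab)

    def attach_library_sizes(self, reps) -> "CohortTable":
        """Fill/validate library_size against repertoire sums (must match)."""
        sizes = pd.Series(
            {r.sample_id: r.library_size for r in reps}, name="library_size"
        )
        df = self.df.copy()
        if "library_size" in df.columns:
            common = df.index.intersection(sizes.index)
            mismatch = df.loc[common, "library_size"] != sizes.loc[common]
            if mismatch.any():
                bad = common[mismatch].tolist()
                raise ValueError(f"library_size mismatch with repertoires: {bad}")
        df["library_size"] = sizes.reindex(df.index).fillna(
            df.get("library_size", np.nan)
        )
        return CohortTable(df.reset_index())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def library_sizes(self) -> pd.Series:
        if "library_size" not in self.df.columns:
            raise KeyError("cohort table has no library_size column")
        return self.df["library_size"]

    def covariate(self, name: str) -> pd.Series:
        """Return a covariate as numeric; two-level categoricals become 0/1."""
        if name not in self.df.columns:
            raise KeyError(f"covariate {name!r} not in cohort table")
        col = self.df[name]
        if pd.api.types.is_numeric_dtype(col):
            return col.astype(float)
        levels = sorted(col.dropna().unique().tolist())
        if len(levels) != 2:
            raise ValueError(
                f"covariate {name!r} is non-numeric with {len(levels)} levels; "
                "only two-level categoricals are supported"
            )
        return col.map({levels[0]: 0.0, levels[1]: 1.0})


def _resolve_columns(column_map: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ValueError(f"unknown logical column(s) in column_map: {sorted(unknown)}")
        cols.update(column_map)
    return cols


def read_repertoire_table(path, column_map: Mapping[str, str] | None = None) -> list[Repertoire]:
    """Read a TSV clonotype count table into one Repertoire per sample.

    Rows sharing the same (sample, V, CDR3aa, J) are aggregated by summing
    counts (exports commonly split such rows by nucleotide sequence).  The
    returned list is sorted by sample id, so input row order is irrelevant.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header row.
    column_map : mapping, optional
        Logical name -> file column name; see :data:`AIRR_COLUMNS` for the
        AIRR rearrangement preset.
    """
    cols = _resolve_columns(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for logical, col in cols.items():
        if col not in df.columns:
            raise ValueError(
                f"missing required column {col!r} (for field {logical!r}) in {path}"
            )
    counts = pd.to_numeric(df[cols["count"]], errors="coerce")
    bad = counts.isna() | (counts != counts.round()) | (counts < 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"count column {cols['count']!r} must hold positive integers; "
            f"bad value {df[cols['count']].iloc[row]!r} at data row {row + 1}"
        )
    work = pd.DataFrame(
        {
            "sample": df[cols["sample_id"]],
            "v": df[cols["v_gene"]],
            "cdr3": df[cols["cdr3_aa"]],
            "j": df[cols["j_gene"]],
            "n": counts.astype(np.int64),
        }
    )
    agg = work.groupby(["sample", "v", "cdr3", "j"], sort=True)["n"].sum()
    reps = []
    for sid, grp in agg.groupby(level="sample", sort=True):
        cmap = {
            Clonotype(v, c, j): int(n)
            for (_, v, c, j), n in grp.items()
        }
        reps.append(Repertoire(sid, cmap))
    return reps


def write_repertoire_table(reps, path) -> None:
    """Write repertoires to TSV so that a read round-trips exactly."""
    reps = list(reps)
    if not reps:
        raise ValueError("cannot write an empty repertoire list")
    rows = []
    for rep in sorted(reps, key=lambda r: r.sample_id):
        for ct in sorted(rep.counts, key=lambda c: (c.v_gene, c.cdr3_aa, c.j_gene)):
            rows.append((rep.sample_id, ct.v_gene, ct.cdr3_aa, ct.j_gene, rep.counts[ct]))
    out = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values()))
    out.to_csv(path, sep="\t", index=False)


def read_cohort_table(path) -> CohortTable:
    """Read a sample-metadata TSV (sample_id plus covariate columns)."""
    return CohortTable(pd.read_csv(path, sep="\t"))
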