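"""Core data model and TSV readers/writers.

The central container is :class:`AbundanceTable`: a samples x taxa matrix of
non-negative abundances with per-taxon kingdom (``bacteria`` / ``fungi``) and
taxonomic-rank annotations.  Abundances are stored as raw counts or as
fractions in [0, 1]; percentages exist only at the display layer.
Normalisation is total-sum scaling *per kingdom* by default: bacterial and
fungal fractions each sum to 1 within a sample, because both profiles derive
from one metagenome but are reported as kingdom-specific relative abundances.
A joint-normalisation mode is available.

All tabular I/O is plain UTF-8 TSV with "." decimals and no thousands
separators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KINGDOMS = ("bacteria", "fungi")
RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: reserved (non-sample) columns in abundance TSV files
RESERVED_COLUMNS = ("kingdom", "rank")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class AbundanceTable:
    """Samples x taxa abundance matrix with kingdom/rank annotations.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by sample id, columns by taxon id, non-negative floats.
    kingdom : pandas.Series
        Maps taxon id -> ``"bacteria"`` or ``"fungi"``.
    rank : pandas.Series
        Maps taxon id -> taxonomic rank (one of :data:`RANKS`).
    normalized : bool
        True once total-sum scaling has been applied (see
        :func:`to_relative_abundance`).
    norm_mode : str
        ``"per_kingdom"`` or ``"joint"``; meaningful only when normalized.
    """

    data: pd.DataFrame
    kingdom: pd.Series
    rank: pd.Series
    normalized: bool = False
    norm_mode: str = "per_kingdom"

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.kingdom = self.kingdom.reindex(self.data.columns)
        self.rank = self.rank.reindex(self.data.columns)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        _check_unique(self.data.index, "sample")
        _check_unique(self.data.columns, "taxon")
        if self.data.isna().any().any():
            bad = [(s, t) for s, t in zip(*np.where(self.data.isna().values))]
            s, t = bad[0]
            raise DataValidationError(
                f"missing value at sample {self.data.index[s]!r}, "
                f"taxon {self.data.columns[t]!r}"
            )
        vals = self.data.values
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise DataValidationError(
                f"negative abundance {vals[i, j]} at sample "
                f"{self.data.index[i]!r}, taxon {self.data.columns[j]!r}"
            )
        bad_k = set(self.kingdom.dropna()) - set(KINGDOMS)
        if bad_k or self.kingdom.isna().any():
            raise DataValidationError(
                f"kingdom labels must be one of {KINGDOMS}; offending: "
                f"{sorted(map(str, bad_k)) or 'missing labels'}"
            )
        bad_r = set(self.rank.dropna()) - set(RANKS)
        if bad_r or self.rank.isna().any():
            raise DataValidationError(
                f"rank labels must be one of {RANKS}; offending: "
                f"{sorted(map(str, bad_r)) or 'missing labels'}"
            )
        if self.normalized:
            for k in KINGDOMS:
                cols = self.taxa_of(k)
                if len(cols) == 0:
                    continue
                sums = self.data[cols].sum(axis=1).values
                if self.norm_mode == "per_kingdom" and (sums > 1 + 1e-9).any():
                    raise DataValidationError(
                        f"per-sample {k} fractions sum above 1"
                    )
            if self.norm_mode == "joint":
                if (self.data.sum(axis=1).values > 1 + 1e-9).any():
                    raise DataValidationError("per-sample fractions sum above 1")

    # -- convenience ----------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def taxa_of(self, kingdom: str) -> list:
        if kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {kingdom!r}")
        return [t for t in self.data.columns if self.kingdom[t] == kingdom]

    def subset(self, samples=None, taxa=None) -> "AbundanceTable":
        """Return a new table restricted to the given samples and/or taxa."""
        data = self.data
        if samples is not None:
            missing = [s for s in samples if s not in data.index]
            if missing:
                raise KeyError(f"unknown sample ids: {missing}")
            data = data.loc[list(samples)]
        if taxa is not None:
            missing = [t for t in taxa if t not in data.columns]
            if missing:
                raise KeyError(f"unknown taxon ids: {missing}")
            data = data[list(taxa)]
        return AbundanceTable(
            data.copy(),
            self.kingdom.reindex(data.columns),
            self.rank.reindex(data.columns),
            normalized=self.normalized,
            norm_mode=self.norm_mode,
        )

    def copy(self) -> "AbundanceTable":
        return dataclasses.replace(self, data=self.data.copy())


@dataclass
class SampleMetadata:
    """Per-sample clinical metadata: group label plus IgE covariates.

    ``frame`` is indexed by sample id with columns ``group`` (e.g. ARFC / HC),
    ``age``, ``sex`` (M/F), ``height_cm``, ``weight_kg``, ``total_ige``
    (IU/mL) and any number of allergen-specific IgE columns prefixed
    ``sIgE_`` (kU_A/L).  Sensitization is called at >= 0.35 kU_A/L.
    """

    frame: pd.DataFrame
    sensitization_threshold: float = 0.35

    def __post_init__(self) -> None:
        _check_unique(self.frame.index, "sample")
        if "group" not in self.frame.columns:
            raise DataValidationError("metadata requires a 'group' column")
        if "total_ige" in self.frame.columns:
            tot = pd.to_numeric(self.frame["total_ige"])
            if (tot.dropna() < 0).any():
                raise DataValidationError("total_ige must be >= 0")
        for c in self.specific_ige_columns:
            v = pd.to_numeric(self.frame[c])
            if (v.dropna() < 0).any():
                raise DataValidationError(f"{c} must be >= 0")

    @property
    def sample_ids(self) -> list:
        return list(self.frame.index)

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    @property
    def groups(self) -> list:
        return sorted(self.frame["group"].unique())

    @property
    def total_ige(self) -> pd.Series:
        return self.frame["total_ige"]

    @property
    def specific_ige_columns(self) -> list:
        return [c for c in self.frame.columns if c.startswith("sIgE_")]

    @property
    def specific_ige(self) -> pd.DataFrame:
        """Allergen-specific IgE (kU_A/L), columns named by allergen."""
        sub = self.frame[self.specific_ige_columns]
        return sub.rename(columns=lambda c: c[len("sIgE_"):])

    def samples_in(self, group: str) -> list:
        if group not in set(self.frame["group"]):
            raise KeyError(f"unknown group label {group!r}")
        return list(self.frame.index[self.frame["group"] == group])

    def sensitized(self, allergen: str) -> pd.Series:
        col = f"sIgE_{allergen}"
        if col not in self.frame.columns:
            raise KeyError(f"no specific IgE column for allergen {allergen!r}")
        return self.frame[col] >= self.sensitization_threshold


@dataclass
class DistanceMatrix:
    """Symmetric, hollow, non-negative sample-by-sample distance matrix."""

    sample_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (n, n):
            raise DataValidationError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} sample ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise DataValidationError("distance matrix is not symmetric")
        if not (np.diag(self.values) == 0).all():
            raise DataValidationError("distance matrix diagonal must be 0")
        if (self.values < 0).any():
            raise DataValidationError("distances must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PipelineConfig:
    """Thresholds and sizes shared across the analysis stages.

    Defaults follow the study design this pipeline models: correlation-network
    edges require |rho| >= 0.6 and BH-adjusted q < 0.05; PERMANOVA and
    Procrustes use 9999 permutations; biomarkers require |LDA score| >= 2;
    pathway calls require |ReporterScore| > 1.5; the random forest uses
    10-fold cross-validation.  A prevalence floor of 0.25 is applied before
    network inference (0 disables it).
    """

    rho_min: float = 0.6
    q_alpha: float = 0.05
    n_perm: int = 9999
    lda_min: float = 2.0
    reporter_threshold: float = 1.5
    prevalence_min: float = 0.25
    rf_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rho_min <= 1):
            raise ValueError("rho_min must be in (0, 1]")
        if not (0 < self.q_alpha < 1):
            raise ValueError("q_alpha must be in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        for name in ("lda_min", "reporter_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.prevalence_min <= 1):
            raise ValueError("prevalence_min must be in [0, 1]")
        if self.rf_folds < 2:
            raise ValueError("rf_folds must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_strict(path) -> list[list[str]]:
    """Read a TSV into rows of fields, rejecting ragged rows."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise DataValidationError(f"{path}: empty file")
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise DataValidationError(
                f"{path}: ragged row {i + 1} has {len(r)} fields, expected {width}"
            )
    return rows


def read_abundance_tsv(path, kingdom: str | None = None,
                       default_rank: str = "genus",
                       normalized: bool | str = "auto") -> AbundanceTable:
    """Read an abundance TSV (rows = taxa, columns = samples).

    The first column holds taxon ids; optional reserved columns ``kingdom``
    and ``rank`` annotate each taxon.  When the file carries no kingdom
    column, ``kingdom`` must be supplied (single-kingdom file).

    ``normalized="auto"`` marks the table as already total-sum scaled when
    every per-kingdom sample total is <= 1 (fraction tables round-trip
    without an explicit flag; count tables sum well above 1).
    """
    rows = _read_tsv_strict(path)
    header = rows[0]
    cols = header[1:]
    has_kingdom = "kingdom" in cols
    has_rank = "rank" in cols
    sample_cols = [c for c in cols if c not in RESERVED_COLUMNS]
    _check_unique(sample_cols, "sample")
    if not has_kingdom and kingdom is None:
        raise DataValidationError(
            f"{path}: no 'kingdom' column and no kingdom argument given"
        )

    taxa, kingdoms, ranks, values = [], [], [], []
    for r in rows[1:]:
        rec = dict(zip(cols, r[1:]))
        taxa.append(r[0])
        kingdoms.append(rec["kingdom"] if has_kingdom else kingdom)
        ranks.append(rec["rank"] if has_rank else default_rank)
        row_vals = []
        for c in sample_cols:
            try:
                v = float(rec[c])
            except ValueError as exc:
                raise DataValidationError(
                    f"{path}: non-numeric value {rec[c]!r} at taxon {r[0]!r}, "
                    f"sample {c!r}"
                ) from exc
            if v < 0:
                raise DataValidationError(
                    f"{path}: negative value {v} at taxon {r[0]!r}, sample {c!r}"
                )
            row_vals.append(v)
        values.append(row_vals)
    _check_unique(taxa, "taxon")

    data = pd.DataFrame(values, index=taxa, columns=sample_cols).T
    king = pd.Series(kingdoms, index=taxa)
    if normalized == "auto":
        normalized = all(
            data[[t for t in taxa if king[t] == k]].sum(axis=1).max() <= 1 + 1e-9
            for k in KINGDOMS
            if any(king[t] == k for t in taxa)
        )
    return AbundanceTable(
        data,
        kingdom=king,
        rank=pd.Series(ranks, index=taxa),
        normalized=bool(normalized),
    )


def write_abundance_tsv(table: AbundanceTable, path) -> None:
    """Write an AbundanceTable (taxa as rows) losslessly at 12 sig. digits."""
    out = table.data.T
    df = pd.DataFrame(index=out.index)
    df["kingdom"] = table.kingdom.reindex(out.index)
    df["rank"] = table.rank.reindex(out.index)
    df = pd.concat([df, out], axis=1)
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_metadata_tsv(path, sensitization_threshold: float = 0.35) -> SampleMetadata:
    """Read sample metadata keyed by ``sample_id``."""
    rows = _read_tsv_strict(path)
    header = rows[0]
    if header[0] != "sample_id":
        raise DataValidationError(f"{path}: first column must be 'sample_id'")
    frame = pd.DataFrame(rows[1:], columns=header).set_index("sample_id")
    numeric = [c for c in frame.columns if c not in ("group", "sex")]
    for c in numeric:
        frame[c] = pd.to_numeric(frame[c])
    return SampleMetadata(frame, sensitization_threshold=sensitization_threshold)


def write_metadata_tsv(metadata: SampleMetadata, path) -> None:
    df = metadata.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def align(table: AbundanceTable, metadata: SampleMetadata):
    """Check pairing and return (table, metadata) restricted to shared order.

    Every sample in the abundance table must be present in the metadata.
    """
    missing = [s for s in table.sample_ids if s not in metadata.frame.index]
    if missing:
        raise DataValidationError(
            f"samples missing from metadata: {missing}"
        )
    meta = SampleMetadata(
        metadata.frame.loc[table.sample_ids].copy(),
        sensitization_threshold=metadata.sensitization_threshold,
    )
    return table, meta


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def to_relative_abundance(table: AbundanceTable, mode: str = "per_kingdom") -> AbundanceTable:
    """Total-sum scale a count table into relative fractions.

    ``mode="per_kingdom"`` (default) divides each sample's bacterial and
    fungal abundances by that kingdom's sample total, so each kingdom's
    fractions sum to 1 within a sample; ``mode="joint"`` divides by the
    overall sample total.  Samples whose total is zero for a kingdom yield
    zero fractions rather than NaN.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    if mode not in ("per_kingdom", "joint"):
        raise ValueError("mode must be 'per_kingdom' or 'joint'")
    data = table.data.copy()
    if mode == "per_kingdom":
        for k in KINGDOMS:
            cols = table.taxa_of(k)
            if not cols:
                continue
            tot = data[cols].sum(axis=1)
            safe = tot.replace(0.0, np.nan)
            data[cols] = data[cols].div(safe, axis=0).fillna(0.0)
    else:
        tot = data.sum(axis=1).replace(0.0, np.nan)
        data = data.div(tot, axis=0).fillna(0.0)
    return AbundanceTable(data, table.kingdom, table.rank,
                          normalized=True, norm_mode=mode)


def prevalence_filter(table: AbundanceTable, min_prev: float) -> AbundanceTable:
    """Keep taxa detected (abundance > 0) in at least ``min_prev`` of samples.

    The boundary is inclusive: a taxon present in exactly
    ``min_prev * n_samples`` samples is retained.  Column order is preserved.
    """
    if not (0 <= min_prev <= 1):
        raise ValueError("min_prev must be in [0, 1]")
    prev = (table.data.values > 0).mean(axis=0)
    keep = [t for t, p in zip(table.taxon_ids, prev) if p >= min_prev]
    return table.subset(taxa=keep)
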