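"""Reading, validation, and writing of GWAS summary statistics and LD matrices.

Data model
----------
A summary dataset is one trait's GWAS: one row per variant with alleles,
effect-allele frequency, effect size, standard error, p-value and sample
size.  Continuous traits are assumed to be reported per SD of the trait
(``effect_scale="sd"``); binary traits per unit log odds
(``effect_scale="log_or"``).  Genomic coordinates are 1-based inclusive
throughout the package; this module is the single place where external
conventions are converted.

Files are delimited text with a header, gzip-transparent.  Column naming
varies wildly between consortia, so reading goes through a
:class:`DatasetDialect` that maps canonical field names onto source headers.
An LD matrix is a square delimited table of signed correlations labelled by
variant ID on both axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, MissingVariantError, ValidationError

#: Canonical column order for written tables.
CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)

#: Fields a dialect must map for a table to be usable at all.
REQUIRED_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se")

_ALLELE_CHARS = set("ACGT")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary association with one trait."""

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pvalue: float | None = None
    n: float | None = None

    def __post_init__(self):
        if self.effect_allele == self.other_allele:
            raise ValidationError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        if not self.se > 0:
            raise ValidationError(f"{self.variant_id}: nonpositive se")
        if self.pvalue is not None and not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.variant_id}: p-value outside (0, 1]")
        if self.pos is not None and self.pos < 1:
            raise ValidationError(f"{self.variant_id}: position < 1")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G single-base variant — ambiguous under strand flips."""
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}

    @property
    def is_indel(self) -> bool:
        return len(self.effect_allele) != 1 or len(self.other_allele) != 1


@dataclass(frozen=True)
class DatasetDialect:
    """How to interpret one source's column naming and missing-data tokens.

    ``column_map`` maps canonical field names (see :data:`CANONICAL_COLUMNS`)
    to the source file's headers and must cover at least
    :data:`REQUIRED_FIELDS`.  P-values of exactly zero (common in files that
    underflowed double precision) are replaced by ``p_floor``.
    """

    column_map: Mapping[str, str]
    delimiter: str = "\t"
    missing_tokens: frozenset[str] = frozenset({"", "NA", "NaN", "nan", "."})
    p_floor: float = 1e-300

    def __post_init__(self):
        missing = [f for f in REQUIRED_FIELDS if f not in self.column_map]
        if missing:
            raise ConfigurationError(
                f"dialect column_map missing required fields: {', '.join(missing)}"
            )

    @classmethod
    def canonical(cls) -> "DatasetDialect":
        """The package's own tab-delimited output dialect."""
        return cls(column_map={c: c for c in CANONICAL_COLUMNS})


@dataclass
class SummaryDataset:
    """An ordered collection of variant associations for one trait.

    Backed by a :class:`pandas.DataFrame` in canonical column order; variant
    IDs are unique within a dataset.
    """

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    table: pd.DataFrame
    effect_scale: str | None = None  # "sd" | "log_or"
    genome_build: str = "GRCh37"

    def __post_init__(self):
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"unknown trait_type {self.trait_type!r}")
        if self.effect_scale is None:
            self.effect_scale = "log_or" if self.trait_type == "binary" else "sd"
        if self.trait_type == "binary" and self.effect_scale != "log_or":
            raise ValidationError("binary traits must be on the log_or scale")
        tab = self.table
        for col in CANONICAL_COLUMNS:
            if col not in tab.columns:
                tab[col] = np.nan
        self.table = tab.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)
        ids = self.table["variant_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate variant_id values: {', '.join(map(str, dups))}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    @property
    def records(self) -> Iterator[VariantAssociation]:
        for row in self.table.itertuples(index=False):
            yield VariantAssociation(
                variant_id=row.variant_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=row.beta,
                se=row.se,
                chrom=None if _is_missing(row.chrom) else str(row.chrom),
                pos=None if _is_missing(row.pos) else int(row.pos),
                eaf=None if _is_missing(row.eaf) else float(row.eaf),
                pvalue=None if _is_missing(row.pvalue) else float(row.pvalue),
                n=None if _is_missing(row.n) else float(row.n),
            )

    def subset(self, mask) -> "SummaryDataset":
        """New dataset keeping rows where ``mask`` is true; order preserved."""
        return SummaryDataset(
            trait_name=self.trait_name,
            trait_type=self.trait_type,
            table=self.table.loc[np.asarray(mask)].reset_index(drop=True),
            effect_scale=self.effect_scale,
            genome_build=self.genome_build,
        )


@dataclass
class ReadReport:
    """Accounting of rows dropped during validation at read time."""

    n_read: int
    n_kept: int
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )


@dataclass
class LDMatrix:
    """Signed pairwise correlation (r) among variants, indexed by variant ID."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self):
        self.variant_ids = list(self.variant_ids)
        self.r = np.asarray(self.r, dtype=float)
        J = len(self.variant_ids)
        if self.r.shape != (J, J):
            raise ValidationError(
                f"LD matrix shape {self.r.shape} does not match {J} variant IDs"
            )
        if J and np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise ValidationError("LD matrix not symmetric within 1e-8")
        if J and np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise ValidationError("LD matrix diagonal not 1 within 1e-8")
        if J and np.max(np.abs(self.r)) > 1 + 1e-8:
            raise ValidationError("LD correlations outside [-1, 1]")

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        """Rows/columns reordered (or subset) to ``ids``."""
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in index]
        if missing:
            raise MissingVariantError(
                f"variants absent from LD matrix: {', '.join(missing)}"
            )
        idx = [index[v] for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])

    def r2(self) -> np.ndarray:
        return self.r**2


def _to_float(value, missing_tokens) -> float:
    if isinstance(value, str):
        if value.strip() in missing_tokens:
            return np.nan
        return float(value)
    if value is None:
        return np.nan
    return float(value)


def read_summary_table(
    path,
    dialect: DatasetDialect,
    trait_name: str,
    trait_type: str,
    effect_scale: str | None = None,
    genome_build: str = "GRCh37",
) -> tuple[SummaryDataset, ReadReport]:
    """Read a delimited summary-statistics table in the given dialect.

    Rows violating per-variant invariants (nonpositive se, p outside (0, 1],
    invalid or identical alleles, position < 1, frequency outside [0, 1]) are
    dropped and itemised in the returned :class:`ReadReport`.  Alleles are
    uppercased; p-values of exactly 0 are floored at ``dialect.p_floor``.

    Raises
    ------
    ConfigurationError
        if a mapped column is absent from the file header.
    ValidationError
        if variant IDs are duplicated after filtering.
    """
    raw = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        keep_default_na=False,
        compression="infer",
    )
    for canonical, source in dialect.column_map.items():
        if source not in raw.columns:
            raise ConfigurationError(
                f"column {source!r} (mapped to {canonical!r}) not found in {path}"
            )

    tokens = set(dialect.missing_tokens)
    n_read = len(raw)
    cols: dict[str, list] = {c: [] for c in CANONICAL_COLUMNS}
    drop_ids: list[str] = []
    drop_reasons: list[str] = []

    get = {
        c: raw[dialect.column_map[c]] if c in dialect.column_map else None
        for c in CANONICAL_COLUMNS
    }

    for i in range(n_read):
        vid = str(get["variant_id"].iloc[i]).strip()

        def _field(name):
            series = get[name]
            return None if series is None else series.iloc[i]

        try:
            ea = str(_field("effect_allele")).strip().upper()
            oa = str(_field("other_allele")).strip().upper()
            beta = _to_float(_field("beta"), tokens)
            se = _to_float(_field("se"), tokens)
            eaf = _to_float(_field("eaf"), tokens) if get["eaf"] is not None else np.nan
            pval = (
                _to_float(_field("pvalue"), tokens)
                if get["pvalue"] is not None
                else np.nan
            )
            n = _to_float(_field("n"), tokens) if get["n"] is not None else np.nan
            chrom_raw = _field("chrom") if get["chrom"] is not None else None
            chrom = (
                None
                if chrom_raw is None or str(chrom_raw).strip() in tokens
                else str(chrom_raw).strip()
            )
            pos_raw = _field("pos") if get["pos"] is not None else None
            pos = (
                np.nan
                if pos_raw is None or str(pos_raw).strip() in tokens
                else float(int(float(pos_raw)))
            )
        except ValueError:
            drop_ids.append(vid)
            drop_reasons.append("unparseable numeric field")
            continue

        if pval == 0.0:
            pval = dialect.p_floor

        reason = None
        if math.isnan(beta) or math.isnan(se):
            reason = "missing beta or se"
        elif not se > 0:
            reason = "nonpositive se"
        elif not set(ea) <= _ALLELE_CHARS or not set(oa) <= _ALLELE_CHARS or not ea or not oa:
            reason = "invalid alleles"
        elif ea == oa:
            reason = "identical alleles"
        elif not math.isnan(pval) and not (0 < pval <= 1):
            reason = "p-value outside (0, 1]"
        elif not math.isnan(eaf) and not (0 <= eaf <= 1):
            reason = "eaf outside [0, 1]"
        elif not math.isnan(pos) and pos < 1:
            reason = "position < 1"

        if reason is not None:
            drop_ids.append(vid)
            drop_reasons.append(reason)
            continue

        cols["variant_id"].append(vid)
        cols["chrom"].append(chrom)
        cols["pos"].append(pos)
        cols["effect_allele"].append(ea)
        cols["other_allele"].append(oa)
        cols["eaf"].append(eaf)
        cols["beta"].append(beta)
        cols["se"].append(se)
        cols["pvalue"].append(pval)
        cols["n"].append(n)

    table = pd.DataFrame(cols)
    dataset = SummaryDataset(
        trait_name=trait_name,
        trait_type=trait_type,
        table=table,
        effect_scale=effect_scale,
        genome_build=genome_build,
    )
    report = ReadReport(
        n_read=n_read,
        n_kept=len(dataset),
        dropped=pd.DataFrame({"variant_id": drop_ids, "reason": drop_reasons}),
    )
    return dataset, report


def _format_value(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, (float, np.floating)):
        value = float(value)
        if math.isnan(value):
            return "NA"
        if value == int(value) and abs(value) < 1e15:
            # positions / sample sizes come back as floats from pandas
            return str(int(value))
        return repr(value)  # shortest round-trip representation
    return str(value)


def write_summary_table(dataset: SummaryDataset, path) -> None:
    """Write in the canonical tab-delimited dialect.

    Floats are written with full round-trip precision (17 significant
    digits), so write→read reproduces every numeric field bit-for-bit.
    """
    with open(path, "w") as handle:
        handle.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in dataset.table.itertuples(index=False):
            handle.write(
                "\t".join(_format_value(getattr(row, c)) for c in CANONICAL_COLUMNS)
                + "\n"
            )


def read_ld_matrix(path, ids: Sequence[str], delimiter: str = "\t") -> LDMatrix:
    """Read a square LD matrix and reorder it to ``ids``.

    The file must carry variant IDs as both header row and first column.
    Asymmetries up to 1e-6 (absolute) are repaired as (M + Mᵀ)/2; larger
    asymmetry is a format error.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0, compression="infer")
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    if frame.shape[0] != frame.shape[1] or list(frame.index) != list(frame.columns):
        raise FormatError(f"{path}: LD matrix is not square with matching labels")
    m = frame.to_numpy(dtype=float)
    asym = np.max(np.abs(m - m.T)) if m.size else 0.0
    if asym > 1e-6:
        raise FormatError(f"{path}: LD matrix asymmetry {asym:.3g} exceeds 1e-6")
    m = (m + m.T) / 2.0
    full = LDMatrix(list(frame.index), m)
    return full.subset(list(ids))


def write_ld_matrix(ld: LDMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w") as handle:
        handle.write(delimiter.join([""] + ld.variant_ids) + "\n")
        for vid, row in zip(ld.variant_ids, ld.r):
            handle.write(delimiter.join([vid] + [repr(float(v)) for v in row]) + "\n")
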