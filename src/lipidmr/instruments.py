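"""Instrument selection and qualification.

Covers the selection chain used for each analysis arm: genome-wide p-value
thresholding, cis-window extraction around drug-target genes, MHC exclusion,
greedy LD clumping, Steiger directionality filtering, and instrument-strength
metrics (per-SNP F statistic and variance explained).

Conventions
-----------
* Coordinates are 1-based inclusive; BED input is converted on read.
* The per-SNP F statistic is (β/se)²; variance explained uses either the
  t-statistic identity R² = F/(F + n − 2) or, for standardized traits with
  known allele frequency, R² = 2·eaf·(1 − eaf)·β².
* The default MHC exclusion window is chr6:24,000,000–35,000,000 (GRCh37).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, MissingVariantError, ValidationError
from .harmonize import HarmonizedInstruments
from .sumstats import LDMatrix, SummaryDataset

#: GRCh37 extended MHC window excluded from the MS outcome GWAS.
MHC_CHROM = "6"
MHC_START = 24_000_000
MHC_END = 35_000_000

#: Default genome-wide significance threshold.
GENOME_WIDE_P = 5e-8

#: Default cis-window flank around a gene body.
CIS_FLANK_BP = 5_000


@dataclass(frozen=True)
class GeneRegion:
    """A gene body with its pathway grouping (1-based inclusive coordinates)."""

    symbol: str
    chrom: str
    start: int
    end: int
    pathway_label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"{self.symbol}: start > end")


@dataclass
class InstrumentSet:
    """Qualified instruments with per-SNP and aggregate strength metrics."""

    harmonized: HarmonizedInstruments
    per_snp_F: np.ndarray
    per_snp_r2_x: np.ndarray
    per_snp_r2_y: np.ndarray | None = None
    steiger_dropped: list[str] = field(default_factory=list)
    r2_method: str = "t_stat"

    @property
    def mean_F(self) -> float:
        return float(np.mean(self.per_snp_F)) if len(self.per_snp_F) else float("nan")

    @property
    def total_r2_x(self) -> float:
        """Variance explained under the independent-instrument approximation."""
        return float(np.sum(self.per_snp_r2_x))

    @property
    def n_snps(self) -> int:
        return len(self.per_snp_F)


def threshold_by_pvalue(dataset: SummaryDataset, alpha: float) -> SummaryDataset:
    """Keep records with p-value strictly below ``alpha``; order preserved."""
    if not (0 < alpha < 1) and alpha != 1.0:
        raise ValidationError("alpha must be in (0, 1]")
    p = dataset.table["pvalue"].to_numpy(dtype=float)
    return dataset.subset(p < alpha)


def extract_cis_window(
    dataset: SummaryDataset, region: GeneRegion, flank_bp: int = CIS_FLANK_BP
) -> SummaryDataset:
    """Keep records within ``region`` ± ``flank_bp`` (inclusive both ends)."""
    if flank_bp < 0:
        raise ValidationError("flank_bp must be >= 0")
    chrom = dataset.table["chrom"].astype(str).str.removeprefix("chr")
    pos = dataset.table["pos"].to_numpy(dtype=float)
    target = str(region.chrom).removeprefix("chr")
    mask = (
        (chrom == target)
        & (pos >= region.start - flank_bp)
        & (pos <= region.end + flank_bp)
    )
    return dataset.subset(mask.to_numpy())


def exclude_region(
    dataset: SummaryDataset, chrom: str, start_bp: int, end_bp: int
) -> SummaryDataset:
    """Remove records with matching chromosome and position in [start, end]."""
    if start_bp > end_bp:
        raise ValidationError("start_bp must be <= end_bp")
    ds_chrom = dataset.table["chrom"].astype(str).str.removeprefix("chr")
    pos = dataset.table["pos"].to_numpy(dtype=float)
    target = str(chrom).removeprefix("chr")
    inside = (ds_chrom == target) & (pos >= start_bp) & (pos <= end_bp)
    return dataset.subset(~inside.to_numpy())


def exclude_mhc(dataset: SummaryDataset) -> SummaryDataset:
    """Remove the extended MHC region (chr6:24–35 Mb, GRCh37)."""
    return exclude_region(dataset, MHC_CHROM, MHC_START, MHC_END)


def _chrom_sort_key(chrom) -> tuple:
    s = str(chrom).removeprefix("chr") if chrom is not None else ""
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


def ld_clump(
    dataset: SummaryDataset, ld: LDMatrix, r2_threshold: float
) -> SummaryDataset:
    """Greedy LD clumping against a precomputed correlation matrix.

    Repeatedly take the smallest-p remaining variant as index and discard
    all remaining variants with r² strictly above ``r2_threshold`` against
    it.  Returns index variants in selection order.  Ties on p-value break
    deterministically by (chromosome, position, variant_id).

    Raises
    ------
    MissingVariantError
        if a dataset variant is absent from the LD matrix.
    """
    if not (0 < r2_threshold <= 1):
        raise ValidationError("r2_threshold must be in (0, 1]")
    ids = dataset.variant_ids
    if not ids:
        return dataset
    sub = ld.subset(ids)  # raises MissingVariantError when absent
    r2 = sub.r2()

    tab = dataset.table
    pvals = tab["pvalue"].to_numpy(dtype=float)
    if np.isnan(pvals).any():
        raise ValidationError("clumping requires p-values for every variant")
    keys = sorted(
        range(len(ids)),
        key=lambda i: (
            pvals[i],
            _chrom_sort_key(tab["chrom"].iloc[i]),
            tab["pos"].iloc[i] if not pd.isna(tab["pos"].iloc[i]) else float("inf"),
            ids[i],
        ),
    )

    alive = np.ones(len(ids), dtype=bool)
    selected: list[int] = []
    for i in keys:
        if not alive[i]:
            continue
        selected.append(i)
        alive &= r2[i] <= r2_threshold
        alive[i] = False

    order = np.array(selected, dtype=int)
    out = dataset.subset(np.isin(np.arange(len(ids)), order))
    # reorder rows to selection order
    sel_ids = [ids[i] for i in order]
    out.table = (
        out.table.set_index("variant_id").loc[sel_ids].reset_index()
    )
    return SummaryDataset(
        trait_name=out.trait_name,
        trait_type=out.trait_type,
        table=out.table,
        effect_scale=out.effect_scale,
        genome_build=out.genome_build,
    )


def _r2_t_stat(beta: np.ndarray, se: np.ndarray, n: float) -> np.ndarray:
    F = (beta / se) ** 2
    return F / (F + n - 2)


def per_snp_strength(
    harmonized: HarmonizedInstruments,
    n_x: float,
    method: str = "t_stat",
    n_y: float | None = None,
) -> InstrumentSet:
    """Per-SNP F statistics and variance explained for the exposure.

    ``method="t_stat"`` uses R² = F/(F + n − 2) and requires ``n_x`` > 2;
    ``method="freq_beta"`` uses R² = 2·eaf·(1 − eaf)·β² (standardized trait)
    and requires effect-allele frequencies.  When ``n_y`` is given, the
    outcome-side R² (t-statistic rule) is attached as well.
    """
    bx, sx = harmonized.beta_x, harmonized.se_x
    F = (bx / sx) ** 2
    if method == "t_stat":
        if n_x is None or not n_x > 2:
            raise ConfigurationError("method 't_stat' requires exposure sample size > 2")
        r2_x = _r2_t_stat(bx, sx, n_x)
    elif method == "freq_beta":
        if harmonized.eaf_x is None or np.isnan(harmonized.eaf_x).any():
            raise ConfigurationError(
                "method 'freq_beta' requires effect-allele frequencies for every variant"
            )
        eaf = harmonized.eaf_x
        r2_x = np.clip(2.0 * eaf * (1.0 - eaf) * bx**2, 0.0, 1.0)
    else:
        raise ConfigurationError(f"unknown strength method {method!r}")

    r2_y = None
    if n_y is not None:
        if not n_y > 2:
            raise ConfigurationError("outcome sample size must be > 2")
        r2_y = _r2_t_stat(harmonized.beta_y, harmonized.se_y, n_y)

    return InstrumentSet(
        harmonized=harmonized,
        per_snp_F=F,
        per_snp_r2_x=r2_x,
        per_snp_r2_y=r2_y,
        r2_method=method,
    )


def steiger_filter(
    harmonized: HarmonizedInstruments,
    n_x: float,
    n_y: float,
    use_z_test: bool = False,
    z_alpha: float = 0.05,
) -> tuple[HarmonizedInstruments, list[str]]:
    """Drop variants explaining more outcome than exposure variance.

    Per-variant R² on each side is computed by the t-statistic identity
    R² = F/(F + n − 2); variant j is dropped when r2_y_j > r2_x_j (strict;
    ties retained).  For binary outcomes this applies the same formula on
    the log-OR scale (observed-scale approximation).

    With ``use_z_test`` the drop additionally requires the difference of
    Fisher-z-transformed correlations to be significant at ``z_alpha``
    (one-sided); off by default.

    Returns the filtered instruments and the dropped variant IDs.
    """
    if not (n_x > 2 and n_y > 2):
        raise ValidationError("Steiger filtering requires both sample sizes > 2")
    r2_x = _r2_t_stat(harmonized.beta_x, harmonized.se_x, n_x)
    r2_y = _r2_t_stat(harmonized.beta_y, harmonized.se_y, n_y)
    wrong_direction = r2_y > r2_x
    if use_z_test:
        zx = np.arctanh(np.sqrt(np.clip(r2_x, 0.0, 1.0 - 1e-15)))
        zy = np.arctanh(np.sqrt(np.clip(r2_y, 0.0, 1.0 - 1e-15)))
        z = (zy - zx) / np.sqrt(1.0 / (n_y - 3) + 1.0 / (n_x - 3))
        wrong_direction &= z > stats.norm.ppf(1.0 - z_alpha)
    dropped = [v for v, w in zip(harmonized.variant_ids, wrong_direction) if w]
    return harmonized.subset(~wrong_direction), dropped


def read_gene_regions(path) -> list[GeneRegion]:
    """Read gene regions from a BED-like tab-delimited file.

    Columns: chrom, start, end, symbol, pathway_label (no header).  BED's
    0-based half-open convention is converted to 1-based inclusive here.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "symbol", "pathway_label"],
        dtype={"chrom": str, "symbol": str, "pathway_label": str},
        comment="#",
    )
    regions = []
    for row in frame.itertuples(index=False):
        regions.append(
            GeneRegion(
                symbol=row.symbol,
                chrom=str(row.chrom),
                start=int(row.start) + 1,
                end=int(row.end),
                pathway_label="" if pd.isna(row.pathway_label) else str(row.pathway_label),
            )
        )
    return regions
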