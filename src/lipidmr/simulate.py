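"""Two-sample GWAS summary-statistics simulator with known ground truth.

The generative model mirrors the statistical structure assumed by
summary-data MR.  For variant j with minor-allele frequency maf_j:

* true variant-exposure effect γ_j (per allele, SD units of the exposure),
* direct (pleiotropic) variant-outcome effect α_j,
* total variant-outcome effect Γ_j = θ·γ_j + α_j where θ is the causal
  effect of one SD of exposure on the outcome,
* reported effects carry two-sample, non-overlapping estimation noise:
  β̂_Xj ~ N(γ_j, se_Xj²), β̂_Yj ~ N(Γ_j, se_Yj²) with
  se = 1/√(2·n·maf·(1 − maf)) on the standardized scale (binary outcomes
  use the same form on the log-OR scale, n_y read as effective size).

Pleiotropy regimes: ``("none",)``, ``("balanced", sd)`` with α ~ N(0, sd²),
and ``("directional", mean, sd)`` where α_j = sign(γ_j)·N(mean, sd²) — the
directional mean is defined relative to the exposure-increasing allele, the
orientation under which MR-Egger's intercept estimates it.  An InSIDE
violation correlates α with γ.  Optional AR(1) LD blocks correlate the
estimation errors within a block and are emitted as the study's LD matrix.
Reverse-causation variants act primarily on the outcome (Γ drawn from the
γ distribution) with an induced exposure effect θ_rev·Γ.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .harmonize import HarmonizedInstruments
from .sumstats import LDMatrix, SummaryDataset

#: Default true-effect distribution: Normal(0, 0.05²) truncated away from 0
#: at |γ| > 0.03, roughly the genome-wide detectability limit at n = 1e5 —
#: instruments drawn from it pass p < 5e-8 and carry mean F in the 100–200
#: range typical of large lipid GWAS.
DEFAULT_GAMMA_DIST = ("truncnormal", 0.0, 0.05, 0.03)


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one simulated two-sample study."""

    J: int = 100
    theta: float = 0.0
    n_x: float = 1e5
    n_y: float = 1e5
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_dist: tuple = DEFAULT_GAMMA_DIST
    pleiotropy: tuple = ("none",)
    inside_violation: bool = False
    inside_strength: float = 0.1
    ld_spec: tuple | None = None  # ("ar1", rho, block_size)
    outcome_type: str = "continuous"
    n_reverse: int = 0
    theta_rev: float | None = None
    palindromic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.J < 1:
            raise ConfigurationError("J must be >= 1")
        if not (self.n_x > 2 and self.n_y > 2):
            raise ConfigurationError("sample sizes must be > 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.n_reverse <= self.J):
            raise ConfigurationError("n_reverse must be in [0, J]")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown outcome_type {self.outcome_type!r}")
        if self.pleiotropy[0] not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy regime {self.pleiotropy!r}")
        if self.ld_spec is not None and self.ld_spec[0] != "ar1":
            raise ConfigurationError(f"unknown ld_spec {self.ld_spec!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class SimulatedStudy:
    """Generated datasets plus the ground truth that produced them."""

    config: SimulationConfig
    truth: pd.DataFrame  # variant_id, maf, gamma, alpha, Gamma, is_reverse
    exposure: SummaryDataset
    outcome: SummaryDataset
    ld: LDMatrix | None = None
    exposure_matrix: np.ndarray | None = None  # J×K estimated effects (MV studies)
    exposure_se_matrix: np.ndarray | None = None
    thetas: np.ndarray | None = None

    def to_harmonized(self, exposure_index: int | None = None) -> HarmonizedInstruments:
        """Aligned effect vectors, bypassing harmonize() (data share alleles)."""
        ex, oc = self.exposure.table, self.outcome.table
        if exposure_index is None:
            bx = ex["beta"].to_numpy()
            sx = ex["se"].to_numpy()
        else:
            bx = self.exposure_matrix[:, exposure_index]
            sx = self.exposure_se_matrix[:, exposure_index]
        return HarmonizedInstruments(
            variant_ids=ex["variant_id"].tolist(),
            beta_x=bx,
            se_x=sx,
            beta_y=oc["beta"].to_numpy(),
            se_y=oc["se"].to_numpy(),
            eaf_x=ex["eaf"].to_numpy(),
            eaf_y=oc["eaf"].to_numpy(),
            effect_alleles=ex["effect_allele"].tolist(),
            other_alleles=ex["other_allele"].tolist(),
            exposure_name=self.exposure.trait_name,
            outcome_name=self.outcome.trait_name,
            outcome_type=self.outcome.trait_type,
        )

    def write(self, directory) -> None:
        """Write exposure/outcome tables, truth sidecar, and LD matrix."""
        from pathlib import Path

        from .sumstats import write_ld_matrix, write_summary_table

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_summary_table(self.exposure, directory / "exposure.tsv")
        write_summary_table(self.outcome, directory / "outcome.tsv")
        self.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
        if self.ld is not None:
            write_ld_matrix(self.ld, directory / "ld.tsv")


def _draw_gamma(spec, size, rng) -> np.ndarray:
    """Draw true effects; resampling enforces truncation away from zero."""
    kind = spec[0]
    if kind == "normal":
        _, mean, sd = spec
        return rng.normal(mean, sd, size)
    if kind == "truncnormal":
        _, mean, sd, min_abs = spec
        out = rng.normal(mean, sd, size)
        for _ in range(1000):
            small = np.abs(out) <= min_abs
            if not small.any():
                return out
            out[small] = rng.normal(mean, sd, small.sum())
        raise ConfigurationError("truncation bound rejects nearly all draws")
    if kind == "abs_normal":
        _, mean, sd, min_abs = spec
        out = np.abs(rng.normal(mean, sd, size))
        for _ in range(1000):
            small = out <= min_abs
            if not small.any():
                return out
            out[small] = np.abs(rng.normal(mean, sd, small.sum()))
        raise ConfigurationError("truncation bound rejects nearly all draws")
    if kind == "uniform":
        _, lo, hi = spec
        return rng.uniform(lo, hi, size)
    raise ConfigurationError(f"unknown gamma_dist {spec!r}")


def _ar1_blocks(J: int, rho: float, block_size: int) -> np.ndarray:
    """Block-diagonal correlation with r_jk = rho^|j−k| within each block."""
    r = np.eye(J)
    start = 0
    while start < J:
        stop = min(start + block_size, J)
        idx = np.arange(start, stop)
        d = np.abs(idx[:, None] - idx[None, :])
        r[start:stop, start:stop] = rho**d
        start = stop
    return r


def _correlated_noise(J: int, r: np.ndarray | None, rng) -> np.ndarray:
    z = rng.standard_normal(J)
    if r is None:
        return z
    chol = np.linalg.cholesky(r)
    return chol @ z


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.maximum(p, 1e-300)


def _build_dataset(name, trait_type, ids, chrom, pos, ea, oa, eaf, beta, se, n):
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pvalue": _two_sided_p(beta, se),
            "n": float(n),
        }
    )
    return SummaryDataset(trait_name=name, trait_type=trait_type, table=table)


def simulate_study(
    config: SimulationConfig,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> SimulatedStudy:
    """Generate one two-sample study; bit-identical given the config seed."""
    rng = np.random.default_rng(config.seed)
    J = config.J

    maf = rng.uniform(*config.maf_range, J)
    gamma = _draw_gamma(config.gamma_dist, J, rng)
    alpha = _draw_alpha(config, gamma, rng)

    is_reverse = np.zeros(J, dtype=bool)
    if config.n_reverse:
        is_reverse[rng.choice(J, size=config.n_reverse, replace=False)] = True
    theta_rev = config.theta if config.theta_rev is None else config.theta_rev

    Gamma = config.theta * gamma + alpha
    if is_reverse.any():
        # primary effect on the outcome; exposure effect is induced
        Gamma[is_reverse] = gamma[is_reverse]
        gamma = np.where(is_reverse, theta_rev * Gamma, gamma)
        alpha[is_reverse] = 0.0

    se_x = 1.0 / np.sqrt(2.0 * config.n_x * maf * (1.0 - maf))
    se_y = 1.0 / np.sqrt(2.0 * config.n_y * maf * (1.0 - maf))

    r = None
    if config.ld_spec is not None:
        _, rho, block_size = config.ld_spec
        r = _ar1_blocks(J, float(rho), int(block_size))

    beta_x = gamma + se_x * _correlated_noise(J, r, rng)
    beta_y = Gamma + se_y * _correlated_noise(J, r, rng)

    ids = [f"rs{j + 1}" for j in range(J)]
    pos = 1_000_000 + 10_000 * np.arange(J, dtype=float)
    n_palin = int(round(config.palindromic_fraction * J))
    ea = ["A"] * J
    oa = ["T" if j < n_palin else "G" for j in range(J)]

    exposure = _build_dataset(
        exposure_name, "continuous", ids, "1", pos, ea, oa, maf, beta_x, se_x, config.n_x
    )
    outcome = _build_dataset(
        outcome_name,
        config.outcome_type,
        ids,
        "1",
        pos,
        ea,
        oa,
        maf,
        beta_y,
        se_y,
        config.n_y,
    )
    truth = pd.DataFrame(
        {
            "variant_id": ids,
            "maf": maf,
            "gamma": gamma,
            "alpha": alpha,
            "Gamma": Gamma,
            "is_reverse": is_reverse,
        }
    )
    ld = LDMatrix(ids, r) if r is not None else None
    return SimulatedStudy(
        config=config, truth=truth, exposure=exposure, outcome=outcome, ld=ld
    )


def _draw_alpha(config: SimulationConfig, gamma: np.ndarray, rng) -> np.ndarray:
    J = gamma.size
    regime = config.pleiotropy
    if regime[0] == "none":
        alpha = np.zeros(J)
    elif regime[0] == "balanced":
        alpha = rng.normal(0.0, regime[1], J)
    else:  # directional, oriented to the exposure-increasing allele
        _, mean, sd = regime
        alpha = np.sign(gamma) * rng.normal(mean, sd, J)
    if config.inside_violation:
        alpha = alpha + config.inside_strength * gamma
    return alpha


def simulate_mv_study(
    config: SimulationConfig,
    K: int,
    cross_effects: np.ndarray | None = None,
    thetas=None,
) -> SimulatedStudy:
    """Simulate K correlated exposures for multivariable MR.

    Per-variant true effects on the K exposures are independent draws mixed
    through the K×K ``cross_effects`` matrix (identity → K independent
    single-exposure studies); the outcome is Σ_k θ_k·γ_jk + α_j.
    """
    if K < 2:
        raise ConfigurationError("simulate_mv_study requires K >= 2")
    if cross_effects is None:
        cross_effects = np.eye(K)
    cross_effects = np.asarray(cross_effects, dtype=float)
    if cross_effects.shape != (K, K):
        raise ConfigurationError("cross_effects must be K×K")
    if abs(np.linalg.det(cross_effects)) < 1e-12:
        raise ConfigurationError("cross_effects mixing matrix is singular")
    thetas = (
        np.full(K, config.theta, dtype=float)
        if thetas is None
        else np.asarray(thetas, dtype=float)
    )
    if thetas.shape != (K,):
        raise ConfigurationError("thetas must have length K")

    rng = np.random.default_rng(config.seed)
    J = config.J
    maf = rng.uniform(*config.maf_range, J)
    raw = np.column_stack([_draw_gamma(config.gamma_dist, J, rng) for _ in range(K)])
    gamma_mat = raw @ cross_effects.T
    alpha = _draw_alpha(config, gamma_mat[:, 0], rng)
    Gamma = gamma_mat @ thetas + alpha

    se_x = 1.0 / np.sqrt(2.0 * config.n_x * maf * (1.0 - maf))
    se_y = 1.0 / np.sqrt(2.0 * config.n_y * maf * (1.0 - maf))
    beta_x_mat = gamma_mat + se_x[:, None] * rng.standard_normal((J, K))
    beta_y = Gamma + se_y * rng.standard_normal(J)

    ids = [f"rs{j + 1}" for j in range(J)]
    pos = 1_000_000 + 10_000 * np.arange(J, dtype=float)
    ea, oa = ["A"] * J, ["G"] * J
    exposure = _build_dataset(
        "exposure_0", "continuous", ids, "1", pos, ea, oa, maf,
        beta_x_mat[:, 0], se_x, config.n_x,
    )
    outcome = _build_dataset(
        "outcome", config.outcome_type, ids, "1", pos, ea, oa, maf,
        beta_y, se_y, config.n_y,
    )
    truth = pd.DataFrame(
        {
            "variant_id": ids,
            "maf": maf,
            "gamma": gamma_mat[:, 0],
            "alpha": alpha,
            "Gamma": Gamma,
            "is_reverse": False,
        }
    )
    se_mat = np.repeat(se_x[:, None], K, axis=1)
    return SimulatedStudy(
        config=config,
        truth=truth,
        exposure=exposure,
        outcome=outcome,
        exposure_matrix=beta_x_mat,
        exposure_se_matrix=se_mat,
        thetas=thetas,
    )
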