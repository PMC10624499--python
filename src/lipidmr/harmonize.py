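"""Alignment of exposure and outcome summary statistics to a shared effect allele.

Two-sample MR needs, for every instrument, the exposure effect and outcome
effect expressed for the *same* allele.  Consortium files disagree on which
allele is the effect allele and sometimes on reported strand, so each shared
variant goes through a resolution cascade:

1. outcome alleles equal exposure alleles           → kept
2. equal after swapping effect/other                → effect flipped
   (outcome beta negated, eaf_y → 1 − eaf_y)
3. equal after complementing strand (A↔T, C↔G)      → strand corrected,
   then rule 1/2 applies
4. palindromic variants (A/T, C/G) are inherently strand-ambiguous: they
   are dropped when either frequency is missing or too close to 0.5,
   otherwise the allele-based alignment is accepted only when the two
   frequencies fall on the same side of 0.5
5. anything else                                    → dropped (mismatch)

Indel alleles cannot be strand-ambiguous in the palindromic sense and use
exact/swap matching only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoSharedVariantsError, ValidationError
from .sumstats import SummaryDataset

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

KEPT = "kept"
FLIPPED = "flipped"
STRAND_CORRECTED = "strand_corrected"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_mismatch"


@dataclass
class HarmonizedInstruments:
    """Exposure/outcome effect vectors aligned to a common effect allele.

    Retained variants only; the full per-variant action log (including
    drops) lives in ``audit`` with columns variant_id, action, reason.
    """

    variant_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf_x: np.ndarray | None = None
    eaf_y: np.ndarray | None = None
    effect_alleles: list[str] | None = None
    other_alleles: list[str] | None = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    outcome_type: str = "continuous"
    audit: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "action", "reason"])
    )

    def __post_init__(self):
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        self.se_x = np.asarray(self.se_x, dtype=float)
        self.beta_y = np.asarray(self.beta_y, dtype=float)
        self.se_y = np.asarray(self.se_y, dtype=float)
        J = len(self.variant_ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            if len(getattr(self, name)) != J:
                raise ValidationError(f"{name} length does not match variant_ids")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValidationError("standard errors must be positive")
        if self.eaf_x is not None:
            self.eaf_x = np.asarray(self.eaf_x, dtype=float)
        if self.eaf_y is not None:
            self.eaf_y = np.asarray(self.eaf_y, dtype=float)

    def __len__(self) -> int:
        return len(self.variant_ids)

    @property
    def n_retained(self) -> int:
        return len(self)

    def subset(self, mask) -> "HarmonizedInstruments":
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        return HarmonizedInstruments(
            variant_ids=[self.variant_ids[i] for i in idx],
            beta_x=self.beta_x[idx],
            se_x=self.se_x[idx],
            beta_y=self.beta_y[idx],
            se_y=self.se_y[idx],
            eaf_x=None if self.eaf_x is None else self.eaf_x[idx],
            eaf_y=None if self.eaf_y is None else self.eaf_y[idx],
            effect_alleles=None
            if self.effect_alleles is None
            else [self.effect_alleles[i] for i in idx],
            other_alleles=None
            if self.other_alleles is None
            else [self.other_alleles[i] for i in idx],
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            outcome_type=self.outcome_type,
            audit=self.audit,
        )

    def write_audit(self, path) -> None:
        """Tab-delimited harmonization audit (variant_id, action, reason)."""
        self.audit.to_csv(path, sep="\t", index=False)


def _complement(allele: str) -> str:
    return allele.translate(_COMPLEMENT)


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedInstruments:
    """Align ``outcome`` effects to the exposure's effect alleles.

    Variants are intersected on ID (exposure order preserved) and resolved
    per the module cascade.  Palindromic variants are dropped when either
    eaf is missing or within ``palindromic_eaf_window`` of 0.5; an accepted
    palindromic alignment additionally requires eaf_x and aligned eaf_y on
    the same side of 0.5.

    Raises
    ------
    NoSharedVariantsError
        if the datasets share no variant IDs.
    ValidationError
        if either dataset is empty or the window is outside [0, 0.5).
    """
    if not (0 <= palindromic_eaf_window < 0.5):
        raise ValidationError("palindromic_eaf_window must be in [0, 0.5)")
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValidationError("exposure and outcome datasets must be nonempty")

    out_by_id = {rec.variant_id: rec for rec in outcome.records}
    rows = []
    audit_rows = []

    for ex in exposure.records:
        oc = out_by_id.get(ex.variant_id)
        if oc is None:
            continue

        action, reason = _resolve(ex, oc, palindromic_eaf_window)
        audit_rows.append((ex.variant_id, action, reason))
        if action in (DROPPED_PALINDROMIC, DROPPED_MISMATCH):
            continue

        flip = action == FLIPPED or reason.endswith("swapped")
        beta_y = -oc.beta if flip else oc.beta
        eaf_y = oc.eaf
        if eaf_y is not None and flip:
            eaf_y = 1.0 - eaf_y
        rows.append(
            (
                ex.variant_id,
                ex.effect_allele,
                ex.other_allele,
                ex.beta,
                ex.se,
                beta_y,
                oc.se,
                np.nan if ex.eaf is None else ex.eaf,
                np.nan if eaf_y is None else eaf_y,
            )
        )

    if not audit_rows:
        raise NoSharedVariantsError(
            f"no shared variants between {exposure.trait_name!r} and {outcome.trait_name!r}"
        )

    audit = pd.DataFrame(audit_rows, columns=["variant_id", "action", "reason"])
    if rows:
        ids, ea, oa, bx, sx, by, sy, fx, fy = map(list, zip(*rows))
    else:
        ids = ea = oa = []
        bx = sx = by = sy = fx = fy = []
    return HarmonizedInstruments(
        variant_ids=ids,
        beta_x=np.array(bx, dtype=float),
        se_x=np.array(sx, dtype=float),
        beta_y=np.array(by, dtype=float),
        se_y=np.array(sy, dtype=float),
        eaf_x=np.array(fx, dtype=float),
        eaf_y=np.array(fy, dtype=float),
        effect_alleles=ea,
        other_alleles=oa,
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
        outcome_type=outcome.trait_type,
        audit=audit,
    )


def _resolve(ex, oc, window: float) -> tuple[str, str]:
    """Classify one shared variant; returns (action, reason)."""
    ea_x, oa_x = ex.effect_allele, ex.other_allele
    ea_y, oa_y = oc.effect_allele, oc.other_allele

    if ex.is_palindromic and not ex.is_indel:
        # exact and swapped matches are indistinguishable from strand flips
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return DROPPED_MISMATCH, "alleles incompatible"
        if ex.eaf is None or oc.eaf is None:
            return DROPPED_PALINDROMIC, "palindromic with missing eaf"
        # small epsilon keeps the inclusive boundary robust to float noise
        if abs(ex.eaf - 0.5) <= window + 1e-12 or abs(oc.eaf - 0.5) <= window + 1e-12:
            return DROPPED_PALINDROMIC, "palindromic with eaf near 0.5"
        # candidate alignment from allele orientation, then frequency check
        swapped = ea_y == oa_x
        eaf_y_aligned = 1.0 - oc.eaf if swapped else oc.eaf
        if (ex.eaf - 0.5) * (eaf_y_aligned - 0.5) > 0:
            if swapped:
                return FLIPPED, "palindromic aligned by frequency, swapped"
            return KEPT, "palindromic aligned by frequency"
        return DROPPED_PALINDROMIC, "palindromic frequency disagreement"

    if (ea_y, oa_y) == (ea_x, oa_x):
        return KEPT, "alleles match"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return FLIPPED, "effect/other swapped"

    if not ex.is_indel and not oc.is_indel:
        cea, coa = _complement(ea_y), _complement(oa_y)
        if (cea, coa) == (ea_x, oa_x):
            return STRAND_CORRECTED, "strand complemented"
        if (cea, coa) == (oa_x, ea_x):
            return STRAND_CORRECTED, "strand complemented, swapped"

    return DROPPED_MISMATCH, "alleles incompatible"


def harmonized_to_outcome_dataset(h: HarmonizedInstruments) -> SummaryDataset:
    """Re-express harmonized outcome effects as a SummaryDataset.

    Useful for re-harmonization (idempotence checks) and for writing the
    aligned outcome back to disk; alleles are the exposure's orientation.
    """
    table = pd.DataFrame(
        {
            "variant_id": h.variant_ids,
            "effect_allele": h.effect_alleles,
            "other_allele": h.other_alleles,
            "eaf": h.eaf_y if h.eaf_y is not None else np.nan,
            "beta": h.beta_y,
            "se": h.se_y,
        }
    )
    return SummaryDataset(
        trait_name=h.outcome_name, trait_type=h.outcome_type, table=table
    )
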