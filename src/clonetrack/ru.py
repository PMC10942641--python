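"""Repopulating-unit (RU) quantification and expansion-fold arithmetic.

In a competitive repopulation assay, test cells are co-transplanted with a
known dose of competitor whole-bone-marrow (WBM) cells and the test graft's
percent chimerism is read per lineage. One RU is the average reconstitution
activity of 1e5 WBM cells, so a recipient with test chimerism ``p`` percent
against ``C`` competitor cells carries::

    RU = p / (100 - p) * (C / 1e5)

Dividing by the number of input-cell equivalents transplanted (e.g. EE10 =
the expanded progeny of 10 input cHSCs) gives RU per input cell, and the
ratio of cohort means between expanded and fresh grafts is the functional
expansion fold. The phenotypic fold is plain cell arithmetic: total cells x
candidate-HSC frequency / input cells.

Chimerism at or near 100% saturates the assay (the RU diverges); such
recipients are flagged and excluded from cohort means by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

WBM_PER_RU = 1e5
LINEAGES = ("PB_total", "B", "T", "myeloid", "BM_cHSC")
DEFAULT_SATURATION_PCT = 99.9


@dataclass(frozen=True)
class ChimerismRecord:
    """Per-recipient, per-lineage donor chimerism against a competitor dose."""

    recipient_id: str
    lineage: str
    test_pct: float
    competitor_cells: float
    input_equivalents: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.test_pct <= 100.0:
            raise ValueError("test_pct must be in [0, 100]")
        if self.competitor_cells < 0:
            raise ValueError("competitor_cells must be >= 0")
        if self.input_equivalents <= 0:
            raise ValueError("input_equivalents must be positive")


@dataclass(frozen=True)
class RUResult:
    ru: float
    ru_per_input_cell: float
    lineage: str
    recipient_id: str
    saturated: bool = False


def repopulating_units(rec: ChimerismRecord) -> RUResult:
    """RU of one recipient/lineage: ``p/(100-p) * competitor/1e5``."""
    if rec.test_pct >= 100.0:
        raise ValueError(
            "test_pct = 100 saturates the assay; the RU is undefined "
            "(signal out of quantification range)"
        )
    if rec.competitor_cells <= 0:
        raise ValueError("competitor_cells must be positive to define an RU")
    ru = rec.test_pct / (100.0 - rec.test_pct) * (rec.competitor_cells / WBM_PER_RU)
    return RUResult(
        ru=float(ru),
        ru_per_input_cell=float(ru / rec.input_equivalents),
        lineage=rec.lineage,
        recipient_id=rec.recipient_id,
        saturated=rec.test_pct >= DEFAULT_SATURATION_PCT,
    )


def chimerism_from_ru(ru: float, competitor_cells: float) -> float:
    """Inverse of :func:`repopulating_units`: percent chimerism from an RU."""
    if ru < 0 or competitor_cells <= 0:
        raise ValueError("ru must be >= 0 and competitor_cells positive")
    competitor_ru = competitor_cells / WBM_PER_RU
    return 100.0 * ru / (ru + competitor_ru)


def _cohort_mean(results: list[RUResult], geometric: bool, exclude_saturated: bool) -> float:
    vals = [r.ru_per_input_cell for r in results if not (exclude_saturated and r.saturated)]
    if not vals:
        raise ValueError("no quantifiable recipients in cohort (all saturated?)")
    if geometric:
        arr = np.asarray(vals)
        if (arr <= 0).any():
            raise ValueError("geometric mean requires positive RUs")
        return float(np.exp(np.mean(np.log(arr))))
    return float(np.mean(vals))


def functional_expansion_fold(
    fresh: list[RUResult],
    expanded: list[RUResult],
    geometric: bool = False,
    exclude_saturated: bool = True,
) -> float:
    """Fold increase in per-input-cell RU of expanded vs fresh cohorts.

    Cohorts must share one lineage. Arithmetic cohort means by default;
    geometric optionally. Saturated recipients are excluded by default.
    """
    if not fresh or not expanded:
        raise ValueError("both cohorts must be non-empty")
    lineages = {r.lineage for r in fresh} | {r.lineage for r in expanded}
    if len(lineages) != 1:
        raise ValueError(f"cohorts must share one lineage, got {sorted(lineages)}")
    mean_fresh = _cohort_mean(fresh, geometric, exclude_saturated)
    mean_exp = _cohort_mean(expanded, geometric, exclude_saturated)
    if mean_fresh == 0:
        raise ValueError("fresh cohort mean RU is zero; fold undefined")
    return mean_exp / mean_fresh


def phenotypic_expansion_fold(
    total_cells: float, chsc_frequency: float, input_chsc: float
) -> float:
    """Fold change of phenotypic candidate HSCs over the culture period."""
    if total_cells <= 0 or input_chsc <= 0 or not 0 <= chsc_frequency <= 1:
        raise ValueError("inputs must be positive, frequency in [0, 1]")
    return total_cells * chsc_frequency / input_chsc


# ---------------------------------------------------------------------------
# tabular interface
# ---------------------------------------------------------------------------


def read_chimerism_csv(path: str | Path) -> list[ChimerismRecord]:
    """CSV columns: recipient, lineage, test_pct, competitor_cells, input_equivalents."""
    df = pd.read_csv(path)
    return [
        ChimerismRecord(
            recipient_id=str(r.recipient),
            lineage=str(r.lineage),
            test_pct=float(r.test_pct),
            competitor_cells=float(r.competitor_cells),
            input_equivalents=float(r.input_equivalents),
        )
        for r in df.itertuples()
    ]


def ru_table(records: list[ChimerismRecord]) -> pd.DataFrame:
    """RUs for a batch of chimerism records (saturated rows get NaN RU)."""
    rows = []
    for rec in records:
        try:
            res = repopulating_units(rec)
            rows.append(
                {
                    "recipient": rec.recipient_id,
                    "lineage": rec.lineage,
                    "test_pct": rec.test_pct,
                    "ru": res.ru,
                    "ru_per_input_cell": res.ru_per_input_cell,
                    "saturated": res.saturated,
                }
            )
        except ValueError:
            rows.append(
                {
                    "recipient": rec.recipient_id,
                    "lineage": rec.lineage,
                    "test_pct": rec.test_pct,
                    "ru": np.nan,
                    "ru_per_input_cell": np.nan,
                    "saturated": True,
                }
            )
    return pd.DataFrame(rows)
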