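"""Background filtering, multi-parental exclusion and normalization.

The three documented processing rules for barcode count matrices, applied in
this fixed order:

1. **Background filter** — within each recipient, a barcode whose read
   frequency among assigned reads is strictly below a threshold (default
   0.1%, an explicitly arbitrary cut-off) is zeroed in that recipient.
2. **Multi-parental exclusion** — a barcode surviving the filter in two or
   more *parental* recipients cannot be traced to a single well (independent
   transductions with the same barcode, or an over-represented library
   member) and is removed from every recipient. Sharing between a parental
   and daughter recipients is the biological signal and is never excluded.
3. **Normalization** — each recipient's surviving counts are rescaled to sum
   to 1e6 (reads per million).

The numpy kernels (`_background_filter`, `_exclude_multi_parental`,
`_normalize`, `pooled_log_sd`) operate on bare arrays and are reused by the
heterogeneity fit's bootstrap, where thousands of pipeline passes are run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix

DEFAULT_THRESHOLD = 0.001
DEFAULT_SCALE = 1e6


# ---------------------------------------------------------------------------
# array kernels
# ---------------------------------------------------------------------------


def _background_filter(counts: np.ndarray, threshold: float) -> np.ndarray:
    """Zero entries with count/assigned_total strictly below threshold."""
    assigned = counts.sum(axis=0)
    # count/assigned < t  <=>  count < t*assigned (assigned >= 0, strict)
    return np.where(counts < threshold * assigned, 0, counts)


def _exclude_multi_parental(
    counts: np.ndarray, parental_cols: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Zero rows present (nonzero) in >= 2 parental columns; return row mask."""
    if parental_cols.sum() == 0:
        return counts, np.zeros(counts.shape[0], dtype=bool)
    n_parental = (counts[:, parental_cols] > 0).sum(axis=1)
    excluded = n_parental >= 2
    out = counts.copy()
    out[excluded, :] = 0
    return out, excluded


def _normalize(counts: np.ndarray, scale: float) -> np.ndarray:
    totals = counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(totals > 0, counts * (scale / totals), 0.0)
    return out


def pooled_log_sd(
    counts: np.ndarray,
    parental_cols: np.ndarray | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> float:
    """Pooled within-recipient SD of log clone sizes after the full pipeline.

    The raw heterogeneity statistic: filter, exclude, then take the standard
    deviation of log frequencies of surviving barcodes within each selected
    recipient (parental columns when present, else all), pooling the
    within-recipient sums of squares. Within-recipient centring makes the
    statistic invariant to normalization scale.
    """
    filt = _background_filter(counts, threshold)
    if parental_cols is None:
        parental_cols = np.zeros(counts.shape[1], dtype=bool)
    filt, _ = _exclude_multi_parental(filt, parental_cols)
    cols = np.flatnonzero(parental_cols) if parental_cols.any() else range(filt.shape[1])
    ss = 0.0
    dof = 0
    for j in cols:
        x = filt[:, j]
        x = np.log(x[x > 0].astype(float))
        if len(x) >= 2:
            ss += ((x - x.mean()) ** 2).sum()
            dof += len(x) - 1
    if dof == 0:
        return float("nan")
    return float(np.sqrt(ss / dof))


# ---------------------------------------------------------------------------
# CountMatrix-level operations
# ---------------------------------------------------------------------------


def filter_background(counts: CountMatrix, threshold: float = DEFAULT_THRESHOLD) -> CountMatrix:
    """Zero per-recipient background barcodes (frequency strictly < threshold).

    The denominator is the recipient's assigned-read total before filtering;
    a barcode may survive in one recipient and be background in another.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    filt = _background_filter(counts.counts.to_numpy(), threshold)
    df = pd.DataFrame(filt, index=counts.counts.index, columns=counts.counts.columns)
    return CountMatrix(
        counts=df,
        roles=dict(counts.roles),
        wells=dict(counts.wells),
        unassigned=dict(counts.unassigned),
    )


def exclude_multi_parental(counts: CountMatrix) -> tuple[CountMatrix, pd.DataFrame]:
    """Remove barcodes present in >= 2 parental recipients from all recipients.

    Returns the cleaned matrix and an exclusion log (barcode, reason,
    recipients). Presence is evaluated on the matrix as given — run the
    background filter first so sub-threshold spillover does not trigger
    exclusion. With no parental recipients this is a no-op (with a warning).
    """
    parentals = counts.recipients_with_role("parental")
    cols = counts.counts.columns
    parental_mask = np.array([c in parentals for c in cols])
    if not parental_mask.any():
        warnings.warn("no parental recipients; multi-parental exclusion is a no-op")
        return counts, pd.DataFrame(columns=["barcode", "reason", "recipients"])
    arr, excluded = _exclude_multi_parental(counts.counts.to_numpy(), parental_mask)
    log_rows = []
    raw = counts.counts.to_numpy()
    for i in np.flatnonzero(excluded):
        present = [c for c, m in zip(cols, parental_mask) if m and raw[i, list(cols).index(c)] > 0]
        log_rows.append(
            {
                "barcode": counts.counts.index[i],
                "reason": "multi_parental",
                "recipients": ",".join(present),
            }
        )
    df = pd.DataFrame(arr, index=counts.counts.index, columns=cols)
    out = CountMatrix(
        counts=df,
        roles=dict(counts.roles),
        wells=dict(counts.wells),
        unassigned=dict(counts.unassigned),
    )
    return out, pd.DataFrame(log_rows, columns=["barcode", "reason", "recipients"])


@dataclass
class CloneTable:
    """Filtered, normalized clone sizes with exclusion provenance.

    ``normalized`` holds reads-per-``scale`` values (default reads per 1e6);
    every recipient column with at least one kept barcode sums to ``scale``.
    ``exclusions`` records each fully removed barcode with its reason
    (``below_threshold`` with the recipients where it fell below, or
    ``multi_parental`` with the parental ids involved).
    """

    normalized: pd.DataFrame
    roles: dict[str, str]
    wells: dict[str, object] = field(default_factory=dict)
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["barcode", "reason", "recipients"])
    )
    threshold: float = DEFAULT_THRESHOLD
    scale: float = DEFAULT_SCALE

    @property
    def kept_barcodes(self) -> set[str]:
        return set(self.normalized.index[(self.normalized.to_numpy() > 0).any(axis=1)])

    @property
    def recipients(self) -> list[str]:
        return list(self.normalized.columns)

    def recipients_with_role(self, role: str) -> list[str]:
        return [r for r in self.normalized.columns if self.roles[r] == role]

    def frequencies_pct(self, role: str | None = None) -> pd.DataFrame:
        """Normalized values as percent of each recipient's total."""
        cols = self.recipients_with_role(role) if role else self.recipients
        return self.normalized[cols] * (100.0 / self.scale)

    def write_tsv(self, path: str | Path, exclusions_path: str | Path | None = None) -> None:
        path = Path(path)
        cols = list(self.normalized.columns)
        with open(path, "w") as fh:
            fh.write("#role\t" + "\t".join(self.roles[c] for c in cols) + "\n")
            fh.write("#well\t" + "\t".join(str(self.wells.get(c, "")) for c in cols) + "\n")
            fh.write(f"#threshold\t{self.threshold}\n#scale\t{self.scale}\n")
            fh.write("barcode\t" + "\t".join(cols) + "\n")
            for bc, row in self.normalized.iterrows():
                fh.write(bc + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        if exclusions_path is not None:
            self.exclusions.to_csv(exclusions_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CloneTable":
        meta: dict[str, list[str]] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, *vals = line.rstrip("\n").split("\t")
                meta[key[1:]] = vals
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        cols = list(df.columns)
        roles = dict(zip(cols, meta.get("role", ["plain"] * len(cols))))
        wells_raw = meta.get("well", [""] * len(cols))
        wells = {c: (None if w in ("", "None") else w) for c, w in zip(cols, wells_raw)}
        return cls(
            normalized=df,
            roles=roles,
            wells=wells,
            threshold=float(meta.get("threshold", [DEFAULT_THRESHOLD])[0]),
            scale=float(meta.get("scale", [DEFAULT_SCALE])[0]),
        )


def normalize(counts: CountMatrix, scale: float = DEFAULT_SCALE) -> CloneTable:
    """Rescale each recipient's surviving counts to sum to ``scale``."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    arr = counts.counts.to_numpy()
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        empty = [c for c, t in zip(counts.counts.columns, totals) if t == 0]
        warnings.warn(f"recipients with no surviving reads (rows of zeros): {empty}")
    norm = _normalize(arr, scale)
    df = pd.DataFrame(norm, index=counts.counts.index, columns=counts.counts.columns)
    return CloneTable(normalized=df, roles=dict(counts.roles), wells=dict(counts.wells), scale=scale)


def run_pipeline(
    counts: CountMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    scale: float = DEFAULT_SCALE,
) -> CloneTable:
    """filter -> multi-parental exclusion -> normalize, with provenance."""
    raw = counts.counts.to_numpy()
    filtered = filter_background(counts, threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cleaned, mp_log = exclude_multi_parental(filtered)
        table = normalize(cleaned, scale)

    # provenance: barcodes dropped entirely by the background filter
    filt_arr = filtered.counts.to_numpy()
    mp_set = set(mp_log["barcode"])
    dropped = (filt_arr == 0).all(axis=1) & (raw > 0).any(axis=1)
    rows = []
    cols = list(counts.counts.columns)
    for i in np.flatnonzero(dropped):
        bc = counts.counts.index[i]
        if bc in mp_set:
            continue
        present = [c for c, v in zip(cols, raw[i]) if v > 0]
        rows.append({"barcode": bc, "reason": "below_threshold", "recipients": ",".join(present)})
    exclusions = pd.concat(
        [pd.DataFrame(rows, columns=["barcode", "reason", "recipients"]), mp_log],
        ignore_index=True,
    )
    table.exclusions = exclusions
    table.threshold = threshold
    return table
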