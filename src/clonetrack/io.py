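"""Barcode counting and count-matrix I/O.

Reads single-end amplicon FASTQ files, extracts the variable barcode between
the constant amplicon anchors, and tallies reads per library barcode into a
:class:`CountMatrix` (barcodes x recipients). Recipients carry a role —
``parental`` (one transplant per culture well), ``daughter`` (recipients of
the pooled aliquots) or ``plain`` — which the downstream filtering pipeline
uses for the multi-parental exclusion rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .library import BarcodeLibrary

ROLES = ("parental", "daughter", "plain")


@dataclass
class CountMatrix:
    """Raw barcode read counts per recipient.

    Attributes
    ----------
    counts
        Integer DataFrame, rows indexed by barcode sequence, one column per
        recipient id.
    roles
        Recipient id -> role in ``{"parental", "daughter", "plain"}``.
    wells
        Recipient id -> culture well of origin (parental recipients only,
        else ``None``).
    unassigned
        Recipient id -> number of reads without an anchor or without a unique
        barcode match. Assigned + unassigned = total reads, always.
    """

    counts: pd.DataFrame
    roles: dict[str, str]
    wells: dict[str, object] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate barcode rows")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate recipient ids")
        for rec in self.counts.columns:
            role = self.roles.get(rec)
            if role not in ROLES:
                raise ValueError(f"recipient {rec!r} has invalid role {role!r}")
            self.unassigned.setdefault(rec, 0)
            self.wells.setdefault(rec, None)

    @property
    def recipients(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def barcodes(self) -> list[str]:
        return list(self.counts.index)

    def assigned_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def total_reads(self) -> pd.Series:
        return self.assigned_totals() + pd.Series(self.unassigned)[self.counts.columns]

    def recipients_with_role(self, role: str) -> list[str]:
        return [r for r in self.counts.columns if self.roles[r] == role]

    # -- serialisation ----------------------------------------------------
    # TSV dialect: '#role' / '#well' / '#unassigned' header lines, then a
    # 'barcode' header row and one row per barcode.

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        cols = list(self.counts.columns)
        with open(path, "w") as fh:
            fh.write("#role\t" + "\t".join(self.roles[c] for c in cols) + "\n")
            fh.write("#well\t" + "\t".join(str(self.wells.get(c, "")) for c in cols) + "\n")
            fh.write(
                "#unassigned\t" + "\t".join(str(self.unassigned.get(c, 0)) for c in cols) + "\n"
            )
            fh.write("barcode\t" + "\t".join(cols) + "\n")
            for bc, row in self.counts.iterrows():
                fh.write(bc + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
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
        wells = {c: (None if w in ("", "None") else _maybe_int(w)) for c, w in zip(cols, wells_raw)}
        unassigned = {c: int(u) for c, u in zip(cols, meta.get("unassigned", ["0"] * len(cols)))}
        return cls(counts=df, roles=roles, wells=wells, unassigned=unassigned)


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s


def _neighbor_index(library: BarcodeLibrary) -> dict[str, str | None]:
    """Map every sequence at Hamming distance 1 from a barcode to that barcode.

    Sequences reachable from two or more distinct barcodes map to ``None``
    (ambiguous -> unassigned). Exact library members are excluded; they are
    resolved by the exact lookup first.
    """
    exact = set(library.barcodes)
    nbr: dict[str, str | None] = {}
    for bc in library.barcodes:
        for i, orig in enumerate(bc):
            for base in "ACGT":
                if base == orig:
                    continue
                mut = bc[:i] + base + bc[i + 1 :]
                if mut in exact:
                    continue
                if mut in nbr and nbr[mut] != bc:
                    nbr[mut] = None
                else:
                    nbr[mut] = bc
    return nbr


def extract_barcodes(
    fastq: str | Path,
    library: BarcodeLibrary,
    recipient_id: str = "sample",
    role: str = "plain",
    well=None,
    max_mismatch: int = 0,
) -> CountMatrix:
    """Count library barcodes in one recipient's amplicon FASTQ.

    For each read the 5' anchor is located exactly (first occurrence); the
    next ``library.length`` bases are matched against the library at Hamming
    distance <= ``max_mismatch`` (0 or 1). Reads lacking the anchor, truncated
    before the barcode end, unmatched, or matching ambiguously are counted as
    unassigned.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    fastq = Path(fastq)
    exact = {bc: i for i, bc in enumerate(library.barcodes)}
    nbr = _neighbor_index(library) if max_mismatch == 1 else None
    flank5, blen = library.flank5, library.length

    tallies = np.zeros(len(library.barcodes), dtype=np.int64)
    unassigned = 0
    n_records = 0
    records = SeqIO.parse(str(fastq), "fastq")
    while True:
        try:
            rec = next(records)
        except StopIteration:
            break
        except ValueError as err:
            raise ValueError(f"malformed FASTQ record at index {n_records}: {err}") from err
        n_records += 1
        seq = str(rec.seq)
        pos = seq.find(flank5)
        if pos < 0:
            unassigned += 1
            continue
        start = pos + len(flank5)
        candidate = seq[start : start + blen]
        if len(candidate) < blen:
            unassigned += 1
            continue
        hit = exact.get(candidate)
        if hit is not None:
            tallies[hit] += 1
            continue
        if nbr is not None:
            bc = nbr.get(candidate)
            if bc is not None:
                tallies[exact[bc]] += 1
                continue
        unassigned += 1

    if n_records == 0:
        warnings.warn(f"{fastq} contains no reads; returning empty matrix")
    observed = tallies > 0
    df = pd.DataFrame(
        {recipient_id: tallies[observed]},
        index=pd.Index(np.asarray(library.barcodes)[observed], name="barcode"),
    )
    return CountMatrix(
        counts=df,
        roles={recipient_id: role},
        wells={recipient_id: well},
        unassigned={recipient_id: int(unassigned)},
    )


def merge_recipients(matrices: list[CountMatrix]) -> CountMatrix:
    """Column-union of per-recipient count matrices; absent entries are 0."""
    if not matrices:
        raise ValueError("nothing to merge")
    seen: set[str] = set()
    for m in matrices:
        dup = seen & set(m.recipients)
        if dup:
            raise ValueError(f"duplicate recipient ids: {sorted(dup)}")
        seen |= set(m.recipients)
    counts = pd.concat([m.counts for m in matrices], axis=1).fillna(0).astype(np.int64)
    counts.index.name = "barcode"
    roles: dict[str, str] = {}
    wells: dict[str, object] = {}
    unassigned: dict[str, int] = {}
    for m in matrices:
        roles.update(m.roles)
        wells.update(m.wells)
        unassigned.update(m.unassigned)
    return CountMatrix(counts=counts, roles=roles, wells=wells, unassigned=unassigned)
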