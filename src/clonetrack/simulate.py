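"""Generative model of barcoded HSC expansion cultures and amplicon sequencing.

The model mirrors the two clonal-labelling designs of the expansion study:

* **pre-culture**: five wells of 1,000 input HSCs are lentivirally barcoded at
  ~35% efficiency against an 8 bp, 5,737-barcode library, expanded, and split
  half-per-well to one dedicated "parental" recipient with the remaining
  halves pooled and divided over five shared "daughter" recipients;
* **post-culture**: a pool of 3,000 input HSCs is expanded first and barcoded
  afterwards at ~15% efficiency against a 21 bp, 10,090-barcode library, with
  four analysed recipients each receiving a tenth of the pool.

Each transduced founder is a clone. Clone sizes at harvest are i.i.d.
lognormal — a two-parameter heavy-tailed law whose spread ``sigma``
(``log_expansion_sd``) encodes the heterogeneity in per-cell expansion
potential. Cells are allocated to recipients by multinomial splitting of each
clone (so no cell is counted twice), thinned binomially by an engraftment
fraction, and sequenced with negative-binomial-style read noise: per-barcode
gamma amplification jackpots of squared-CV ``pcr_dispersion`` followed by a
multinomial draw of the total read budget. Per-base substitution errors are
applied when emitting FASTQ. All randomness descends from one integer seed
through named substreams, so identical models produce byte-identical FASTQ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix
from .library import BarcodeLibrary, post_culture_library, pre_culture_library

READ_LENGTH = 100
#: Constant stuffer downstream of the amplicon, used to pad reads to READ_LENGTH.
_FILLER = (
    "CTGCAGGCATGCAAGCTTGGCACTGGCCGTCGTTTTACAACGTCGTGACTGG"
    "GAAAACCCTGGCGTTACCCAACTTAATCGCCTTGCAGCACATCCCCCTTTCG"
)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ExpansionModel:
    """Parameters of the clonal-expansion + sequencing simulator.

    ``log_expansion_mean`` / ``log_expansion_sd`` are the lognormal location
    and spread of clone cell counts at harvest; ``sigma = 0`` gives equal
    expected clone sizes. ``engraftment_fraction`` is the probability that a
    transplanted cell contributes to the sampled read-out compartment.
    ``pcr_dispersion`` is the squared coefficient of variation of per-barcode
    amplification; 0 recovers pure multinomial read sampling.
    """

    n_wells: int = 5
    n_cells_per_well: int = 1000
    transduction_efficiency: float = 0.35
    log_expansion_mean: float = math.log(2e4)
    log_expansion_sd: float = 1.0
    engraftment_fraction: float = 0.01
    reads_per_recipient: int = 1_000_000
    pcr_dispersion: float = 0.05
    seq_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells <= 0 or self.n_cells_per_well <= 0:
            raise ValueError("well counts must be positive")
        if not 0.0 <= self.transduction_efficiency <= 1.0:
            raise ValueError("transduction_efficiency must be in [0, 1]")
        if self.log_expansion_sd < 0:
            raise ValueError("log_expansion_sd must be >= 0")
        if not 0.0 < self.engraftment_fraction <= 1.0:
            raise ValueError("engraftment_fraction must be in (0, 1]")
        if self.reads_per_recipient <= 0:
            raise ValueError("reads_per_recipient must be positive")
        if self.pcr_dispersion < 0:
            raise ValueError("pcr_dispersion must be >= 0")
        if not 0.0 <= self.seq_error_rate < 1.0:
            raise ValueError("seq_error_rate must be in [0, 1)")

    @classmethod
    def pre_culture(cls, **overrides) -> "ExpansionModel":
        """Five wells x 1,000 HSCs, 35% transduction (pre-culture design)."""
        return cls(**{
            "n_wells": 5,
            "n_cells_per_well": 1000,
            "transduction_efficiency": 0.35,
            **overrides,
        })

    @classmethod
    def post_culture(cls, **overrides) -> "ExpansionModel":
        """One pool of 3,000 founders, 15% transduction (post-culture design)."""
        return cls(**{
            "n_wells": 1,
            "n_cells_per_well": 3000,
            "transduction_efficiency": 0.15,
            **overrides,
        })


@dataclass(frozen=True)
class SplitDesign:
    """How harvested cells are divided among recipients.

    ``fractions[r][w]`` is the fraction of well ``w``'s harvest given to
    recipient ``r``; column sums must not exceed 1.
    """

    names: tuple[str, ...]
    roles: tuple[str, ...]
    fractions: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        F = self.fraction_matrix()
        if (F < 0).any():
            raise ValueError("fractions must be non-negative")
        if (F.sum(axis=0) > 1 + 1e-9).any():
            raise ValueError("per-well split fractions must sum to <= 1")
        if len(self.names) != len(self.roles) or len(self.names) != F.shape[0]:
            raise ValueError("names, roles and fractions must align")

    def fraction_matrix(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    @property
    def n_wells(self) -> int:
        return self.fraction_matrix().shape[1]

    def well_of(self, recipient: str):
        """Well of origin for a parental recipient (unique nonzero well)."""
        r = self.names.index(recipient)
        if self.roles[r] != "parental":
            return None
        nz = np.flatnonzero(self.fraction_matrix()[r] > 0)
        return int(nz[0]) if len(nz) == 1 else None

    @classmethod
    def pre_culture(cls, n_wells: int = 5, n_daughters: int = 5) -> "SplitDesign":
        """Half of each well to its parental; pooled halves split over daughters."""
        names, roles, rows = [], [], []
        for w in range(n_wells):
            names.append(f"P{w + 1}")
            roles.append("parental")
            rows.append(tuple(0.5 if i == w else 0.0 for i in range(n_wells)))
        for d in range(n_daughters):
            names.append(f"D{d + 1}")
            roles.append("daughter")
            rows.append(tuple(0.5 / n_daughters for _ in range(n_wells)))
        return cls(names=tuple(names), roles=tuple(roles), fractions=tuple(rows))

    @classmethod
    def post_culture(cls, n_recipients: int = 4, fraction_each: float = 0.1) -> "SplitDesign":
        """Equal aliquots of one pooled culture to plain recipients."""
        names = tuple(f"R{i + 1}" for i in range(n_recipients))
        return cls(
            names=names,
            roles=tuple("plain" for _ in names),
            fractions=tuple((fraction_each,) for _ in names),
        )


def default_design(model: ExpansionModel) -> SplitDesign:
    if model.n_wells == 1:
        return SplitDesign.post_culture()
    return SplitDesign.pre_culture(n_wells=model.n_wells)


def default_library(model: ExpansionModel) -> BarcodeLibrary:
    return pre_culture_library() if model.n_wells > 1 else post_culture_library()


@dataclass
class GroundTruth:
    """Per-clone truth for parameter-recovery and oracle tests.

    ``clones`` has one row per transduced clone (clone_id, well, barcode,
    harvest_cells); ``engrafted`` is a clone x recipient integer table of
    engrafted cell counts (filled by :func:`split_recipients`). Barcode
    collisions (two clones drawing one barcode) are kept, not prevented.
    """

    clones: pd.DataFrame
    engrafted: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.engrafted is not None:
            if (self.engrafted.to_numpy().sum(axis=1) > self.clones["harvest_cells"].to_numpy()).any():
                raise ValueError("engrafted cells exceed harvest cells")

    @property
    def n_collisions(self) -> int:
        """Number of barcodes carried by more than one clone."""
        vc = self.clones["barcode"].value_counts()
        return int((vc > 1).sum())

    def barcode_cells(self, recipient: str | None = None) -> pd.Series:
        """True cell count per barcode: harvest totals, or engrafted in one recipient."""
        if recipient is None:
            return self.clones.groupby("barcode")["harvest_cells"].sum()
        if self.engrafted is None:
            raise ValueError("recipients not yet split")
        df = self.clones[["barcode"]].join(self.engrafted[recipient])
        return df.groupby("barcode")[recipient].sum()

    def write_tsv(self, path: str | Path) -> None:
        if self.engrafted is None:
            raise ValueError("recipients not yet split")
        long = (
            self.clones.join(self.engrafted)
            .melt(
                id_vars=["well", "barcode", "harvest_cells"],
                var_name="recipient",
                value_name="engrafted_cells",
                ignore_index=False,
            )
            .reset_index(names="clone_id")
        )
        long.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulation operations
# ---------------------------------------------------------------------------


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_clone_sizes(model: ExpansionModel, rng=None) -> pd.DataFrame:
    """Draw founder clones and their lognormal cell counts at harvest.

    Returns a DataFrame (index clone_id) with columns well, harvest_cells and
    transduced; only transduced founders later carry barcodes.
    """
    rng = _as_rng(rng if rng is not None else [model.seed, 1])
    n = model.n_wells * model.n_cells_per_well
    wells = np.repeat(np.arange(model.n_wells), model.n_cells_per_well)
    sizes = np.rint(
        rng.lognormal(model.log_expansion_mean, model.log_expansion_sd, size=n)
    ).astype(np.int64)
    sizes = np.maximum(sizes, 0)
    transduced = rng.random(n) < model.transduction_efficiency
    return pd.DataFrame(
        {"well": wells, "harvest_cells": sizes, "transduced": transduced},
        index=pd.RangeIndex(n, name="clone_id"),
    )


def assign_barcodes(clones: pd.DataFrame, library: BarcodeLibrary, rng=None) -> GroundTruth:
    """Give each transduced clone one barcode, uniform with replacement.

    Collisions are recorded (``GroundTruth.n_collisions``), not prevented —
    the downstream multi-parental exclusion rule exists for exactly this case.
    """
    if len(library) == 0:
        raise ValueError("empty barcode library")
    rng = _as_rng(rng)
    tr = clones[clones["transduced"]].copy() if "transduced" in clones else clones.copy()
    idx = rng.integers(0, len(library), size=len(tr))
    tr["barcode"] = np.asarray(library.barcodes)[idx] if len(tr) else pd.Series(dtype=str)
    return GroundTruth(clones=tr[["well", "barcode", "harvest_cells"]])


def split_recipients(
    truth: GroundTruth,
    design: SplitDesign,
    engraftment_fraction: float,
    rng=None,
) -> GroundTruth:
    """Allocate each clone's cells to recipients and thin by engraftment.

    Cells are split multinomially according to the design's per-well
    fractions (so allocations never exceed the harvest), then each allocated
    cell engrafts independently with probability ``engraftment_fraction``.
    """
    rng = _as_rng(rng)
    sizes = truth.clones["harvest_cells"].to_numpy()
    wells = truth.clones["well"].to_numpy()
    F = design.fraction_matrix()
    alloc = _split_cells(sizes, wells, F, rng)
    engrafted = rng.binomial(alloc, engraftment_fraction)
    eng = pd.DataFrame(engrafted, index=truth.clones.index, columns=list(design.names))
    return GroundTruth(clones=truth.clones, engrafted=eng)


def _split_cells(sizes, wells, F, rng) -> np.ndarray:
    """Sequential conditional-binomial multinomial split, vectorised over clones."""
    n_rec = F.shape[0]
    out = np.zeros((len(sizes), n_rec), dtype=np.int64)
    for w in np.unique(wells):
        mask = wells == w
        remaining = sizes[mask].copy()
        p_left = 1.0
        for r in range(n_rec):
            f = F[r, w]
            if f <= 0:
                continue
            p = min(f / p_left, 1.0)
            draw = rng.binomial(remaining, p)
            out[mask, r] = draw
            remaining -= draw
            p_left -= f
    return out


def _read_counts(cells: np.ndarray, n_reads: int, dispersion: float, rng) -> np.ndarray:
    """Sequencing read counts given engrafted cells (gamma-multinomial)."""
    out = np.zeros_like(cells, dtype=np.int64)
    nz = np.flatnonzero(cells > 0)
    if len(nz) == 0:
        return out
    c = cells[nz].astype(float)
    if dispersion > 0:
        w = rng.gamma(1.0 / dispersion, dispersion * c)
        w = np.maximum(w, 1e-300)
    else:
        w = c
    out[nz] = rng.multinomial(n_reads, w / w.sum())
    return out


def _aggregate_counts(truth: GroundTruth, design: SplitDesign, model: ExpansionModel, rng):
    """Barcode x recipient engrafted-cell matrix and sampled read counts."""
    cells = truth.clones[["barcode"]].join(truth.engrafted).groupby("barcode").sum()
    reads = np.zeros_like(cells.to_numpy(), dtype=np.int64)
    for j, _rec in enumerate(cells.columns):
        reads[:, j] = _read_counts(
            cells.iloc[:, j].to_numpy(), model.reads_per_recipient, model.pcr_dispersion, rng
        )
    reads_df = pd.DataFrame(reads, index=cells.index, columns=cells.columns)
    return cells, reads_df


def _design_metadata(design: SplitDesign):
    roles = dict(zip(design.names, design.roles))
    wells = {name: design.well_of(name) for name in design.names}
    return roles, wells


def simulate_counts(
    model: ExpansionModel,
    design: SplitDesign | None = None,
    library: BarcodeLibrary | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Run the generative model down to per-recipient read counts (no FASTQ).

    This is the error-free fast path: read counts are tallied per true
    barcode directly, equivalent to extraction at ``seq_error_rate = 0``.
    """
    design = design or default_design(model)
    library = library or default_library(model)
    if design.n_wells != model.n_wells:
        raise ValueError("design and model disagree on the number of wells")
    clones = simulate_clone_sizes(model, rng=[model.seed, 1])
    truth = assign_barcodes(clones, library, rng=[model.seed, 2])
    truth = split_recipients(truth, design, model.engraftment_fraction, rng=[model.seed, 3])
    _, reads = _aggregate_counts(truth, design, model, _as_rng([model.seed, 4]))
    observed = reads.to_numpy().sum(axis=1) > 0
    roles, wells = _design_metadata(design)
    cm = CountMatrix(counts=reads.loc[observed], roles=roles, wells=wells)
    return cm, truth


def generate_reads(
    truth: GroundTruth,
    model: ExpansionModel,
    library: BarcodeLibrary,
    design: SplitDesign,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Emit one Phred+33 single-end FASTQ per recipient.

    Each read is flank5 + barcode + flank3, padded with a constant stuffer to
    100 nt, with uniform per-base substitution errors at ``seq_error_rate``.
    Per-recipient RNG substreams make output byte-identical for a given seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng_counts = _as_rng([model.seed, 4])
    cells, reads = _aggregate_counts(truth, design, model, rng_counts)
    paths: dict[str, Path] = {}
    qual = "I" * READ_LENGTH
    for j, rec in enumerate(reads.columns):
        rng = _as_rng([model.seed, 5, j])
        path = out_dir / f"{rec}.fastq"
        with open(path, "w") as fh:
            serial = 0
            for bc, n in zip(reads.index, reads.iloc[:, j].to_numpy()):
                if n == 0:
                    continue
                core = library.flank5 + bc + library.flank3
                template = (core + _FILLER)[:READ_LENGTH]
                arr0 = np.frombuffer(template.encode(), dtype=np.uint8)
                n_err = (
                    rng.binomial(READ_LENGTH, model.seq_error_rate, size=n)
                    if model.seq_error_rate > 0
                    else np.zeros(n, dtype=int)
                )
                for k in n_err:
                    if k:
                        arr = arr0.copy()
                        pos = rng.choice(READ_LENGTH, size=k, replace=False)
                        shift = rng.integers(1, 4, size=k)
                        cur = np.searchsorted(_BASES, arr[pos])
                        arr[pos] = _BASES[(cur + shift) % 4]
                        seq = arr.tobytes().decode()
                    else:
                        seq = template
                    fh.write(f"@{rec}:{serial}\n{seq}\n+\n{qual}\n")
                    serial += 1
        paths[rec] = path
    return paths


def simulate_fastq(
    model: ExpansionModel,
    out_dir: str | Path,
    design: SplitDesign | None = None,
    library: BarcodeLibrary | None = None,
) -> tuple[dict[str, Path], GroundTruth]:
    """Full experiment: clones -> barcodes -> split -> FASTQ files on disk."""
    design = design or default_design(model)
    library = library or default_library(model)
    if design.n_wells != model.n_wells:
        raise ValueError("design and model disagree on the number of wells")
    clones = simulate_clone_sizes(model, rng=[model.seed, 1])
    truth = assign_barcodes(clones, library, rng=[model.seed, 2])
    truth = split_recipients(truth, design, model.engraftment_fraction, rng=[model.seed, 3])
    paths = generate_reads(truth, model, library, design, out_dir)
    return paths, truth


# ---------------------------------------------------------------------------
# fast array path (used by the heterogeneity fit's calibration/bootstrap)
# ---------------------------------------------------------------------------


def _simulate_count_arrays(
    model: ExpansionModel,
    design: SplitDesign,
    library_size: int,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Library-size x recipients read-count array plus parental column mask.

    Pure-numpy equivalent of :func:`simulate_counts` (anonymous barcode
    indices instead of sequences); used where thousands of replicate
    simulations are needed.
    """
    rng = _as_rng(rng)
    n = model.n_wells * model.n_cells_per_well
    wells = np.repeat(np.arange(model.n_wells), model.n_cells_per_well)
    sizes = np.rint(
        rng.lognormal(model.log_expansion_mean, model.log_expansion_sd, size=n)
    ).astype(np.int64)
    transduced = rng.random(n) < model.transduction_efficiency
    sizes, wells = sizes[transduced], wells[transduced]
    bc = rng.integers(0, library_size, size=len(sizes))
    F = design.fraction_matrix()
    alloc = _split_cells(sizes, wells, F, rng)
    engrafted = rng.binomial(alloc, model.engraftment_fraction)
    n_rec = F.shape[0]
    cells = np.zeros((library_size, n_rec), dtype=np.int64)
    np.add.at(cells, bc, engrafted)
    counts = np.zeros_like(cells)
    for j in range(n_rec):
        counts[:, j] = _read_counts(cells[:, j], model.reads_per_recipient, model.pcr_dispersion, rng)
    parental = np.array([r == "parental" for r in design.roles])
    return counts, parental
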