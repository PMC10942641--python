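"""Lentiviral barcode libraries.

A barcode library is a designed set of equal-length nucleotide tags embedded
in a fixed amplicon context: every sequenced read carries a constant 5' anchor
(``flank5``), the variable barcode, and a constant 3' anchor (``flank3``).
Two library designs are bundled, mirroring the two labelling strategies of
the expansion experiments they model:

* an 8 bp library of 5,737 barcodes used to tag input HSCs *before* culture
  ("pre-culture" design), and
* a 21 bp library of 10,090 barcodes used to tag expanded cells *after*
  culture ("post-culture" design).

The bundled libraries are synthetic stand-ins generated reproducibly from
fixed seeds; they share the size and barcode length of the commercial
libraries but not their actual sequences.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = "ACGT"

#: Constant amplicon anchors placed immediately up/downstream of the barcode.
DEFAULT_FLANK5 = "ACCGGTCGCA"
DEFAULT_FLANK3 = "TGCGTCAGGT"

PRE_CULTURE_LIBRARY_SIZE = 5737
PRE_CULTURE_BARCODE_LENGTH = 8
POST_CULTURE_LIBRARY_SIZE = 10090
POST_CULTURE_BARCODE_LENGTH = 21

_PRE_LIBRARY_SEED = 804211
_POST_LIBRARY_SEED = 911533


@dataclass(frozen=True)
class BarcodeLibrary:
    """A set of unique, equal-length nucleotide barcodes with amplicon anchors."""

    barcodes: tuple[str, ...]
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ValueError("barcode library must not be empty")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"barcodes must share one length, got lengths {sorted(lengths)}")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        alphabet = set("".join(self.barcodes) + self.flank5 + self.flank3)
        if not alphabet <= set(BASES):
            raise ValueError(f"sequences restricted to {BASES}, got {sorted(alphabet - set(BASES))}")

    @property
    def length(self) -> int:
        """Barcode length in bp."""
        return len(self.barcodes[0])

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, seq: str) -> bool:
        return seq in set(self.barcodes)

    @classmethod
    def random(
        cls,
        n: int,
        length: int,
        seed: int,
        flank5: str = DEFAULT_FLANK5,
        flank3: str = DEFAULT_FLANK3,
    ) -> "BarcodeLibrary":
        """Draw ``n`` distinct random barcodes of ``length`` bp."""
        if n <= 0 or length <= 0:
            raise ValueError("n and length must be positive")
        if n > 4**length:
            raise ValueError(f"cannot draw {n} distinct {length}-mers")
        rng = np.random.default_rng(seed)
        chosen: set[str] = set()
        # rejection sampling; libraries are tiny relative to 4^length
        while len(chosen) < n:
            block = rng.integers(0, 4, size=(n - len(chosen) + 16, length))
            for row in block:
                chosen.add("".join(BASES[i] for i in row))
                if len(chosen) == n:
                    break
        return cls(barcodes=tuple(sorted(chosen)), flank5=flank5, flank3=flank3)

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"#flank5\t{self.flank5}\n#flank3\t{self.flank3}\n")
            for bc in self.barcodes:
                fh.write(bc + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BarcodeLibrary":
        flank5, flank3 = DEFAULT_FLANK5, DEFAULT_FLANK3
        barcodes: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#flank5"):
                    flank5 = line.split("\t")[1]
                elif line.startswith("#flank3"):
                    flank3 = line.split("\t")[1]
                elif not line.startswith("#"):
                    barcodes.append(line)
        return cls(barcodes=tuple(barcodes), flank5=flank5, flank3=flank3)


@functools.lru_cache(maxsize=None)
def pre_culture_library() -> BarcodeLibrary:
    """Synthetic 5,737-barcode, 8 bp library (pre-culture labelling design)."""
    return BarcodeLibrary.random(
        PRE_CULTURE_LIBRARY_SIZE, PRE_CULTURE_BARCODE_LENGTH, seed=_PRE_LIBRARY_SEED
    )


@functools.lru_cache(maxsize=None)
def post_culture_library() -> BarcodeLibrary:
    """Synthetic 10,090-barcode, 21 bp library (post-culture labelling design)."""
    return BarcodeLibrary.random(
        POST_CULTURE_LIBRARY_SIZE, POST_CULTURE_BARCODE_LENGTH, seed=_POST_LIBRARY_SEED
    )
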