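"""Genetic map container: bp/cM coordinates of tracked loci per chromosome.

The map anchors every downstream coordinate computation: meiosis simulation
(crossover placement in cM), marker density summaries (bp and cM spans), and
bp->cM interpolation for marker tables.  Coordinates are 1-based and
inclusive, following VCF convention.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["GeneticMap"]


class GeneticMap:
    """Ordered loci with physical (bp) and genetic (cM) positions.

    Parameters
    ----------
    loci :
        DataFrame with columns ``id``, ``chrom``, ``bp``, ``cM``.  Within a
        chromosome both bp and cM must be strictly increasing; cM must be
        non-negative and bp must fall inside the chromosome length.
    chrom_lengths :
        Mapping chromosome name -> length in bp.  Every chromosome that
        appears in ``loci`` must have a length.
    """

    def __init__(self, loci: pd.DataFrame, chrom_lengths: Mapping[str, int]):
        required = {"id", "chrom", "bp", "cM"}
        missing = required - set(loci.columns)
        if missing:
            raise ValueError(f"genetic map is missing columns: {sorted(missing)}")
        loci = loci[["id", "chrom", "bp", "cM"]].reset_index(drop=True)
        if loci["id"].duplicated().any():
            dupes = loci.loc[loci["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate locus ids: {dupes}")
        self.chrom_lengths: dict[str, int] = {str(c): int(n) for c, n in chrom_lengths.items()}
        for chrom, sub in loci.groupby("chrom", sort=False):
            if chrom not in self.chrom_lengths:
                raise ValueError(f"no chromosome length for {chrom!r}")
            bp = sub["bp"].to_numpy()
            cm = sub["cM"].to_numpy(dtype=float)
            if not (np.diff(bp) > 0).all():
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
            if not (np.diff(cm) >= 0).all():
                raise ValueError(f"cM positions decreasing on {chrom}")
            if (cm < 0).any():
                raise ValueError(f"negative cM position on {chrom}")
            if bp[0] < 1 or bp[-1] > self.chrom_lengths[chrom]:
                raise ValueError(f"locus outside chromosome length on {chrom}")
        # canonical order: chromosome (input order preserved) then bp
        self.loci = loci
        self._by_chrom = {c: sub.reset_index(drop=True) for c, sub in loci.groupby("chrom", sort=False)}

    # ------------------------------------------------------------------ basic
    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def chrom_loci(self, chrom: str) -> pd.DataFrame:
        try:
            return self._by_chrom[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in map") from None

    def locus_position(self, locus_id: str) -> tuple[str, int]:
        """(chrom, index-within-chromosome) of a locus id."""
        row = self.loci.index[self.loci["id"] == locus_id]
        if len(row) == 0:
            raise KeyError(f"locus {locus_id!r} not in map")
        chrom = self.loci.loc[row[0], "chrom"]
        sub = self._by_chrom[chrom]
        return chrom, int(sub.index[sub["id"] == locus_id][0])

    def chrom_cm_end(self, chrom: str) -> float:
        """Genetic length of a chromosome: the terminal mapped cM position."""
        return float(self.chrom_loci(chrom)["cM"].iloc[-1])

    def interp_cm(self, chrom: str, bp: Iterable[int]) -> np.ndarray:
        """Linear bp->cM interpolation along a chromosome's mapped loci."""
        sub = self.chrom_loci(chrom)
        return np.interp(np.asarray(list(bp), dtype=float),
                         sub["bp"].to_numpy(dtype=float),
                         sub["cM"].to_numpy(dtype=float))

    # ------------------------------------------------------------------- I/O
    @classmethod
    def from_tsv(cls, map_path, lengths_path) -> "GeneticMap":
        """Read a (id, chrom, bp, cM) map TSV and a (chrom, length_bp) TSV."""
        loci = pd.read_csv(map_path, sep="\t", comment="#")
        lengths = pd.read_csv(lengths_path, sep="\t", comment="#")
        if "id" not in loci.columns:
            loci["id"] = [f"{c}_{p}" for c, p in zip(loci["chrom"], loci["bp"])]
        return cls(loci, dict(zip(lengths["chrom"], lengths["length_bp"])))

    def to_tsv(self, map_path, lengths_path) -> None:
        self.loci.to_csv(map_path, sep="\t", index=False)
        pd.DataFrame({"chrom": list(self.chrom_lengths),
                      "length_bp": list(self.chrom_lengths.values())}
                     ).to_csv(lengths_path, sep="\t", index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneticMap({len(self._by_chrom)} chromosomes, {self.n_loci} loci)"
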