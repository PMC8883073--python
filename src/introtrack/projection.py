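"""Sparse-to-dense genotype projection via a genome-wide SNP panel.

Diagnostic markers are sparse (one every few cM), so diversity analyses of
introgression lines against resequenced accessions need a denser common
coordinate set.  The approach: partition the genome into equal-width
regions, keep within each region the variant that is homozygous in every
parent and accession and closest to the region midpoint (the dense panel),
then give each introgression line a genotype at every panel SNP by carrying
over the class (donor hom / recipient hom / het) of its nearest diagnostic
marker and instantiating the corresponding parental alleles.

The nearest-in-bp, left-on-tie rule matches the missing-fill convention of
the genotype matrix, so one spatial rule governs the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import MarkerGenotypeMatrix

ALLELE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
ALLELE_CHAR = np.array(list("ACGT"))
MISSING_ALLELE = -1

__all__ = ["DenseSNPPanel", "ProjectedGenotypeMatrix", "build_dense_panel",
           "project_genotypes"]


@dataclass
class DenseSNPPanel:
    """Genome-wide panel of homozygous SNPs, at most one per region.

    ``snps``: frame indexed by ``chrom:pos`` with chrom, pos, region_id;
    ``alleles``: same index, one column per sample, values in ACGT (each
    sample's homozygous allele at that SNP).
    """

    snps: pd.DataFrame
    alleles: pd.DataFrame

    def __post_init__(self):
        if not self.snps.index.equals(self.alleles.index):
            raise ValueError("snps and alleles must share an index")
        if self.snps.groupby("region_id").size().max() > 1:
            raise ValueError("more than one SNP in a region")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"panel positions not increasing on {chrom}")

    @property
    def samples(self) -> list[str]:
        return list(self.alleles.columns)

    def __len__(self) -> int:
        return len(self.snps)


def _hom_allele(gt: str) -> str | None:
    """The allele of a homozygous 'X/Y' call, or None if het/missing."""
    a, _, b = gt.partition("/")
    if a == b and a in ALLELE_CODE:
        return a
    return None


def build_dense_panel(variants: pd.DataFrame, n_regions: int,
                      chrom_lengths: Mapping[str, int]) -> DenseSNPPanel:
    """Build the dense panel from genome-wide variants of parents + accessions.

    ``variants`` holds chrom, pos and one ``"X/Y"`` genotype column per
    sample.  The genome (total assayed length) is cut into ``n_regions``
    equal-width windows laid chromosome by chromosome; within each window the
    candidate SNP (homozygous in *every* sample) nearest the window midpoint
    is kept, ties to the smaller bp.  Windows without candidates contribute
    nothing, so the panel size is at most ``n_regions``.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    sample_cols = [c for c in variants.columns if c not in ("chrom", "pos")]
    if not sample_cols:
        raise ValueError("variants carry no sample genotype columns")
    total = sum(chrom_lengths.values())
    width = total / n_regions

    alleles = variants[sample_cols].map(_hom_allele)
    keep = alleles.notna().all(axis=1)
    cand = variants.loc[keep, ["chrom", "pos"]].copy()
    cand_alleles = alleles.loc[keep]

    picked_rows = []
    picked_idx = []
    for chrom, sub in cand.groupby("chrom", sort=False):
        if chrom not in chrom_lengths:
            raise ValueError(f"no chromosome length for {chrom}")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        win = ((pos - 1) // width).astype(int)
        for w in np.unique(win):
            in_w = np.nonzero(win == w)[0]
            mid = w * width + width / 2
            dist = np.abs(pos[in_w] - mid)
            best = in_w[int(np.argmin(dist))]  # argmin takes first -> smaller bp on tie
            picked_rows.append({"chrom": chrom, "pos": int(pos[best]),
                                "region_id": f"{chrom}:{w}"})
            picked_idx.append(sub.index[best])
    snps = pd.DataFrame(picked_rows)
    order = snps.sort_values(["chrom", "pos"]).index
    snps = snps.loc[order].reset_index(drop=True)
    picked_idx = [picked_idx[i] for i in order]
    key = snps["chrom"] + ":" + snps["pos"].astype(str)
    snps = snps.set_axis(key, axis=0)
    panel_alleles = cand_alleles.loc[picked_idx].set_axis(key, axis=0)
    return DenseSNPPanel(snps, panel_alleles)


@dataclass
class ProjectedGenotypeMatrix:
    """Diploid genotypes of lines (plus parents/accessions) at panel SNPs.

    ``a1``/``a2`` are (n_samples, n_snps) integer allele codes (ACGT -> 0..3,
    missing/unassignable -> -1), sorted so a1 <= a2 within a cell.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    a1: np.ndarray
    a2: np.ndarray

    def __post_init__(self):
        lo = np.minimum(self.a1, self.a2)
        hi = np.maximum(self.a1, self.a2)
        self.a1, self.a2 = lo, hi

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def donor_dosage_fraction(self, donor_id: str) -> pd.Series:
        """Per-sample fraction of panel alleles identical to the donor's."""
        i = self.sample_ids.index(donor_id)
        d1 = self.a1[i][None, :]
        valid = (self.a1 >= 0)
        shared = ((self.a1 == d1).astype(int) + (self.a2 == d1).astype(int))
        frac = (shared * valid).sum(axis=1) / (2.0 * valid.sum(axis=1))
        return pd.Series(frac, index=self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Genotypes as 'X/Y' strings (samples x SNPs) for export."""
        def chars(a):
            return np.where(a >= 0, ALLELE_CHAR[np.clip(a, 0, 3)], ".")
        g = np.char.add(np.char.add(chars(self.a1).astype(str), "/"),
                        chars(self.a2).astype(str))
        return pd.DataFrame(g, index=self.sample_ids, columns=self.snps.index)


def project_genotypes(matrix: MarkerGenotypeMatrix, panel: DenseSNPPanel,
                      donor: str, recipient_samples: Mapping[str, str] | None = None,
                      carry_samples: Sequence[str] | None = None
                      ) -> ProjectedGenotypeMatrix:
    """Replace each line's marker genotypes with parental alleles at panel SNPs.

    For every line and panel SNP, the genotype class of the nearest
    diagnostic marker in bp on that chromosome (tie -> left marker) is
    transferred: class A becomes the donor's homozygote, class B the line's
    recipient-parent homozygote, H the donor/recipient heterozygote.  When
    donor and recipient carry the same allele at a SNP the cell is that
    homozygote regardless of class.  Panel samples listed in
    ``carry_samples`` (default: all panel samples) are appended unchanged.

    ``matrix`` must be missing-free (run :func:`introtrack.genotypes.fill_missing`
    first); a chromosome with no markers leaves its panel SNPs unassigned
    (missing) for the lines.  ``recipient_samples`` maps matrix recipient
    labels to panel sample ids when they differ.
    """
    if (matrix.calls.to_numpy() == "D").any():
        raise ValueError("matrix has missing calls; run fill_missing first")
    if donor not in panel.samples:
        raise ValueError(f"donor {donor!r} not a panel sample")
    rec_map = dict(recipient_samples or {})
    for lab in matrix.recipients.unique():
        sample = rec_map.get(lab, lab)
        if sample not in panel.samples:
            raise ValueError(f"recipient {lab!r} (panel sample {sample!r}) not in panel")

    n_lines = len(matrix.line_ids)
    n_snps = len(panel)
    # nearest diagnostic marker for every panel SNP
    nearest = np.full(n_snps, -1, dtype=int)
    marker_cols = np.array(matrix.marker_ids)
    marker_chrom = matrix.markers["chrom"].to_numpy()
    marker_bp = matrix.markers["bp"].to_numpy(dtype=np.int64)
    snp_chrom = panel.snps["chrom"].to_numpy()
    snp_pos = panel.snps["pos"].to_numpy(dtype=np.int64)
    for chrom in pd.unique(snp_chrom):
        snp_sel = np.nonzero(snp_chrom == chrom)[0]
        mk_sel = np.nonzero(marker_chrom == chrom)[0]
        if len(mk_sel) == 0:
            continue  # stays unassigned for lines on this chromosome
        mbp = marker_bp[mk_sel]
        k = np.searchsorted(mbp, snp_pos[snp_sel])
        k = np.clip(k, 0, len(mbp) - 1)
        left = np.clip(k - 1, 0, len(mbp) - 1)
        dl = np.abs(snp_pos[snp_sel] - mbp[left])
        dr = np.abs(mbp[k] - snp_pos[snp_sel])
        pick = np.where((k == 0) | (dr < dl), k, left)  # tie (dl == dr) -> left
        nearest[snp_sel] = mk_sel[pick]

    donor_al = panel.alleles[donor].map(ALLELE_CODE).to_numpy()
    rec_al = {lab: panel.alleles[rec_map.get(lab, lab)].map(ALLELE_CODE).to_numpy()
              for lab in matrix.recipients.unique()}

    a1 = np.full((n_lines, n_snps), MISSING_ALLELE, dtype=np.int8)
    a2 = np.full((n_lines, n_snps), MISSING_ALLELE, dtype=np.int8)
    calls = matrix.calls.to_numpy()
    assigned = nearest >= 0
    cls = np.empty((n_lines, n_snps), dtype="<U1")
    cls[:, assigned] = calls[:, nearest[assigned]]
    for i, line in enumerate(matrix.line_ids):
        r = rec_al[matrix.recipients.iloc[i]]
        row_cls = cls[i]
        is_a = assigned & (row_cls == "A")
        is_b = assigned & (row_cls == "B")
        is_h = assigned & (row_cls == "H")
        a1[i, is_a] = donor_al[is_a]
        a2[i, is_a] = donor_al[is_a]
        a1[i, is_b] = r[is_b]
        a2[i, is_b] = r[is_b]
        a1[i, is_h] = np.minimum(donor_al[is_h], r[is_h])
        a2[i, is_h] = np.maximum(donor_al[is_h], r[is_h])

    carry = list(panel.samples) if carry_samples is None else list(carry_samples)
    carry_codes = np.stack([panel.alleles[s].map(ALLELE_CODE).to_numpy() for s in carry]) \
        if carry else np.empty((0, n_snps), dtype=np.int8)
    samples = list(matrix.line_ids) + carry
    A1 = np.vstack([a1, carry_codes]).astype(np.int8)
    A2 = np.vstack([a2, carry_codes]).astype(np.int8)
    return ProjectedGenotypeMatrix(samples, panel.snps.copy(), A1, A2)
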