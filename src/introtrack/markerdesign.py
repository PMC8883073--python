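"""Selection of subgenome-diagnostic SNP markers from parental variant tables.

The marker-design problem: in an allotetraploid recipient (AABB) receiving
chromatin from a diploid donor (AA), a useful diagnostic marker must
distinguish the donor's A-genome allele from the recipient's A-subgenome
allele while never cross-amplifying the B-subgenome homoeolog.  Candidate
loci therefore have to be homozygous and fixed-different between donor and
recipients, match the donor reference, be uniform across all recipient
accessions, carry no flanking variation that would break assay primers, and
have no homologous region in the B-progenitor genome.  A final spacing pass
selects an evenly distributed subset per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genmap import GeneticMap

HOM_REF = "0/0"
HOM_ALT = "1/1"
HET = "0/1"
GT_MISSING = "./."
VALID_GTS = {HOM_REF, HOM_ALT, HET, GT_MISSING}

__all__ = [
    "ParentalVariantTable",
    "DiagnosticMarker",
    "DistributionStats",
    "filter_a_genome_diagnostic",
    "filter_b_genome_detection",
    "select_evenly_spaced",
    "distribution_stats",
    "genome_wide_means",
    "find_gaps",
]


class ParentalVariantTable:
    """Per-locus parental genotypes and assay-design annotations.

    ``variants`` is indexed by locus key ``"chrom:pos"`` and carries:

    - ``chrom``, ``pos``, ``ref``, ``alt``: coordinates and alleles against
      the donor-side (B. rapa) reference;
    - ``gt_donor`` plus one ``gt_<recipient>`` column per recipient:
      VCF-style diploid genotypes (``0/0``, ``1/1``, ``0/1``, ``./.``);
    - optional ``bjub_<recipient>`` columns: the allele observed at the
      B-subgenome homoeolog of the locus in each recipient;
    - boolean flags ``flag_flanking_variation`` (variation within the 100-bp
      flanking region) and ``flag_nigra_hit`` (homologous region in the
      B-progenitor genome), both derived upstream from alignments.

    An optional ``annotations`` frame (same index) records ground-truth
    criterion violations for simulated tables.
    """

    def __init__(self, variants: pd.DataFrame, recipients: Sequence[str],
                 annotations: pd.DataFrame | None = None):
        needed = {"chrom", "pos", "ref", "alt", "gt_donor"}
        missing = needed - set(variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        self.recipients = list(recipients)
        for r in self.recipients:
            if f"gt_{r}" not in variants.columns:
                raise ValueError(f"variant table missing genotype column gt_{r}")
        if variants.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate chrom:pos in variant table")
        key = variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
        self.variants = variants.set_axis(key, axis=0)
        self.annotations = None if annotations is None else annotations.set_axis(key, axis=0)

    @property
    def gt_columns(self) -> list[str]:
        return ["gt_donor"] + [f"gt_{r}" for r in self.recipients]

    @property
    def bjub_columns(self) -> list[str]:
        return [c for c in self.variants.columns if c.startswith("bjub_")]

    def __len__(self) -> int:
        return len(self.variants)

    # ------------------------------------------------------------------- I/O
    def to_vcf(self, path, annotations_path=None) -> None:
        """Write a minimal VCF (GT-only) plus a sidecar annotation TSV.

        Samples are the donor followed by the recipients; flags and homoeolog
        alleles travel in the sidecar, keyed by chrom:pos.
        """
        v = self.variants
        samples = ["donor"] + list(self.recipients)
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples) + "\n")
            for key, row in v.iterrows():
                gts = "\t".join(row["gt_donor" if s == "donor" else f"gt_{s}"] for s in samples)
                fh.write(f"{row['chrom']}\t{row['pos']}\t{key}\t{row['ref']}\t{row['alt']}"
                         f"\t.\tPASS\t.\tGT\t{gts}\n")
        if annotations_path is not None:
            side_cols = [c for c in v.columns
                         if c.startswith(("flag_", "bjub_"))]
            side = v[["chrom", "pos"] + side_cols].copy()
            if self.annotations is not None:
                side = side.join(self.annotations)
            side.to_csv(annotations_path, sep="\t", index_label="locus")

    @classmethod
    def from_vcf(cls, vcf_path, annotations_path) -> "ParentalVariantTable":
        """Read the minimal VCF + sidecar written by :meth:`to_vcf`."""
        rows = []
        with open(vcf_path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                if line.startswith("#CHROM"):
                    samples = line.rstrip("\n").split("\t")[9:]
                    continue
                f = line.rstrip("\n").split("\t")
                rec = {"chrom": f[0], "pos": int(f[1]), "ref": f[3], "alt": f[4]}
                for s, gt in zip(samples, f[9:]):
                    rec["gt_donor" if s == "donor" else f"gt_{s}"] = gt
                rows.append(rec)
        variants = pd.DataFrame(rows)
        recipients = [s for s in samples if s != "donor"]
        side = pd.read_csv(annotations_path, sep="\t", comment="#").set_index("locus")
        side = side.drop(columns=["chrom", "pos"])
        flag_cols = [c for c in side.columns if c.startswith(("flag_", "bjub_"))]
        ann_cols = [c for c in side.columns if c not in flag_cols]
        key = variants["chrom"].astype(str) + ":" + variants["pos"].astype(str)
        variants = variants.set_axis(key, axis=0).join(side[flag_cols]).reset_index(drop=True)
        ann = side[ann_cols] if ann_cols else None
        return cls(variants, recipients, annotations=ann)


@dataclass(frozen=True)
class DiagnosticMarker:
    """A selected subgenome-diagnostic SNP marker."""

    id: str
    chrom: str
    bp: int
    cM: float
    donor_allele: str
    recipient_allele: str

    def __post_init__(self):
        if self.donor_allele == self.recipient_allele:
            raise ValueError(f"marker {self.id}: donor and recipient alleles identical")


def _is_hom(gt: pd.Series) -> pd.Series:
    return gt.isin([HOM_REF, HOM_ALT])


def filter_a_genome_diagnostic(table: ParentalVariantTable) -> pd.Index:
    """Loci usable as donor-vs-recipient A-genome diagnostic markers.

    Keeps exactly the loci that are (i) homozygous in the donor and every
    recipient, (ii) identical between the donor and the reference, (iii)
    polymorphic between donor and recipients, (iv) uniform across recipient
    accessions, (v) free of flanking variation within 100 bp and (vi) without
    a homologous region in the B-progenitor genome.  Even spacing along
    chromosomes is a separate step (:func:`select_evenly_spaced`).
    """
    v = table.variants
    for col in ("flag_flanking_variation", "flag_nigra_hit"):
        if col not in v.columns:
            raise ValueError(f"variant table missing annotation column: {col}")
    rec_cols = [f"gt_{r}" for r in table.recipients]
    hom_all = _is_hom(v["gt_donor"])
    for c in rec_cols:
        hom_all &= _is_hom(v[c])
    donor_ref = v["gt_donor"] == HOM_REF
    uniform_rec = v[rec_cols].nunique(axis=1) == 1
    polymorphic = v[rec_cols[0]] != v["gt_donor"]
    keep = (hom_all & donor_ref & uniform_rec & polymorphic
            & ~v["flag_flanking_variation"] & ~v["flag_nigra_hit"])
    return v.index[keep]


def filter_b_genome_detection(table: ParentalVariantTable) -> pd.Index:
    """Loci usable to assay B-genome presence via A/B homoeolog contrast.

    Keeps loci uniform between donor and recipient A subgenomes but
    polymorphic between the A-site allele and the B-subgenome homoeolog,
    with all recipients homozygous at the A site and uniform at the
    homoeolog.
    """
    v = table.variants
    bjub_cols = table.bjub_columns
    if not bjub_cols:
        raise ValueError("variant table has no bjub_* homoeolog columns")
    rec_cols = [f"gt_{r}" for r in table.recipients]
    hom_all = _is_hom(v["gt_donor"])
    for c in rec_cols:
        hom_all &= _is_hom(v[c])
    uniform_a = (v[rec_cols].nunique(axis=1) == 1) & (v[rec_cols[0]] == v["gt_donor"])
    uniform_b = v[bjub_cols].nunique(axis=1) == 1
    a_allele = np.where(v["gt_donor"] == HOM_REF, v["ref"], v["alt"])
    b_contrast = v[bjub_cols[0]].to_numpy() != a_allele
    keep = hom_all & uniform_a & uniform_b & b_contrast
    return v.index[keep]


def _marker_id(chrom: str, bp: int, taken: set[str]) -> str:
    """Marker ids in <chrom>_<index> style; index derives from bp (100-kb units)."""
    base = f"{chrom}_{bp // 100_000}"
    mid, k = base, 1
    while mid in taken:
        mid = f"{base}.{k}"
        k += 1
    taken.add(mid)
    return mid


def select_evenly_spaced(table: ParentalVariantTable, candidates: Iterable[str],
                         targets: Mapping[str, int], gmap: GeneticMap
                         ) -> list[DiagnosticMarker]:
    """Greedy maximin selection of evenly spaced markers per chromosome.

    Seeds each chromosome with the two candidates closest to its ends, then
    repeatedly adds the candidate maximising its minimum bp distance to the
    already-chosen set, until the per-chromosome target count is reached.
    Distance ties are broken toward the smaller bp position, making the
    selection deterministic.
    """
    v = table.variants.loc[list(candidates)]
    markers: list[DiagnosticMarker] = []
    taken: set[str] = set()
    for chrom, sub in v.groupby("chrom", sort=False):
        target = targets.get(chrom, 0)
        if target == 0:
            continue
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if target > len(pos):
            raise ValueError(f"target {target} exceeds {len(pos)} candidates on {chrom}")
        length = gmap.chrom_lengths.get(chrom)
        if length is None:
            raise ValueError(f"no chromosome length for {chrom}")
        if target == 1:
            chosen = [int(np.argmin(np.abs(pos - (length + 1) / 2)))]
        else:
            left = int(np.argmin(pos - 1))          # closest to chromosome start
            right = int(np.argmax(pos))             # closest to chromosome end
            chosen = [left] if left == right else [left, right]
            while len(chosen) < target:
                free = [i for i in range(len(pos)) if i not in chosen]
                dmin = np.array([min(abs(pos[i] - pos[j]) for j in chosen) for i in free])
                best = free[int(np.argmax(dmin))]   # argmax takes first -> smaller bp on tie
                chosen.append(best)
        for i in sorted(chosen):
            row = sub.iloc[i]
            donor = row["ref"] if row["gt_donor"] == HOM_REF else row["alt"]
            rec_gt = row[f"gt_{table.recipients[0]}"]
            recip = row["ref"] if rec_gt == HOM_REF else row["alt"]
            cm = float(gmap.interp_cm(chrom, [row["pos"]])[0])
            markers.append(DiagnosticMarker(_marker_id(chrom, int(row["pos"]), taken),
                                            chrom, int(row["pos"]), cm, donor, recip))
    return markers


def markers_to_frame(markers: Sequence[DiagnosticMarker]) -> pd.DataFrame:
    """Marker table (id-indexed) with chrom, bp, cM and parental alleles."""
    return pd.DataFrame(
        {"chrom": [m.chrom for m in markers], "bp": [m.bp for m in markers],
         "cM": [m.cM for m in markers],
         "donor_allele": [m.donor_allele for m in markers],
         "recipient_allele": [m.recipient_allele for m in markers]},
        index=pd.Index([m.id for m in markers], name="marker_id"),
    )


@dataclass
class DistributionStats:
    """Per-chromosome marker distribution and genome-wide means.

    Two density variants are reported: length-based (chromosome length /
    marker count) and span-based (marker bp span / (count - 1)); the genetic
    interval is the cM span / (count - 1).  Genome-wide values are arithmetic
    means of the per-chromosome values (chromosomes lacking a defined value
    are excluded from that mean).
    """

    per_chromosome: pd.DataFrame
    genome_wide: pd.Series = field(init=False)

    def __post_init__(self):
        num = self.per_chromosome.drop(columns=["n_markers"], errors="ignore")
        gw = num.mean(axis=0, skipna=True)
        gw["n_markers"] = self.per_chromosome["n_markers"].sum()
        self.genome_wide = gw


def distribution_stats(markers: pd.DataFrame | Sequence[DiagnosticMarker],
                       chrom_lengths: Mapping[str, int],
                       gmap: GeneticMap | None = None) -> DistributionStats:
    """Summarise the physical and genetic distribution of selected markers.

    ``markers`` is either a frame with chrom/bp/cM columns or a list of
    :class:`DiagnosticMarker`.  Chromosomes with fewer than two markers get
    NaN for the span-based quantities.
    """
    if not isinstance(markers, pd.DataFrame):
        markers = markers_to_frame(markers)
    rows = {}
    for chrom, sub in markers.groupby("chrom", sort=False):
        n = len(sub)
        length = chrom_lengths[chrom]
        rec = {"n_markers": n,
               "length_bp": length,
               "density_length_mb": length / n / 1e6,
               "density_span_mb": np.nan,
               "genetic_interval_cm": np.nan}
        if n >= 2:
            rec["density_span_mb"] = (sub["bp"].max() - sub["bp"].min()) / (n - 1) / 1e6
            if "cM" in sub:
                rec["genetic_interval_cm"] = (sub["cM"].max() - sub["cM"].min()) / (n - 1)
        rows[chrom] = rec
    per_chrom = pd.DataFrame.from_dict(rows, orient="index")
    return DistributionStats(per_chrom)


def genome_wide_means(per_chromosome: pd.DataFrame) -> pd.Series:
    """Genome-wide summary of externally supplied per-chromosome values.

    Takes a frame of per-chromosome statistics (e.g. a published density /
    genetic-distance table) and returns the arithmetic mean of each numeric
    column — the convention used for genome-wide average marker density and
    genetic interval.
    """
    return per_chromosome.select_dtypes("number").mean(axis=0)


def find_gaps(markers: pd.DataFrame | Sequence[DiagnosticMarker], gmap: GeneticMap,
              threshold_cm: float) -> pd.DataFrame:
    """Marker-free genetic intervals longer than ``threshold_cm``.

    Scans consecutive marker cM positions per chromosome, including the
    leading interval from 0 cM to the first marker and the trailing interval
    from the last marker to the chromosome's terminal mapped cM.  Returns a
    frame with chrom, start/end cM, span and kind (leading/internal/trailing).
    """
    if not isinstance(markers, pd.DataFrame):
        markers = markers_to_frame(markers)
    gaps = []
    for chrom, sub in markers.groupby("chrom", sort=False):
        cm = np.sort(sub["cM"].to_numpy(dtype=float))
        end = gmap.chrom_cm_end(chrom)
        edges = np.concatenate([[0.0], cm, [end]])
        kinds = ["leading"] + ["internal"] * (len(cm) - 1) + ["trailing"]
        for (a, b), kind in zip(zip(edges[:-1], edges[1:]), kinds):
            if b - a > threshold_cm:
                gaps.append({"chrom": chrom, "start_cm": a, "end_cm": b,
                             "span_cm": b - a, "kind": kind})
    return pd.DataFrame(gaps, columns=["chrom", "start_cm", "end_cm", "span_cm", "kind"])
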