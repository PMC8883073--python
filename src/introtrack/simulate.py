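"""Crossing-scheme simulation: founders, meiosis, BC1S1 populations, fixtures.

This module generates every synthetic input the rest of the pipeline
consumes.  Only the diploid A (sub)genome is simulated: the donor is a
diploid AA species and the recipient an allotetraploid whose A subgenome is
what the diagnostic markers interrogate; B-genome presence is an assay
question, not a segregation one, so B chromosomes are not modelled.

Meiosis follows a no-interference (Haldane) model: the number of crossovers
per chromosome is Poisson with mean equal to the chromosome's map length in
Morgans, and crossover positions are uniform on the cM axis.  Between two
loci d cM apart this yields the Haldane recombination fraction
(1 - exp(-2d/100)) / 2.

Selection (e.g. self-incompatibility loci dragging the population toward
the recipient genotype) is modelled as zygotic fitness reweighting at named
loci, applied at every post-F1 generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .genotypes import MarkerGenotypeMatrix
from .markerdesign import (HET, HOM_ALT, HOM_REF, ParentalVariantTable)

STEPS = ("make_f1", "backcross_to_recipient", "self")

__all__ = [
    "FounderGenome",
    "SelectionEntry",
    "CrossSpec",
    "SimulatedPopulation",
    "simulate_meiosis",
    "simulate_gametes",
    "run_cross",
    "genotype_population",
    "simulate_parental_variants",
    "simulate_accession_variants",
    "demo_map",
]


# ---------------------------------------------------------------------------
# founders and cross specification
# ---------------------------------------------------------------------------

@dataclass
class FounderGenome:
    """A fully homozygous (inbred) founder: two identical haplotypes per chromosome.

    ``haplotypes[chrom]`` is a (2, n_loci) integer array of allele codes at
    the tracked loci of that chromosome.
    """

    label: str
    haplotypes: dict[str, np.ndarray]

    def __post_init__(self):
        for chrom, h in self.haplotypes.items():
            h = np.asarray(h, dtype=np.int8)
            if h.ndim != 2 or h.shape[0] != 2:
                raise ValueError(f"{self.label}/{chrom}: haplotypes must be (2, n_loci)")
            if not (h[0] == h[1]).all():
                raise ValueError(f"founder {self.label} is not homozygous on {chrom}")
            self.haplotypes[chrom] = h

    @classmethod
    def inbred(cls, label: str, gmap: GeneticMap, allele: int) -> "FounderGenome":
        """Founder carrying a single allele code at every mapped locus."""
        haps = {c: np.full((2, len(gmap.chrom_loci(c))), allele, dtype=np.int8)
                for c in gmap.chroms}
        return cls(label, haps)


@dataclass(frozen=True)
class SelectionEntry:
    """Zygotic fitness weights at one locus, keyed by genotype class A/H/B."""

    locus: str
    fitness: Mapping[str, float]

    def __post_init__(self):
        w = {k: float(self.fitness.get(k, 1.0)) for k in ("A", "H", "B")}
        if any(x < 0 for x in w.values()):
            raise ValueError(f"negative fitness weight at {self.locus}")
        if all(x == 0 for x in w.values()):
            raise ValueError(f"all-zero fitness weights at {self.locus}")
        object.__setattr__(self, "fitness", w)


@dataclass(frozen=True)
class CrossSpec:
    """Declarative crossing scheme: ordered steps, optional selection, size, seed."""

    steps: tuple[str, ...]
    n: int = 1
    selection: tuple[SelectionEntry, ...] = ()
    seed: int | None = None

    def __post_init__(self):
        if not self.steps or self.steps[0] != "make_f1":
            raise ValueError("first step must be make_f1")
        for s in self.steps:
            if s not in STEPS:
                raise ValueError(f"unknown step {s!r}; valid steps: {STEPS}")
        if self.n < 1:
            raise ValueError("population size must be >= 1")

    @classmethod
    def bc1s1(cls, n: int, seed: int | None = None,
              selection: Sequence[SelectionEntry] = ()) -> "CrossSpec":
        """The standard scheme: F1 = donor x recipient, backcross, one selfing."""
        return cls(("make_f1", "backcross_to_recipient", "self"), n=n,
                   selection=tuple(selection), seed=seed)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _gametes_chrom(haps: np.ndarray, cm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent for a batch of parents on one chromosome.

    ``haps`` is (n, 2, L); returns (n, L).  Crossover counts are Poisson with
    mean = terminal cM / 100 (Morgans); positions uniform on [0, terminal cM];
    the starting chromatid is chosen fairly, and the chromatid in play flips
    at each crossover (parity rule).
    """
    n, _, L = haps.shape
    cm_end = float(cm[-1]) if L else 0.0
    k = rng.poisson(cm_end / 100.0, size=n)
    start = rng.integers(0, 2, size=n)
    kmax = int(k.max()) if n else 0
    if kmax == 0:
        hap_idx = np.broadcast_to(start[:, None], (n, L))
    else:
        pos = rng.uniform(0.0, cm_end, size=(n, kmax))
        valid = np.arange(kmax)[None, :] < k[:, None]
        crossings = ((pos[:, :, None] < cm[None, None, :]) & valid[:, :, None]).sum(axis=1)
        hap_idx = (start[:, None] + crossings) % 2
    return np.take_along_axis(haps, hap_idx[:, None, :], axis=1)[:, 0, :]


def simulate_gametes(parent: Mapping[str, np.ndarray], gmap: GeneticMap,
                     n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """``n`` independent gametes from one diploid parent, per chromosome (n, L)."""
    out = {}
    for chrom in gmap.chroms:
        if chrom not in parent:
            raise ValueError(f"parent has no haplotypes for chromosome {chrom}")
        h = np.asarray(parent[chrom])
        L = len(gmap.chrom_loci(chrom))
        if h.shape != (2, L):
            raise ValueError(f"{chrom}: expected haplotypes (2, {L}), got {h.shape}")
        cm = gmap.chrom_loci(chrom)["cM"].to_numpy(dtype=float)
        batch = np.broadcast_to(h, (n, 2, L))
        out[chrom] = _gametes_chrom(batch, cm, rng)
    return out


def simulate_meiosis(parent: Mapping[str, np.ndarray], gmap: GeneticMap,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Produce one gamete (haplotype per chromosome) from a diploid parent.

    ``parent[chrom]`` is a (2, n_loci) array over the map's loci of that
    chromosome.  The gamete is a crossover mosaic of the two parental
    haplotypes under the Haldane model.
    """
    return {c: g[0] for c, g in simulate_gametes(parent, gmap, 1, rng).items()}


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPopulation:
    """Diploid individuals over the map's loci, with known founder origin.

    ``haplotypes[chrom]`` is (n, 2, n_loci) of allele codes; because founders
    are homozygous with distinct codes at polymorphic loci, every allele is
    attributable to its founder.
    """

    gmap: GeneticMap
    haplotypes: dict[str, np.ndarray]
    donor: FounderGenome
    recipient: FounderGenome
    generation: str
    spec: CrossSpec | None = None

    @property
    def n(self) -> int:
        first = next(iter(self.haplotypes.values()))
        return first.shape[0]

    def genotype_classes(self) -> pd.DataFrame:
        """True genotype class (A/B/H) per individual at every mapped locus."""
        cols, data = [], []
        for chrom in self.gmap.chroms:
            haps = self.haplotypes[chrom]
            d = self.donor.haplotypes[chrom][0][None, None, :]
            from_donor = (haps == d).sum(axis=1)  # 0, 1 or 2 donor alleles
            data.append(from_donor)
            cols.extend(self.gmap.chrom_loci(chrom)["id"])
        dosage = np.concatenate(data, axis=1)
        classes = np.array(["B", "H", "A"])[dosage]
        return pd.DataFrame(classes, columns=cols,
                            index=[f"IL{i + 1:04d}" for i in range(dosage.shape[0])])

    def allele_counts(self, chrom: str, locus_index: int) -> dict[int, int]:
        col = self.haplotypes[chrom][:, :, locus_index]
        vals, counts = np.unique(col, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _locus_dosage(haplotypes, donor, chrom, idx) -> np.ndarray:
    d = donor.haplotypes[chrom][0, idx]
    return (haplotypes[chrom][:, :, idx] == d).sum(axis=1)


def run_cross(spec: CrossSpec, donor: FounderGenome, recipient: FounderGenome,
              gmap: GeneticMap) -> SimulatedPopulation:
    """Execute a crossing scheme and return the resulting population.

    Deterministic for a fixed (spec, seed).  Selection entries reweight
    offspring genotype frequencies at their locus at every post-F1 step via
    rejection sampling against the stated zygotic fitness weights.
    """
    for e in spec.selection:
        gmap.locus_position(e.locus)  # raises if the locus is not tracked
    distinct = any((donor.haplotypes[c][0] != recipient.haplotypes[c][0]).any()
                   for c in gmap.chroms)
    if not distinct:
        raise ValueError("donor and recipient founders are identical at all loci")
    rng = np.random.default_rng(spec.seed)
    cm = {c: gmap.chrom_loci(c)["cM"].to_numpy(dtype=float) for c in gmap.chroms}
    n = spec.n
    state: dict[str, np.ndarray] = {}
    for step in spec.steps:
        if step == "make_f1":
            def make(idx):
                out = {}
                for c in gmap.chroms:
                    out[c] = np.stack([np.tile(donor.haplotypes[c][0], (len(idx), 1)),
                                       np.tile(recipient.haplotypes[c][0], (len(idx), 1))],
                                      axis=1).astype(np.int8)
                return out
        elif step == "backcross_to_recipient":
            parents = state

            def make(idx, parents=parents):
                out = {}
                for c in gmap.chroms:
                    gam = _gametes_chrom(parents[c][idx], cm[c], rng)
                    rec = np.tile(recipient.haplotypes[c][0], (len(idx), 1))
                    out[c] = np.stack([gam, rec], axis=1).astype(np.int8)
                return out
        else:  # self
            parents = state

            def make(idx, parents=parents):
                out = {}
                for c in gmap.chroms:
                    g1 = _gametes_chrom(parents[c][idx], cm[c], rng)
                    g2 = _gametes_chrom(parents[c][idx], cm[c], rng)
                    out[c] = np.stack([g1, g2], axis=1).astype(np.int8)
                return out

        if spec.selection and step != "make_f1":
            state = _selection_loop(make, spec, gmap, donor, rng, n)
        else:
            state = make(np.arange(n))
    return SimulatedPopulation(gmap, state, donor, recipient,
                               generation="x".join(spec.steps), spec=spec)


def _selection_loop(make, spec, gmap, donor, rng, n, max_rounds=10_000):
    sel = [(e, *gmap.locus_position(e.locus)) for e in spec.selection]
    offspring = make(np.arange(n))
    pending = np.arange(n)
    for _ in range(max_rounds):
        accept_p = np.ones(len(pending))
        for entry, chrom, idx in sel:
            dosage = _locus_dosage(offspring, donor, chrom, idx)[pending]
            w = np.array([entry.fitness["B"], entry.fitness["H"], entry.fitness["A"]])
            accept_p *= w[dosage] / w.max()
        keep = rng.random(len(pending)) <= accept_p
        pending = pending[~keep]
        if len(pending) == 0:
            return offspring
        redo = make(pending)
        for chrom in offspring:
            offspring[chrom][pending] = redo[chrom]
    raise RuntimeError("selection rejection sampling did not converge; "
                       "check that non-zero-fitness genotypes are reachable")


# ---------------------------------------------------------------------------
# genotyping (assay emulation)
# ---------------------------------------------------------------------------

def genotype_population(pop: SimulatedPopulation, marker_loci: Sequence[str],
                        missing_rate: float = 0.0, error_rate: float = 0.0,
                        rng: np.random.Generator | None = None) -> MarkerGenotypeMatrix:
    """Assay a simulated population at marker loci, with missing calls and errors.

    Each true genotype class (A/B/H) is independently replaced by a uniformly
    random wrong class with probability ``error_rate`` and by the missing
    code ``D`` with probability ``missing_rate`` (a call hit by both events
    is missing).
    """
    if not (0 <= missing_rate < 1 and 0 <= error_rate < 1):
        raise ValueError("missing_rate and error_rate must be in [0, 1)")
    rng = rng if rng is not None else np.random.default_rng()
    truth = pop.genotype_classes()
    absent = [m for m in marker_loci if m not in truth.columns]
    if absent:
        raise ValueError(f"marker loci not tracked by the map: {absent}")
    calls = truth[list(marker_loci)].to_numpy().copy()
    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        shift = rng.integers(1, 3, size=calls.shape)  # wrong code, uniform over the other two
        codes = np.array(["A", "B", "H"])
        code_idx = np.searchsorted(codes, calls)
        calls = np.where(err, codes[(code_idx + shift) % 3], calls)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = "D"
    meta = pop.gmap.loci.set_index("id").loc[list(marker_loci), ["chrom", "bp"]]
    meta.index.name = "marker_id"
    cdf = pd.DataFrame(calls, index=truth.index, columns=list(marker_loci))
    recipients = pd.Series(pop.recipient.label, index=truth.index)
    return MarkerGenotypeMatrix(cdf, meta, recipients)


# ---------------------------------------------------------------------------
# fixture generators: parental variant tables and dense accession variants
# ---------------------------------------------------------------------------

_NUCS = np.array(list("ACGT"))

DEFAULT_VIOLATION_RATES = {
    "het_parent": 0.0,          # (i)  a parent is heterozygous
    "ref_mismatch": 0.0,        # (ii) donor differs from the donor-side reference
    "monomorphic": 0.0,         # (iii) donor and recipients share the allele
    "recipient_nonuniform": 0.0,  # (iv) recipients disagree among themselves
    "flanking_variation": 0.0,  # (v)  variation within the 100-bp flanking region
    "nigra_hit": 0.0,           # (vi) homologous region in the B-progenitor genome
    "bjub_equal_a": 0.0,        # B-detection: homoeolog allele equals the A allele
    "bjub_nonuniform": 0.0,     # B-detection: recipients disagree at the homoeolog
}


def simulate_parental_variants(n_loci: int,
                               violation_rates: Mapping[str, float] | None = None,
                               rng: np.random.Generator | None = None,
                               recipients: Sequence[str] = ("R1", "R2", "R3"),
                               chroms: Mapping[str, int] | None = None
                               ) -> ParentalVariantTable:
    """Generate a parental variant table with planted filter violations.

    Each locus independently violates each marker-design criterion with the
    given rate; the resulting table is annotated with the ground-truth
    violation set (``annotations`` frame, columns ``viol_*``, ``pass_a``,
    ``pass_b``), enabling exact expected-survivor computation in tests.
    """
    rates = dict(DEFAULT_VIOLATION_RATES)
    if violation_rates:
        unknown = set(violation_rates) - set(rates)
        if unknown:
            raise ValueError(f"unknown violation rates: {sorted(unknown)}")
        rates.update(violation_rates)
    if any(not (0 <= r <= 1) for r in rates.values()):
        raise ValueError("violation rates must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    chroms = chroms or {"A01": 30_000_000, "A02": 30_000_000, "A03": 30_000_000}
    chrom_names = list(chroms)

    which = rng.integers(0, len(chrom_names), size=n_loci)
    rows = []
    ann_rows = []
    used_pos: dict[str, set[int]] = {c: set() for c in chrom_names}
    for i in range(n_loci):
        chrom = chrom_names[which[i]]
        while True:
            pos = int(rng.integers(1, chroms[chrom] + 1))
            if pos not in used_pos[chrom]:
                used_pos[chrom].add(pos)
                break
        ref, alt = rng.choice(4, size=2, replace=False)
        ref, alt = _NUCS[ref], _NUCS[alt]
        viol = {k: bool(rng.random() < rates[k]) for k in rates}

        gt_donor = HOM_ALT if viol["ref_mismatch"] else HOM_REF
        rec_gt = gt_donor if viol["monomorphic"] else (HOM_REF if gt_donor == HOM_ALT else HOM_ALT)
        gts = {r: rec_gt for r in recipients}
        if viol["recipient_nonuniform"] and len(recipients) > 1:
            odd = recipients[int(rng.integers(0, len(recipients)))]
            gts[odd] = HOM_REF if rec_gt == HOM_ALT else HOM_ALT
        if viol["het_parent"]:
            victim = int(rng.integers(0, len(recipients) + 1))
            if victim == 0:
                gt_donor = HET
            else:
                gts[recipients[victim - 1]] = HET

        a_allele = ref if gt_donor == HOM_REF else alt
        b_allele = a_allele if viol["bjub_equal_a"] else (alt if a_allele == ref else ref)
        bjub = {r: b_allele for r in recipients}
        if viol["bjub_nonuniform"] and len(recipients) > 1:
            odd = recipients[int(rng.integers(0, len(recipients)))]
            bjub[odd] = ref if b_allele == alt else alt

        row = {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "gt_donor": gt_donor}
        row.update({f"gt_{r}": gts[r] for r in recipients})
        row.update({f"bjub_{r}": bjub[r] for r in recipients})
        row["flag_flanking_variation"] = viol["flanking_variation"]
        row["flag_nigra_hit"] = viol["nigra_hit"]
        rows.append(row)

        # ground truth recomputed from the final genotype columns so that
        # interacting violations (e.g. a het call also breaking criterion ii)
        # are annotated consistently
        all_gts = [gt_donor] + [gts[r] for r in recipients]
        viol_i = any(g == HET for g in all_gts)
        viol_ii = gt_donor != HOM_REF
        rec_vals = [gts[r] for r in recipients]
        viol_iv = len(set(rec_vals)) > 1
        viol_iii = (not viol_iv) and rec_vals[0] == gt_donor
        uniform_a = (not viol_iv) and rec_vals[0] == gt_donor
        bjub_vals = [bjub[r] for r in recipients]
        bjub_uniform = len(set(bjub_vals)) == 1
        pass_a = not (viol_i or viol_ii or viol_iii or viol_iv
                      or viol["flanking_variation"] or viol["nigra_hit"])
        pass_b = ((not viol_i) and uniform_a and bjub_uniform
                  and bjub_vals[0] != a_allele
                  and all(g in (HOM_REF, HOM_ALT) for g in all_gts))
        ann_rows.append({"viol_i": viol_i, "viol_ii": viol_ii, "viol_iii": viol_iii,
                         "viol_iv": viol_iv, "viol_v": viol["flanking_variation"],
                         "viol_vi": viol["nigra_hit"], "pass_a": pass_a, "pass_b": pass_b})

    df = pd.DataFrame(rows)
    order = df.sort_values(["chrom", "pos"]).index
    variants = df.loc[order].reset_index(drop=True)
    ann = pd.DataFrame(ann_rows).loc[order].reset_index(drop=True)
    return ParentalVariantTable(variants, recipients, annotations=ann)


def simulate_accession_variants(samples: Sequence[str], n_loci: int,
                                chrom_lengths: Mapping[str, int],
                                rng: np.random.Generator | None = None,
                                het_rate: float = 0.02,
                                missing_rate: float = 0.0) -> pd.DataFrame:
    """Dense genome-wide variants (allele pairs per sample) for panel building.

    Returns a frame with chrom, pos and one ``"X/Y"`` genotype column per
    sample.  Most calls are homozygous; ``het_rate`` of sample calls are
    heterozygous (and thus excluded by the homozygosity criterion of dense
    panels).  Allele identities are biallelic per site.
    """
    rng = rng if rng is not None else np.random.default_rng()
    chrom_names = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    weights = np.array([chrom_lengths[c] for c in chrom_names], dtype=float) / total
    which = rng.choice(len(chrom_names), size=n_loci, p=weights)
    rows = []
    seen = set()
    for i in range(n_loci):
        chrom = chrom_names[which[i]]
        while True:
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            if (chrom, pos) not in seen:
                seen.add((chrom, pos))
                break
        a1, a2 = _NUCS[rng.choice(4, size=2, replace=False)]
        row = {"chrom": chrom, "pos": pos}
        for s in samples:
            u = rng.random()
            if u < missing_rate:
                row[s] = "./."
            elif u < missing_rate + het_rate:
                row[s] = f"{a1}/{a2}"
            else:
                allele = a1 if rng.random() < 0.5 else a2
                row[s] = f"{allele}/{allele}"
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# demo coordinates
# ---------------------------------------------------------------------------

def demo_map(n_chrom: int = 10, loci_per_chrom: int = 13,
             chrom_bp: int = 30_000_000, chrom_cm: float = 90.0) -> GeneticMap:
    """A regular synthetic map: ``n_chrom`` chromosomes with evenly spaced loci.

    Defaults give 130 loci over 10 chromosomes of 30 Mb / 90 cM each —
    comparable to an A-genome diagnostic marker panel (~13 markers per
    chromosome, ~7 cM intervals).
    """
    rows = []
    for c in range(1, n_chrom + 1):
        chrom = f"A{c:02d}"
        for j in range(loci_per_chrom):
            frac = (j + 0.5) / loci_per_chrom
            bp = int(frac * chrom_bp)
            rows.append({"id": f"{chrom}_{bp // 100_000}", "chrom": chrom,
                         "bp": bp, "cM": frac * chrom_cm})
    loci = pd.DataFrame(rows)
    lengths = {f"A{c:02d}": chrom_bp for c in range(1, n_chrom + 1)}
    return GeneticMap(loci, lengths)
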