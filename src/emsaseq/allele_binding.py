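"""Allele-specific binding potential over ChIP-Seq summit windows.

For every ChIP-Seq binding region (BR) a fixed 300-bp window — the
binding-region summit window (BRS) — is centered on the position of
maximum tag count.  BRS coordinates are BR-specific and shared by all
individuals.  Each individual's personalized window sequence (reference
sequence with that individual's SNP alleles substituted) is scanned for
enriched 11-mers from the in vitro selection data, and the *binding
potential* B is the sum of the enrichment z-scores of all mappable
enriched 11-mers.  Heterozygous individuals contribute both haplotypes
and B is the mean of the two haplotype sums, since the ChIP signal
aggregates both alleles.

A pair of individuals at one BRS shows *direct positive correlation*
when the sign of their binding-potential difference matches the sign of
their in vivo peak-height difference.  Peak-height differences are taken
as given from the upstream ChIP-Seq comparison; only direction is
classified here.

Trait-associated SNPs (TASs) are mapped to their nearest BRS and
category over-representation among the close (<=1 kb) TASs is assessed
with an upper-tail hypergeometric test.

Coordinates are 0-based half-open internally; BED input follows the BED
convention and VCF positions are converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .kmer_counting import canonical

WINDOW_SIZE = 300
TAS_DISTANCE_LIMIT = 1000
DEFAULT_DIMER_ORDER = ("RELAp50", "RELAp52", "RELARELA")

DIRECT_POSITIVE = "direct_positive"
NO_CORRELATION = "no_correlation"
NO_DIFFERENCE = "no_difference"


def window_bounds(summit: int, size: int = WINDOW_SIZE) -> tuple[int, int]:
    """Half-open window [summit - size/2, summit + size/2) of exactly ``size`` bp."""
    half = size // 2
    return summit - half, summit - half + size


@dataclass
class Variant:
    """One SNP inside a window; ``pos`` is window-relative, 0-based."""

    pos: int
    ref: str
    alt: str
    genotype: tuple[int, int]  # 0 = ref allele, 1 = alt allele

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"indels are out of scope: ref={self.ref!r} alt={self.alt!r}"
            )


@dataclass
class BindingRegionSummit:
    """A 300-bp summit-centered window with per-individual data."""

    brs_id: str
    chrom: str
    br_start: int
    br_end: int
    summit: int
    ref_window: str
    heights: dict[str, float]
    variants: dict[str, list[Variant]] = field(default_factory=dict)
    window_size: int = WINDOW_SIZE

    def __post_init__(self):
        if not (self.br_start <= self.summit < self.br_end):
            raise ValueError(
                f"{self.brs_id}: summit {self.summit} outside BR "
                f"[{self.br_start}, {self.br_end})"
            )
        if len(self.ref_window) != self.window_size:
            raise ValueError(
                f"{self.brs_id}: window sequence length {len(self.ref_window)} "
                f"!= {self.window_size}"
            )

    @property
    def window_start(self) -> int:
        return window_bounds(self.summit, self.window_size)[0]

    def haplotypes(self, individual: str) -> list[str]:
        return personalize_sequence(
            self.ref_window, self.variants.get(individual, [])
        )


def parse_genotype(gt: str) -> tuple[int, int]:
    sep = "|" if "|" in gt else "/"
    a, b = gt.split(sep)
    return int(a), int(b)


def personalize_sequence(reference: str, variants: list[Variant]) -> list[str]:
    """Apply SNP genotypes to a reference window.

    Returns one string for a fully homozygous genotype and two haplotype
    strings otherwise.  Unphased heterozygous sites all place their
    reference allele on the first haplotype and the alternate on the
    second (the two reference-vs-alternate expansions), rather than
    enumerating all allele combinations.
    """
    haps = [list(reference), list(reference)]
    for v in variants:
        if not (0 <= v.pos < len(reference)):
            raise ValueError(f"variant position {v.pos} outside window")
        if reference[v.pos] != v.ref:
            raise ValueError(
                f"reference mismatch at window position {v.pos}: "
                f"expected {v.ref!r}, window has {reference[v.pos]!r}"
            )
        for h, allele_idx in zip(haps, v.genotype):
            h[v.pos] = v.ref if allele_idx == 0 else v.alt
    seqs = ["".join(h) for h in haps]
    return [seqs[0]] if seqs[0] == seqs[1] else seqs


def scan_window(seq: str, affinity: dict[str, float], k: int = 11):
    """All enriched k-mer hits in a window.

    Every offset is looked up through its canonical form in the
    ``affinity`` map (canonical k-mer -> enrichment z of enriched
    k-mers); offsets without an enriched k-mer are omitted.  Canonical
    lookup makes the result invariant to reverse-complementing the
    whole window.
    """
    hits = []
    for offset in range(len(seq) - k + 1):
        kmer = canonical(seq[offset : offset + k])
        z = affinity.get(kmer)
        if z is not None:
            hits.append((offset, kmer, z))
    return hits


def binding_potential(hits) -> float:
    """Sum of enrichment z-scores over window hits."""
    return float(sum(z for _, _, z in hits))


def individual_potential(
    brs: BindingRegionSummit, individual: str, affinity: dict[str, float], k: int = 11
) -> float:
    """Binding potential of one individual: mean over haplotype window sums."""
    haps = brs.haplotypes(individual)
    return float(
        np.mean([binding_potential(scan_window(h, affinity, k)) for h in haps])
    )


def pooled_affinity(dimer_affinities: dict[str, dict[str, float]]) -> dict[str, float]:
    """Sum per-k-mer z across dimer datasets (union of enriched k-mers)."""
    pooled: dict[str, float] = {}
    for table in dimer_affinities.values():
        for kmer, z in table.items():
            pooled[kmer] = pooled.get(kmer, 0.0) + z
    return pooled


@dataclass
class PairComparison:
    """Classification of one ordered individual pair at one BRS."""

    brs_id: str
    individuals: tuple[str, str]
    delta_invivo: float
    b_a: float
    b_b: float
    method: str
    dimer: str | None
    cls: str


def _classify(b_a: float, b_b: float, delta_invivo: float) -> str:
    if b_a == b_b:
        return NO_DIFFERENCE
    if np.sign(b_a - b_b) == np.sign(delta_invivo) != 0:
        return DIRECT_POSITIVE
    return NO_CORRELATION


def compare_pair(
    brs: BindingRegionSummit,
    ind_a: str,
    ind_b: str,
    dimer_affinities: dict[str, dict[str, float]],
    method: str = "summed_dimers",
    dimer_order=DEFAULT_DIMER_ORDER,
    k: int = 11,
) -> PairComparison:
    """Compare in vitro binding potential with in vivo binding for one pair.

    ``summed_dimers`` pools the z-scores of every dimer's enriched
    k-mers into one affinity table.  ``per_dimer_fallback`` scores
    dimers one at a time in ``dimer_order`` and stops at the first
    direct positive correlation, reporting the last dimer tried
    otherwise.
    """
    for ind in (ind_a, ind_b):
        if ind not in brs.heights:
            raise KeyError(f"{brs.brs_id}: no peak height for individual {ind!r}")
    delta = brs.heights[ind_a] - brs.heights[ind_b]

    def one(affinity, dimer_name):
        b_a = individual_potential(brs, ind_a, affinity, k)
        b_b = individual_potential(brs, ind_b, affinity, k)
        return PairComparison(
            brs_id=brs.brs_id,
            individuals=(ind_a, ind_b),
            delta_invivo=delta,
            b_a=b_a,
            b_b=b_b,
            method=method,
            dimer=dimer_name,
            cls=_classify(b_a, b_b, delta),
        )

    if method == "summed_dimers":
        return one(pooled_affinity(dimer_affinities), None)
    if method == "per_dimer_fallback":
        comparison = None
        for dimer in dimer_order:
            if dimer not in dimer_affinities:
                continue
            comparison = one(dimer_affinities[dimer], dimer)
            if comparison.cls == DIRECT_POSITIVE:
                return comparison
        if comparison is None:
            raise ValueError("no dimer in dimer_order has an affinity table")
        return comparison
    raise ValueError(f"unknown method {method!r}")


def aggregate(comparisons) -> dict:
    """Counts and fractions per class, overall and by distinct BRS."""
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("no comparisons to aggregate")
    out: dict = {"n_comparisons": len(comparisons), "classes": {}}
    for cls in (DIRECT_POSITIVE, NO_CORRELATION, NO_DIFFERENCE):
        sub = [c for c in comparisons if c.cls == cls]
        out["classes"][cls] = {
            "count": len(sub),
            "fraction": len(sub) / len(comparisons),
            "n_brs": len({c.brs_id for c in sub}),
        }
    with_diff = [c for c in comparisons if c.cls != NO_DIFFERENCE]
    out["n_with_potential_difference"] = len(with_diff)
    out["direct_positive_given_difference"] = (
        sum(c.cls == DIRECT_POSITIVE for c in with_diff) / len(with_diff)
        if with_diff
        else float("nan")
    )
    return out


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "brs_id": c.brs_id,
            "ind_a": c.individuals[0],
            "ind_b": c.individuals[1],
            "delta_invivo": c.delta_invivo,
            "B_a": c.b_a,
            "B_b": c.b_b,
            "method": c.method,
            "dimer": c.dimer,
            "class": c.cls,
        }
        for c in comparisons
    )


def map_tas(
    tas: pd.DataFrame,
    brs_list: list[BindingRegionSummit],
    limit: int = TAS_DISTANCE_LIMIT,
) -> pd.DataFrame:
    """Map each trait-associated SNP to its nearest BRS by summit distance.

    ``tas`` needs columns ``tas_id, chrom, pos`` (0-based) and may carry
    a ``category`` column.  Ties in distance resolve to the summit with
    the lower coordinate.  The result is ordered by distance and flags
    the subset within ``limit`` bp.
    """
    if not brs_list:
        raise ValueError("empty BRS list")
    rows = []
    by_chrom: dict[str, list[BindingRegionSummit]] = {}
    for b in brs_list:
        by_chrom.setdefault(b.chrom, []).append(b)
    for rec in tas.itertuples(index=False):
        candidates = by_chrom.get(rec.chrom, [])
        if not candidates:
            rows.append((rec.tas_id, rec.chrom, rec.pos, None, np.nan, False))
            continue
        nearest = min(candidates, key=lambda b: (abs(b.summit - rec.pos), b.summit))
        dist = abs(nearest.summit - rec.pos)
        rows.append(
            (rec.tas_id, rec.chrom, rec.pos, nearest.brs_id, dist, dist <= limit)
        )
    out = pd.DataFrame(
        rows,
        columns=["tas_id", "chrom", "pos", "nearest_brs", "distance", "within_limit"],
    )
    if "category" in tas.columns:
        out["category"] = tas["category"].to_numpy()
    return out.sort_values(
        ["distance", "tas_id"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def hypergeometric_enrichment(n_total: int, n_category: int, n_drawn: int, n_observed: int) -> float:
    """Upper-tail hypergeometric p: P(X >= n_observed) drawing ``n_drawn``
    of ``n_total`` when ``n_category`` carry the label.  Zero observed
    successes give p = 1."""
    return float(stats.hypergeom.sf(n_observed - 1, n_total, n_category, n_drawn))


def tas_category_test(mapped: pd.DataFrame, category: str) -> dict:
    """Over-representation of one TAS category among within-limit TASs."""
    if "category" not in mapped.columns:
        raise ValueError("mapped TAS table carries no category column")
    n_total = len(mapped)
    n_category = int((mapped["category"] == category).sum())
    close = mapped[mapped["within_limit"]]
    n_drawn = len(close)
    n_observed = int((close["category"] == category).sum())
    return {
        "category": category,
        "N": n_total,
        "K": n_category,
        "n": n_drawn,
        "k": n_observed,
        "p": hypergeometric_enrichment(n_total, n_category, n_drawn, n_observed),
    }


# ---------------------------------------------------------------------------
# file ingest

def load_cohort(
    bed_path: str | Path,
    fasta_path: str | Path,
    vcf_path: str | Path | None = None,
    window_size: int = WINDOW_SIZE,
) -> list[BindingRegionSummit]:
    """Assemble BRS objects from a BED-like region table, a genome FASTA
    and an optional SNP VCF.

    The BED-like table is tab-separated with columns
    ``chrom, start, end, brs_id, summit`` followed by one
    ``height:<individual>`` column per individual.  VCF genotypes are
    matched to windows by overlap; positions convert from 1-based VCF to
    the internal 0-based convention.
    """
    from pyfaidx import Fasta

    bed = pd.read_csv(bed_path, sep="\t", comment="#")
    height_cols = [c for c in bed.columns if c.startswith("height:")]
    individuals = [c.split(":", 1)[1] for c in height_cols]
    genome = Fasta(str(fasta_path))
    brs_list = []
    for _, row in bed.iterrows():
        start, end = window_bounds(int(row["summit"]), window_size)
        ref_window = str(genome[str(row["chrom"])][start:end]).upper()
        brs_list.append(
            BindingRegionSummit(
                brs_id=str(row["brs_id"]),
                chrom=str(row["chrom"]),
                br_start=int(row["start"]),
                br_end=int(row["end"]),
                summit=int(row["summit"]),
                ref_window=ref_window,
                heights={
                    ind: float(row[col]) for ind, col in zip(individuals, height_cols)
                },
                window_size=window_size,
            )
        )
    if vcf_path is not None:
        _attach_vcf(brs_list, vcf_path, individuals)
    return brs_list


def _attach_vcf(brs_list, vcf_path, individuals) -> None:
    import pysam

    vcf = pysam.VariantFile(str(vcf_path))
    samples = [s for s in vcf.header.samples if s in set(individuals)]
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            continue  # SNP-only scope
        pos0 = rec.pos - 1
        for brs in brs_list:
            if brs.chrom != rec.chrom:
                continue
            wstart = brs.window_start
            if not (wstart <= pos0 < wstart + brs.window_size):
                continue
            for sample in samples:
                gt = rec.samples[sample]["GT"]
                if gt is None or None in gt:
                    continue
                if gt == (0, 0):
                    continue
                brs.variants.setdefault(sample, []).append(
                    Variant(
                        pos=pos0 - wstart,
                        ref=rec.ref,
                        alt=rec.alts[0],
                        genotype=(int(gt[0]), int(gt[1])),
                    )
                )
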