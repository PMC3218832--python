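"""Ground-truth simulators for every input the pipeline consumes.

The generator emulates, with known ground truth:

* a **selection-sequencing experiment** — a control pool of oligos with
  i.i.d. uniform degenerate regions, and a selected pool produced by
  resampling control molecules with Boltzmann-like weight
  ``exp(beta * best-window MATCH score)`` under a planted true binding
  model, so that high-affinity k-mers are enriched with known ordering;
* **count-level pools** for calibration studies of the enrichment
  caller (a complete-null pair of multinomial draws, and a spiked pair
  with a known set of k-mers at elevated probability);
* a **toy diploid cohort** — a small genome with summit-centered
  windows carrying planted binder k-mers, SNPs placed inside and
  outside those binders, and per-individual peak heights equal to a
  monotone function of the true binding potential plus Gaussian noise.

Everything derives from one ``numpy`` generator seeded from the
``GroundTruth`` seed, so regenerating with the same seed reproduces
every file byte-identically.  Sequencing error profiles, PCR bias and
chromatin effects are deliberately not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .allele_binding import (
    BindingRegionSummit,
    Variant,
    individual_potential,
    window_bounds,
)
from .kmer_counting import KmerTable, canonical, revcomp
from .motif_models import BindingModel, match_scores, model_from_iupac
from .sequencing_io import OligoDesign

_BASES = "ACGT"

#: default oligo layout: 20-mer degenerate region between constant 4-mer flanks
DEFAULT_DESIGN = OligoDesign(
    degenerate_length=20, flank5="GACG", flank3="CGTC", max_flank_mismatch=0
)
#: planted true model: the generalized NF-kB consensus with sharpened columns
DEFAULT_TRUE_CONSENSUS = "GGGRNNTTCC"
DEFAULT_BETA = 10.0
#: deep enough that the 2,097,152-member canonical 11-mer space is nearly
#: fully covered by the control pool (~9.5 expected counts per k-mer), as in
#: the real assay; shallower pools make per-k-mer recovery a presence lottery
DEFAULT_N_READS = 2_000_000
DEFAULT_N_BRS = 40
DEFAULT_N_INDIVIDUALS = 4


def _decode(codes: np.ndarray) -> list[str]:
    flat = np.array(list(_BASES))[codes]
    return ["".join(row) for row in flat]


def _random_kmer_strings(rng: np.random.Generator, n: int, k: int) -> list[str]:
    return _decode(rng.integers(0, 4, size=(n, k)))


@dataclass
class GroundTruth:
    """Everything the generator planted, serializable to YAML."""

    model: BindingModel
    beta: float = DEFAULT_BETA
    seed: int = 0
    design: OligoDesign = field(default_factory=lambda: DEFAULT_DESIGN)
    n_reads: int = DEFAULT_N_READS
    #: canonical k-mer -> relative true binding weight (consensus == 1)
    spiked: dict[str, float] = field(default_factory=dict)
    sigma: float = 0.0

    @property
    def k(self) -> int:
        return self.model.width

    def true_affinity_map(self, scale: float = 100.0) -> dict[str, float]:
        """Spiked k-mer -> planted affinity on the z-score-like scale
        used for cohort binding potentials (consensus == ``scale``)."""
        return {m: scale * w for m, w in self.spiked.items()}

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "beta": self.beta,
            "seed": self.seed,
            "sigma": self.sigma,
            "n_reads": self.n_reads,
            "design": {
                "degenerate_length": self.design.degenerate_length,
                "flank5": self.design.flank5,
                "flank3": self.design.flank3,
                "max_flank_mismatch": self.design.max_flank_mismatch,
            },
            "model_freqs": [[float(v) for v in row] for row in self.model.freqs],
            "spiked": {m: float(w) for m, w in self.spiked.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            model=BindingModel(np.array(payload["model_freqs"]), source="topN"),
            beta=payload["beta"],
            seed=payload["seed"],
            sigma=payload["sigma"],
            n_reads=payload["n_reads"],
            design=OligoDesign(**payload["design"]),
            spiked=dict(payload["spiked"]),
        )


def default_truth(seed: int, k: int = 11, **overrides) -> GroundTruth:
    """The default stated world: a sharpened NF-kB-like true model of
    width ``k`` and a planted affinity ladder of consensus mutants."""
    consensus = DEFAULT_TRUE_CONSENSUS
    if k == 11:
        consensus = "G" + consensus  # widen to 11 with a leading G
    elif k != len(consensus):
        consensus = ("G" * (k - len(consensus))) + consensus if k > len(consensus) else consensus[:k]
    model = model_from_iupac(consensus, pseudocount=0.02)
    truth = GroundTruth(model=model, seed=seed, **overrides)
    truth.spiked = planted_affinity_ladder(truth)
    return truth


def planted_affinity_ladder(
    truth: GroundTruth, n_per_distance: int = 50, max_mutations: int = 4
) -> dict[str, float]:
    """Canonical k-mer -> relative weight for a ladder of consensus mutants.

    The ladder holds the model consensus plus sampled mutants at 1 to
    ``max_mutations`` substitutions, spanning a wide range of true
    affinities; weights are ``exp(beta * (score - 1))`` so the consensus
    has weight 1.
    """
    rng = np.random.default_rng(truth.seed + 101)
    consensus = truth.model.consensus()
    k = len(consensus)
    candidates = {canonical(consensus)}
    for n_mut in range(1, max_mutations + 1):
        for _ in range(n_per_distance * 3):
            positions = rng.choice(k, size=n_mut, replace=False)
            seq = list(consensus)
            for p in positions:
                choices = [b for b in _BASES if b != seq[p]]
                seq[p] = choices[rng.integers(0, 3)]
            candidates.add(canonical("".join(seq)))
            if len(candidates) >= 1 + n_mut * n_per_distance:
                break
    kmers = sorted(candidates)
    scores = match_scores(kmers, truth.model)
    weights = np.exp(truth.beta * (scores - 1.0))
    return dict(zip(kmers, weights.tolist()))


# ---------------------------------------------------------------------------
# read-level pools

def write_fastq(path: str | Path, reads: list[str], prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def embed_regions(regions: list[str], design: OligoDesign) -> list[str]:
    return [design.flank5 + r + design.flank3 for r in regions]


def make_control_pool(
    n_reads: int,
    design: OligoDesign = DEFAULT_DESIGN,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[str]:
    """Unselected pool: i.i.d. uniform degenerate regions in design flanks."""
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    regions = _decode(rng.integers(0, 4, size=(n_reads, design.degenerate_length)))
    return embed_regions(regions, design)


def best_window_scores(regions: list[str], model: BindingModel) -> np.ndarray:
    """Best MATCH score over all windows and both strands, per region."""
    from .kmer_counting import encode_pool

    w = model.width
    codes = encode_pool(regions)
    if codes.shape[1] < w:
        raise ValueError("regions shorter than model width")
    info = model.info
    lo = float((info * model.freqs.min(axis=1)).sum())
    hi = float((info * model.freqs.max(axis=1)).sum())
    pos = np.arange(w)
    rc_perm = np.array([3, 2, 1, 0])
    best = np.full(len(regions), -np.inf)
    for offset in range(codes.shape[1] - w + 1):
        sub = codes[:, offset : offset + w]
        fwd = (info * model.freqs[pos, sub]).sum(axis=1)
        rc = (info * model.freqs[pos, rc_perm[sub][:, ::-1]]).sum(axis=1)
        best = np.maximum(best, np.maximum(fwd, rc))
    return (best - lo) / (hi - lo)


def make_selected_pool(
    control_reads: list[str],
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    n_reads: int | None = None,
) -> list[str]:
    """One round of selection: resample the control pool with weight
    ``exp(beta * best-window score)`` under the true model.

    ``beta = 0`` degenerates to an unweighted resample (no enrichment
    signal); large ``beta`` concentrates the pool on the highest-
    affinity molecules.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 11)
    design = truth.design
    regions = [
        r[len(design.flank5) : len(design.flank5) + design.degenerate_length]
        for r in control_reads
    ]
    scores = best_window_scores(regions, truth.model)
    weights = np.exp(truth.beta * (scores - scores.max()))
    weights /= weights.sum()
    n_out = n_reads if n_reads is not None else len(control_reads)
    chosen = rng.choice(len(regions), size=n_out, replace=True, p=weights)
    return embed_regions([regions[i] for i in chosen], design)


def simulate_pools(
    truth: GroundTruth, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write control and selected FASTQ pools plus the ground-truth YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    control = make_control_pool(truth.n_reads, truth.design, rng=rng)
    selected = make_selected_pool(control, truth, rng=rng)
    control_path = out_dir / "control.fastq"
    selected_path = out_dir / "selected.fastq"
    write_fastq(control_path, control, prefix="ctrl")
    write_fastq(selected_path, selected, prefix="sel")
    truth.to_yaml(out_dir / "truth.yaml")
    return control_path, selected_path


# ---------------------------------------------------------------------------
# count-level pools for caller calibration

def make_null_kmer_pools(
    n_kmers: int,
    total: int,
    rng: np.random.Generator,
    k: int = 11,
) -> tuple[KmerTable, KmerTable]:
    """Two pools drawn from one shared multinomial (complete null)."""
    kmers = _distinct_canonical_kmers(rng, n_kmers, k)
    p = np.full(len(kmers), 1.0 / len(kmers))
    sel = rng.multinomial(total, p)
    ctrl = rng.multinomial(total, p)
    return (
        KmerTable(k=k, counts=dict(zip(kmers, sel.astype(float))), n_total=float(total)),
        KmerTable(k=k, counts=dict(zip(kmers, ctrl.astype(float))), n_total=float(total)),
    )


def make_spiked_kmer_pools(
    n_background: int,
    n_spiked: int,
    total: int,
    rng: np.random.Generator,
    fold_range: tuple[float, float] = (5.0, 10.0),
    k: int = 11,
) -> tuple[KmerTable, KmerTable, set[str]]:
    """Control uniform; selected with ``n_spiked`` k-mers at ``fold_range``
    times the background probability.  Returns (selected, control, spiked set)."""
    kmers = _distinct_canonical_kmers(rng, n_background + n_spiked, k)
    spiked = set(kmers[:n_spiked])
    p_ctrl = np.full(len(kmers), 1.0 / len(kmers))
    folds = np.ones(len(kmers))
    folds[:n_spiked] = rng.uniform(*fold_range, size=n_spiked)
    p_sel = p_ctrl * folds
    p_sel /= p_sel.sum()
    sel = rng.multinomial(total, p_sel)
    ctrl = rng.multinomial(total, p_ctrl)
    return (
        KmerTable(k=k, counts=dict(zip(kmers, sel.astype(float))), n_total=float(total)),
        KmerTable(k=k, counts=dict(zip(kmers, ctrl.astype(float))), n_total=float(total)),
        spiked,
    )


def _distinct_canonical_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    seen: dict[str, None] = {}
    while len(seen) < n:
        batch = _random_kmer_strings(rng, max(2 * (n - len(seen)), 1000), k)
        for m in batch:
            seen.setdefault(canonical(m), None)
            if len(seen) == n:
                break
    return list(seen)


# ---------------------------------------------------------------------------
# toy diploid cohort

@dataclass
class Cohort:
    """A simulated cohort: genome, windows, genotypes and peak heights."""

    genome: dict[str, str]
    brs_list: list[BindingRegionSummit]
    individuals: list[str]
    truth: GroundTruth
    #: per-BRS list of (window offset, planted canonical k-mer)
    planted: dict[str, list[tuple[int, str]]]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out_dir / "genome.fa",
            "vcf": out_dir / "cohort.vcf",
            "bed": out_dir / "brs.bed.tsv",
            "truth": out_dir / "truth.yaml",
        }
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        self._write_vcf(paths["vcf"])
        self._write_bed(paths["bed"])
        self.truth.to_yaml(paths["truth"])
        return paths

    def _write_bed(self, path: Path) -> None:
        cols = ["chrom", "start", "end", "brs_id", "summit"] + [
            f"height:{ind}" for ind in self.individuals
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for b in self.brs_list:
                row = [b.chrom, str(b.br_start), str(b.br_end), b.brs_id, str(b.summit)]
                row += [f"{b.heights[ind]:.6f}" for ind in self.individuals]
                fh.write("\t".join(row) + "\n")

    def _write_vcf(self, path: Path) -> None:
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ]
        for chrom, seq in self.genome.items():
            lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(self.individuals)
        )
        records = []
        for b in self.brs_list:
            site_map: dict[int, tuple[str, str, dict[str, tuple[int, int]]]] = {}
            for ind in self.individuals:
                for v in b.variants.get(ind, []):
                    pos_genome = b.window_start + v.pos
                    entry = site_map.setdefault(pos_genome, (v.ref, v.alt, {}))
                    entry[2][ind] = v.genotype
            for pos_genome in sorted(site_map):
                ref, alt, gts = site_map[pos_genome]
                gt_fields = [
                    "{}/{}".format(*gts.get(ind, (0, 0))) for ind in self.individuals
                ]
                records.append(
                    (
                        b.chrom,
                        pos_genome + 1,
                        f"{b.chrom}\t{pos_genome + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                        + "\t".join(gt_fields),
                    )
                )
        records.sort(key=lambda r: (r[0], r[1]))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
            for _, _, rec in records:
                fh.write(rec + "\n")


def make_cohort(
    n_individuals: int = DEFAULT_N_INDIVIDUALS,
    n_brs: int = DEFAULT_N_BRS,
    truth: GroundTruth | None = None,
    sigma: float | None = None,
    seed: int | None = None,
    window_size: int = 300,
    br_width: int = 600,
    spacing: int = 2000,
    snps_per_brs: int = 2,
    height_baseline: float = 10.0,
) -> Cohort:
    """Simulate a diploid cohort with planted binders and SNPs.

    Each BRS window carries 1-3 planted high-affinity k-mers from the
    truth's affinity ladder.  ``snps_per_brs`` SNPs per window are
    placed preferentially inside planted binders (so that genotype
    differences translate into binding-potential differences) with one
    SNP outside.  Peak heights are
    ``height_baseline + B_true + sigma * N(0, 1)``, where ``B_true`` is
    the individual's binding potential under the planted affinity map —
    a monotone function of true binding potential plus noise.
    """
    if n_individuals < 2:
        raise ValueError("need at least two individuals")
    if truth is None:
        truth = default_truth(seed if seed is not None else 0)
    if sigma is not None:
        truth.sigma = sigma
    rng = np.random.default_rng(truth.seed + 202 if seed is None else seed)
    k = truth.k
    individuals = [f"IND{i:02d}" for i in range(1, n_individuals + 1)]
    affinity = truth.true_affinity_map()
    ladder = sorted(truth.spiked, key=truth.spiked.get, reverse=True)
    strong = ladder[: max(10, len(ladder) // 4)]

    chrom = "chrSim"
    genome_len = n_brs * spacing + spacing
    genome_codes = rng.integers(0, 4, size=genome_len)
    genome = list("".join(_BASES[c] for c in genome_codes))

    brs_list: list[BindingRegionSummit] = []
    planted: dict[str, list[tuple[int, str]]] = {}
    for i in range(n_brs):
        summit = spacing // 2 + i * spacing
        wstart, wend = window_bounds(summit, window_size)
        n_binders = int(rng.integers(1, 4))
        offsets: list[int] = []
        plants: list[tuple[int, str]] = []
        for _ in range(n_binders):
            for _attempt in range(50):
                off = int(rng.integers(0, window_size - k + 1))
                if all(abs(off - o) >= k for o in offsets):
                    offsets.append(off)
                    break
            else:
                continue
            kmer = strong[int(rng.integers(0, len(strong)))]
            seq = kmer if rng.integers(0, 2) == 0 else revcomp(kmer)
            genome[wstart + off : wstart + off + k] = list(seq)
            plants.append((off, kmer))

        brs_id = f"BRS{i:03d}"
        planted[brs_id] = plants

        variants: dict[str, list[Variant]] = {ind: [] for ind in individuals}
        used_positions: set[int] = set()
        for s in range(snps_per_brs):
            for _attempt in range(50):
                if plants and s < snps_per_brs - 1:
                    off, _ = plants[int(rng.integers(0, len(plants)))]
                    vpos = off + int(rng.integers(0, k))
                else:
                    vpos = int(rng.integers(0, window_size))
                if vpos not in used_positions:
                    break
            else:
                continue
            used_positions.add(vpos)
            ref_base = genome[wstart + vpos]
            alt_base = _BASES[
                (_BASES.index(ref_base) + 1 + int(rng.integers(0, 3))) % 4
            ]
            for ind in individuals:
                dose = int(rng.binomial(2, 0.5))
                if dose == 0:
                    continue
                gt = (0, 1) if dose == 1 else (1, 1)
                variants[ind].append(
                    Variant(pos=vpos, ref=ref_base, alt=alt_base, genotype=gt)
                )

        ref_window = "".join(genome[wstart:wend])
        brs = BindingRegionSummit(
            brs_id=brs_id,
            chrom=chrom,
            br_start=summit - br_width // 2,
            br_end=summit + br_width // 2,
            summit=summit,
            ref_window=ref_window,
            heights={},
            variants={ind: v for ind, v in variants.items() if v},
            window_size=window_size,
        )
        for ind in individuals:
            b_true = individual_potential(brs, ind, affinity, k)
            noise = float(rng.normal(0.0, truth.sigma)) if truth.sigma > 0 else 0.0
            brs.heights[ind] = height_baseline + b_true + noise
        brs_list.append(brs)

    return Cohort(
        genome={chrom: "".join(genome)},
        brs_list=brs_list,
        individuals=individuals,
        truth=truth,
        planted=planted,
    )
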