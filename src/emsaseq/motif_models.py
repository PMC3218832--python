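"""Quantitative binding models (PWMs) and MATCH similarity scoring.

A binding model is a width x 4 base-frequency matrix.  Similarity of a
fixed-width sequence to the model is measured with the matrix-similarity
part of the MATCH scheme of Kel and co-workers: each position is
weighted by its information content

    I(i) = sum_b f(i, b) * ln(4 * f(i, b))

and the score of sequence s is

    MSS = (Current - Min) / (Max - Min)

with Current = sum_i I(i) * f(i, s_i) and Min/Max built from the
per-column minimum/maximum frequencies.  The per-column argmax
(consensus) sequence scores exactly 1 and the per-column argmin scores
0.  Because the assay scores fixed-length k-mers rather than scanning a
genome, no core-similarity pre-filter is used, and by default the better
of the forward and reverse-complement scores is reported (the substrate
is double-stranded).

Sequence sets are classified by similarity to a reference model:
*canonical* binders score above 0.75, and the *extended* binder set
additionally keeps enriched k-mers whose enrichment z-score reaches the
per-MATCH-bin median (minus a 10% slack).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kmer_counting import canonical

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
#: reverse complement as an index permutation (A<->T, C<->G)
_RC_PERM = np.array([3, 2, 1, 0])

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

CANONICAL_MATCH_THRESHOLD = 0.75
DEFAULT_PSEUDOCOUNT = 1e-3
#: generalized NF-kB 11-mer consensus used for the packaged stand-in reference
REFERENCE_CONSENSUS = "RGGRNNHHYYB"


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character {exc} in sequence {seq!r}") from None


def information_vector(freqs: np.ndarray) -> np.ndarray:
    """Per-position information I(i) = sum_b f(i,b) ln(4 f(i,b)).

    Zero for a uniform column; ln 4 in the one-hot limit.  Cells with
    f = 0 contribute 0 (the x ln x -> 0 limit).
    """
    freqs = np.asarray(freqs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = freqs * np.log(4.0 * freqs)
    return np.where(freqs > 0, terms, 0.0).sum(axis=1)


@dataclass
class BindingModel:
    """A position frequency matrix with its MATCH information weights.

    ``freqs`` has one row per position, columns in A, C, G, T order;
    rows sum to 1.  ``source`` records how the model was built
    (``reference_pwm`` or ``topN``).
    """

    freqs: np.ndarray
    source: str = "reference_pwm"
    info: np.ndarray = field(init=False)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise ValueError(f"freqs must be width x 4, got {self.freqs.shape}")
        rowsums = self.freqs.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("frequency rows must each sum to 1")
        self.info = information_vector(self.freqs)

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    def consensus(self) -> str:
        """Per-column argmax sequence (ties broken toward A<C<G<T)."""
        return "".join(_BASES[i] for i in self.freqs.argmax(axis=1))

    def reverse_complement(self) -> "BindingModel":
        return BindingModel(self.freqs[::-1, _RC_PERM], source=self.source)


def build_model(
    kmers,
    weights=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    source: str = "topN",
) -> BindingModel:
    """Build a frequency model from equal-width k-mers.

    Column frequencies are (weighted) base tallies plus ``pseudocount``
    per cell, renormalized.  Weights default to 1 per k-mer; a typical
    choice is the enrichment z-score of each binder, giving a
    quantitative, affinity-weighted model.
    """
    kmers = list(kmers)
    if not kmers:
        raise ValueError("need at least one k-mer")
    width = len(kmers[0])
    if any(len(m) != width for m in kmers):
        raise ValueError("k-mers must all have the same width")
    if weights is None:
        weights = np.ones(len(kmers))
    else:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(kmers):
            raise ValueError("weights length must match k-mers")
        if np.any(weights < 0) or weights.sum() == 0:
            raise ValueError("weights must be non-negative and not all zero")
    counts = np.zeros((width, 4))
    for kmer, w in zip(kmers, weights):
        codes = encode(kmer)
        counts[np.arange(width), codes] += w
    counts += pseudocount
    return BindingModel(counts / counts.sum(axis=1, keepdims=True), source=source)


def _score_components(model: BindingModel):
    info = model.info
    current_min = float((info * model.freqs.min(axis=1)).sum())
    current_max = float((info * model.freqs.max(axis=1)).sum())
    return info, current_min, current_max


def match_scores(
    seqs, model: BindingModel, strand_policy: str = "best"
) -> np.ndarray:
    """Vectorized MATCH matrix-similarity scores for many sequences."""
    if strand_policy not in ("best", "forward"):
        raise ValueError(f"unknown strand_policy {strand_policy!r}")
    codes = np.vstack([encode(s) for s in seqs])
    if codes.shape[1] != model.width:
        raise ValueError(
            f"sequence width {codes.shape[1]} != model width {model.width}"
        )
    info, lo, hi = _score_components(model)
    if hi - lo <= 0:  # fully uniform matrix carries no information
        return np.zeros(len(codes))
    pos = np.arange(model.width)
    current = (info * model.freqs[pos, codes]).sum(axis=1)
    score = (current - lo) / (hi - lo)
    if strand_policy == "best":
        rc_codes = _RC_PERM[codes][:, ::-1]
        rc_current = (info * model.freqs[pos, rc_codes]).sum(axis=1)
        score = np.maximum(score, (rc_current - lo) / (hi - lo))
    return score


def match_score(seq: str, model: BindingModel, strand_policy: str = "best") -> float:
    """MATCH score of one sequence in [0, 1]; 1 at the consensus."""
    return float(match_scores([seq], model, strand_policy=strand_policy)[0])


@dataclass(frozen=True)
class MatchBin:
    """One MATCH-score bin: half-open on the left, closed on the right
    (the lowest bin is closed at both ends)."""

    label: str
    lower: float
    upper: float

    def contains(self, score: float) -> bool:
        if self.lower == 0.0:
            return 0.0 <= score <= self.upper
        return self.lower < score <= self.upper


DEFAULT_MATCH_BINS = [
    MatchBin("Grp1", 0.0, 0.20),
    MatchBin("Grp2", 0.20, 0.40),
    MatchBin("Grp3", 0.40, 0.60),
    MatchBin("Grp4", 0.60, 0.80),
    MatchBin("Grp5", 0.80, 1.0),
]


def assign_bins(scores, bins=None) -> list[str]:
    bins = DEFAULT_MATCH_BINS if bins is None else bins
    labels = []
    for s in scores:
        for b in bins:
            if b.contains(s):
                labels.append(b.label)
                break
        else:
            raise ValueError(f"MATCH score {s} falls in no bin")
    return labels


def canonical_binder_set(
    universe,
    reference: BindingModel,
    threshold: float = CANONICAL_MATCH_THRESHOLD,
) -> set[str]:
    """All k-mers in ``universe`` with MATCH score strictly above ``threshold``."""
    universe = list(universe)
    if not universe:
        return set()
    scores = match_scores(universe, reference)
    return {m for m, s in zip(universe, scores) if s > threshold}


def extended_binder_set(
    records,
    reference: BindingModel,
    bins=None,
    slack: float = 0.10,
) -> set[str]:
    """Enriched k-mers passing the per-MATCH-bin median-z filter.

    Within each MATCH-score bin, enriched k-mers are kept when their
    enrichment z-score is no more than ``slack`` (fractionally) below
    the bin's median z.  This admits strongly enriched non-canonical
    binders that a plain MATCH threshold would discard.
    """
    bins = DEFAULT_MATCH_BINS if bins is None else bins
    enriched = [r for r in records if r.enriched]
    if not enriched:
        return set()
    scores = match_scores([r.kmer for r in enriched], reference)
    labels = assign_bins(scores, bins)
    keep: set[str] = set()
    for b in bins:
        group = [r for r, lab in zip(enriched, labels) if lab == b.label]
        if not group:
            continue
        med = float(np.median([r.z for r in group]))
        cutoff = (1.0 - slack) * med
        keep.update(r.kmer for r in group if r.z >= cutoff)
    return keep


def reference_model(pseudocount: float = DEFAULT_PSEUDOCOUNT) -> BindingModel:
    """Packaged stand-in reference NF-kB model (synthetic).

    Built from the generalized 11-mer consensus RGGRNNHHYYB (each IUPAC
    code spread uniformly over its allowed bases), it stands in for the
    licensed TRANSFAC NF-kB matrix that cannot be redistributed.  All
    threshold-dependent binder sets are reproducible only relative to
    this stand-in.
    """
    return model_from_iupac(REFERENCE_CONSENSUS, pseudocount=pseudocount)


def model_from_iupac(
    consensus: str, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> BindingModel:
    """Frequency model from an IUPAC degenerate consensus string."""
    counts = np.zeros((len(consensus), 4))
    for i, code in enumerate(consensus.upper()):
        try:
            allowed = IUPAC[code]
        except KeyError:
            raise ValueError(f"unknown IUPAC code {code!r}") from None
        for b in allowed:
            counts[i, _BASE_INDEX[b]] = 1.0 / len(allowed)
    counts += pseudocount
    return BindingModel(
        counts / counts.sum(axis=1, keepdims=True), source="reference_pwm"
    )


def read_jaspar(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> BindingModel:
    """Read a JASPAR-format count matrix (``A [ 1 2 ... ]`` rows)."""
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            m = re.match(r"^([ACGT])\s*\[?\s*([\d.\s]+?)\s*\]?$", line)
            if not m:
                raise ValueError(f"{path}: unparsable JASPAR line {line!r}")
            rows[m.group(1)] = [float(v) for v in m.group(2).split()]
    if sorted(rows) != list("ACGT"):
        raise ValueError(f"{path}: expected A/C/G/T rows, got {sorted(rows)}")
    counts = np.array([rows[b] for b in _BASES], dtype=float).T
    counts += pseudocount
    return BindingModel(
        counts / counts.sum(axis=1, keepdims=True), source="reference_pwm"
    )


def read_transfac(path: str | Path, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> BindingModel:
    """Read a TRANSFAC-format matrix (``P0`` header, numbered count rows)."""
    counts_rows = []
    order = None
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if fields[0] in ("P0", "PO"):
                order = fields[1:5]
                if sorted(order) != list("ACGT"):
                    raise ValueError(f"{path}: bad base order {order}")
                continue
            if re.fullmatch(r"\d+", fields[0]) and order is not None:
                counts_rows.append([float(v) for v in fields[1:5]])
    if order is None or not counts_rows:
        raise ValueError(f"{path}: no TRANSFAC matrix block found")
    counts = np.array(counts_rows)
    # reorder columns to A, C, G, T
    counts = counts[:, [order.index(b) for b in _BASES]]
    counts += pseudocount
    return BindingModel(
        counts / counts.sum(axis=1, keepdims=True), source="reference_pwm"
    )


def score_table(kmers, reference: BindingModel, alt: BindingModel | None = None):
    """Per-k-mer MATCH scores against reference (and optional alternative
    model), with bin label and canonical flag; returns a pandas DataFrame."""
    import pandas as pd

    kmers = [canonical(m) for m in kmers]
    ref_scores = match_scores(kmers, reference)
    data = {
        "match_ref": ref_scores,
        "bin": assign_bins(ref_scores),
        "canonical_flag": ref_scores > CANONICAL_MATCH_THRESHOLD,
    }
    if alt is not None:
        data["match_alt"] = match_scores(kmers, alt)
    return pd.DataFrame(data, index=pd.Index(kmers, name="kmer"))


def model_to_transfac(model: BindingModel, path: str | Path, name: str = "model") -> None:
    with open(path, "w") as fh:
        fh.write(f"ID {name}\nP0 A C G T\n")
        for i, row in enumerate(model.freqs, start=1):
            fh.write(f"{i:02d} " + " ".join(f"{v:.6f}" for v in row) + "\n")
        fh.write("//\n")
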