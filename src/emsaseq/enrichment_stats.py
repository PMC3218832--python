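"""Binomial enrichment calling of k-mers in a selected versus a control pool.

The count of each k-mer in a pool is modeled as Binomial(n, p) where n
is the total number of k-mer observations in that pool and p the
probability of drawing that k-mer.  Under the null hypothesis of no
selection the two pools share one p; under the alternative the selected
pool has its own (larger) p.  The two scenarios are compared with a
likelihood-ratio test: the statistic 2(l1 - l0) is referred to a
chi-square distribution with one degree of freedom, and the p-value is
halved when the selected proportion exceeds the control proportion (and
set to 1 otherwise) to make the test one-sided for enrichment.
P-values are corrected with the Benjamini-Hochberg step-up procedure at
a false discovery rate of 0.01.

A pooled two-proportion z-score accompanies every test; it is the
normal-approximation twin of the LRT and is used for ranking and as the
quantitative per-k-mer affinity downstream.

Overlapping k-mers from one read are not independent observations; as
is conventional for this assay class, that dependence is ignored and the
FDR is interpreted per-k-mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from .kmer_counting import KmerTable

DEFAULT_ALPHA = 0.01
#: reporting-only pseudocount for fold-change columns (the LRT uses raw counts)
FOLD_PSEUDOCOUNT = 0.5


@dataclass
class EnrichmentRecord:
    """Result of the enrichment test for one canonical k-mer."""

    kmer: str
    x_sel: float
    x_ctrl: float
    n_sel: float
    n_ctrl: float
    z: float
    lrt_stat: float
    p: float
    q: float
    enriched: bool


def _binom_loglik(x, n, p):
    """Binomial log-likelihood without the constant binomial coefficient."""
    return special.xlogy(x, p) + special.xlogy(n - x, 1.0 - p)


def binomial_lrt(x_sel, n_sel, x_ctrl, n_ctrl):
    """One-sided binomial likelihood-ratio test for enrichment.

    Vectorized over count arrays.  Returns ``(lrt_stat, p_one_sided)``:
    the statistic 2(l1 - l0) and the chi-square(1) p-value halved when
    the selected proportion is larger, else 1 (enrichment only).
    """
    x_sel = np.asarray(x_sel, dtype=float)
    x_ctrl = np.asarray(x_ctrl, dtype=float)
    n_sel = float(n_sel)
    n_ctrl = float(n_ctrl)
    if n_sel <= 0 or n_ctrl <= 0:
        raise ValueError("pool totals must be positive")
    if np.any(x_sel < 0) or np.any(x_ctrl < 0):
        raise ValueError("counts must be non-negative")
    if np.any(x_sel > n_sel) or np.any(x_ctrl > n_ctrl):
        raise ValueError("count exceeds pool total")

    p0 = (x_sel + x_ctrl) / (n_sel + n_ctrl)
    p_sel = x_sel / n_sel
    p_ctrl = x_ctrl / n_ctrl
    l0 = _binom_loglik(x_sel, n_sel, p0) + _binom_loglik(x_ctrl, n_ctrl, p0)
    l1 = _binom_loglik(x_sel, n_sel, p_sel) + _binom_loglik(x_ctrl, n_ctrl, p_ctrl)
    lrt = np.maximum(2.0 * (l1 - l0), 0.0)
    p_two = stats.chi2.sf(lrt, df=1)
    p_one = np.where(p_sel > p_ctrl, 0.5 * p_two, 1.0)
    if np.isscalar(x_sel) or lrt.ndim == 0:
        return float(lrt), float(p_one)
    return lrt, p_one


def enrichment_zscore(x_sel, n_sel, x_ctrl, n_ctrl):
    """Pooled two-proportion z-score for enrichment.

    z = (p_sel - p_ctrl) / sqrt(p0 (1 - p0) (1/n_sel + 1/n_ctrl)) with
    p0 the pooled proportion; positive iff the selected proportion is
    larger.  Degenerate pooled proportions (0 or 1) give z = 0.
    """
    x_sel = np.asarray(x_sel, dtype=float)
    x_ctrl = np.asarray(x_ctrl, dtype=float)
    n_sel = float(n_sel)
    n_ctrl = float(n_ctrl)
    if n_sel <= 0 or n_ctrl <= 0:
        raise ValueError("pool totals must be positive")
    p0 = (x_sel + x_ctrl) / (n_sel + n_ctrl)
    var = p0 * (1.0 - p0) * (1.0 / n_sel + 1.0 / n_ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x_sel / n_sel - x_ctrl / n_ctrl) / np.sqrt(var)
    z = np.where(var > 0, z, 0.0)
    if z.ndim == 0:
        return float(z)
    return z


def bh_adjust(pvals, alpha: float = DEFAULT_ALPHA):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(qvals, reject)`` with monotone q-values and
    ``reject = q <= alpha``.  Empty input gives empty outputs.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy(), np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    qvals = stats.false_discovery_control(pvals, method="bh")
    return qvals, qvals <= alpha


def enrichment_table(
    selected: KmerTable, control: KmerTable, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Joint enrichment test over the union of k-mers seen in either pool.

    Returns a DataFrame indexed by k-mer with columns
    ``x_sel, x_ctrl, fold, z, lrt_stat, p, q, enriched`` sorted by
    descending z.  A k-mer absent from one pool enters with count 0; the
    union of observed k-mers (not the whole 4^k/2 universe) forms the
    family for BH correction.
    """
    if selected.k != control.k:
        raise ValueError(f"mismatched k: {selected.k} vs {control.k}")
    if control.n_total <= 0:
        raise ValueError("control pool is empty")
    kmers = sorted(set(selected.counts) | set(control.counts))
    x_sel = np.array([selected.counts.get(m, 0.0) for m in kmers])
    x_ctrl = np.array([control.counts.get(m, 0.0) for m in kmers])
    n_sel, n_ctrl = selected.n_total, control.n_total
    lrt, p = binomial_lrt(x_sel, n_sel, x_ctrl, n_ctrl)
    z = enrichment_zscore(x_sel, n_sel, x_ctrl, n_ctrl)
    q, reject = bh_adjust(p, alpha=alpha)
    enriched = reject & (x_sel / n_sel > x_ctrl / n_ctrl)
    fold = ((x_sel + FOLD_PSEUDOCOUNT) / n_sel) / ((x_ctrl + FOLD_PSEUDOCOUNT) / n_ctrl)
    df = pd.DataFrame(
        {
            "x_sel": x_sel,
            "x_ctrl": x_ctrl,
            "fold": fold,
            "z": z,
            "lrt_stat": lrt,
            "p": p,
            "q": q,
            "enriched": enriched,
        },
        index=pd.Index(kmers, name="kmer"),
    )
    df.attrs.update(n_sel=n_sel, n_ctrl=n_ctrl, alpha=alpha, k=selected.k)
    return df.sort_values("z", ascending=False, kind="mergesort")


def call_enriched(
    selected: KmerTable, control: KmerTable, alpha: float = DEFAULT_ALPHA
) -> list[EnrichmentRecord]:
    """Per-k-mer :class:`EnrichmentRecord` list, sorted by descending z."""
    df = enrichment_table(selected, control, alpha=alpha)
    n_sel, n_ctrl = df.attrs["n_sel"], df.attrs["n_ctrl"]
    return [
        EnrichmentRecord(
            kmer=kmer,
            x_sel=row.x_sel,
            x_ctrl=row.x_ctrl,
            n_sel=n_sel,
            n_ctrl=n_ctrl,
            z=row.z,
            lrt_stat=row.lrt_stat,
            p=row.p,
            q=row.q,
            enriched=bool(row.enriched),
        )
        for kmer, row in zip(df.index, df.itertuples(index=False))
    ]


def write_enrichment_tsv(df: pd.DataFrame, path: str | Path, header_lines=()) -> None:
    """Write the enrichment table with a provenance/header block."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            f"# alpha={df.attrs.get('alpha')}\tn_sel={df.attrs.get('n_sel'):.10g}"
            f"\tn_ctrl={df.attrs.get('n_ctrl'):.10g}\tk={df.attrs.get('k')}\n"
        )
        df.to_csv(fh, sep="\t", float_format="%.6g")


def read_enrichment_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="kmer")
    return df


def affinity_map(df: pd.DataFrame, enriched_only: bool = True) -> dict[str, float]:
    """Canonical k-mer -> z map for downstream window scanning."""
    sub = df[df["enriched"]] if enriched_only else df
    return dict(zip(sub.index, sub["z"].astype(float)))
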